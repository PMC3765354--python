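"""Architecture- and similarity-based AP2/ERF family, subfamily and group
assignment.

Rule precedence is fixed and deterministic: domain architecture first (two
AP2 domains -> AP2 family; AP2 + B3 -> RAV; one AP2 -> ERF candidate), then
the Soloist check (nearest-exemplar is the divergent Soloist reference),
then the single-domain AP2 rescue (high full-length similarity to an AP2
family reference), then nearest-exemplar group assignment within the
winning family. All identity thresholds are inclusive (>=).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .domains import DomainHit
from .homology import global_align
from .synthetic import AP2_GROUPS, DREB_GROUPS, ERF_GROUPS, ReferencePanel

FAMILIES = ("AP2", "ERF", "RAV", "Soloist")


@dataclasses.dataclass(frozen=True)
class FamilyCall:
    gene_id: str
    family: str      # AP2 | ERF | RAV | Soloist | none
    subfamily: str   # DREB | ERF | n/a
    group: str       # DREB-A1..A6 | ERF-B1..B6 | AP2-R1/R2 | RAV | Soloist | unassigned
    evidence: str    # rule id, optionally with supporting identity %


def classify_architecture(hits: list[DomainHit]) -> tuple[str, str]:
    """Provisional family from domain architecture alone.

    Returns (family, evidence); three or more AP2 domains are flagged for
    review but kept in the AP2 family.
    """
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    n_ap2 = sum(1 for h in hits if h.domain_name == "AP2")
    n_b3 = sum(1 for h in hits if h.domain_name == "B3")
    if n_ap2 >= 3:
        return "AP2", "architecture:multi-AP2-review"
    if n_ap2 == 2:
        return "AP2", "architecture:double-AP2"
    if n_ap2 == 1 and n_b3 >= 1:
        return "RAV", "architecture:AP2+B3"
    if n_ap2 == 1:
        return "ERF-candidate", "architecture:single-AP2"
    return "none", "architecture:no-AP2"


def rescue_single_domain_ap2(protein: str, ap2_family_refs: dict[str, str],
                             min_identity: float = 60.0) -> tuple[bool, float]:
    """Single-AP2 rescue: best full-length global identity against any AP2
    family reference; >= min_identity reassigns the gene to the AP2 family."""
    if not ap2_family_refs:
        raise ValueError("empty AP2 reference set")
    best = max(global_align(protein, ref, "q", rid).identity
               for rid, ref in ap2_family_refs.items())
    return best >= min_identity, best


def detect_soloist(domain_seq: str, panel: ReferencePanel,
                   min_identity: float = 50.0) -> tuple[bool, float]:
    """True iff the Soloist reference is the domain's best exemplar hit and
    the identity clears the floor."""
    best_group, best_ident, best_score = None, -1.0, float("-inf")
    for group in sorted(panel.group_exemplars):
        res = global_align(domain_seq, panel.group_exemplars[group], "q", group)
        if res.score > best_score:
            best_group, best_ident, best_score = group, res.identity, res.score
    return best_group == "Soloist" and best_ident >= min_identity, best_ident


def assign_group(domain_seq: str, panel: ReferencePanel, family: str,
                 min_identity: float = 40.0) -> tuple[str, str, float]:
    """Nearest-exemplar group call over the domain region.

    Candidate exemplars are restricted to the gene's family (DREB/ERF groups
    for ERF-family genes, AP2-R1/R2 for AP2). Ties break by higher alignment
    score, then lexicographic exemplar id. Below the identity floor the gene
    stays 'unassigned'. Returns (group, subfamily, identity)."""
    if family == "ERF":
        candidates = DREB_GROUPS + ERF_GROUPS
    elif family == "AP2":
        candidates = AP2_GROUPS
    else:
        raise ValueError(f"group assignment applies to ERF/AP2, not {family}")
    best = None  # (identity, score, group); ties -> score, then lexicographic id
    for group in sorted(candidates):
        res = global_align(domain_seq, panel.group_exemplars[group], "q", group)
        if best is None or (res.identity, res.score) > (best[0], best[1]):
            best = (res.identity, res.score, group)
    identity, _score, group = best
    if identity < min_identity:
        return "unassigned", "n/a", identity
    if group.startswith("DREB-"):
        return group, "DREB", identity
    if group.startswith("ERF-"):
        return group, "ERF", identity
    return group, "n/a", identity


def classify_proteome(
    proteins: dict[str, str],
    hits_by_protein: dict[str, list[DomainHit]],
    panel: ReferencePanel,
    rescue_identity: float = 60.0,
    soloist_floor: float = 50.0,
    group_floor: float = 40.0,
) -> list[FamilyCall]:
    """One FamilyCall per protein, applying the full rule chain.

    Input order never affects any call: proteins are processed by id."""
    calls = []
    for gid in sorted(proteins):
        hits = hits_by_protein.get(gid, [])
        family, evidence = classify_architecture(hits)
        ap2_hits = [h for h in hits if h.domain_name == "AP2"]
        domain_seq = None
        if ap2_hits:
            h = ap2_hits[0]
            domain_seq = proteins[gid][h.start - 1:h.end]

        if family == "ERF-candidate":
            is_solo, solo_ident = detect_soloist(domain_seq, panel, soloist_floor)
            if is_solo:
                calls.append(FamilyCall(gid, "Soloist", "n/a", "Soloist",
                                        f"soloist:best-hit@{solo_ident:.1f}"))
                continue
            rescued, resc_ident = rescue_single_domain_ap2(
                proteins[gid], panel.ap2_full_refs, rescue_identity)
            if rescued:
                family, evidence = "AP2", f"rescue:single-AP2@{resc_ident:.1f}"
            else:
                family = "ERF"

        if family in ("ERF", "AP2"):
            group, subfamily, ident = assign_group(domain_seq, panel, family,
                                                   group_floor)
            calls.append(FamilyCall(gid, family, subfamily, group,
                                    f"{evidence};group@{ident:.1f}"))
        elif family == "RAV":
            calls.append(FamilyCall(gid, "RAV", "n/a", "RAV", evidence))
        elif family == "none":
            calls.append(FamilyCall(gid, "none", "n/a", "unassigned", evidence))
        else:  # AP2 straight from architecture handled above; safeguard
            raise AssertionError(family)
    return calls


def census(calls: list[FamilyCall]) -> pd.DataFrame:
    """Counts per family, subfamily and group, plus a total row.

    Rows are labelled level/name; total equals the number of genes called
    into a family (family 'none' is counted separately, outside the total)."""
    fam_counts = {f: 0 for f in FAMILIES}
    sub_counts = {"DREB": 0, "ERF": 0}
    group_counts: dict[str, int] = {}
    n_none = 0
    seen = set()
    for c in calls:
        if c.gene_id in seen:
            raise ValueError(f"duplicate call for {c.gene_id}")
        seen.add(c.gene_id)
        if c.family == "none":
            n_none += 1
            continue
        fam_counts[c.family] += 1
        if c.subfamily in sub_counts:
            sub_counts[c.subfamily] += 1
        group_counts[c.group] = group_counts.get(c.group, 0) + 1
    rows = [("family", f, n) for f, n in fam_counts.items()]
    rows += [("subfamily", s, n) for s, n in sub_counts.items()]
    rows += [("group", g, n) for g, n in sorted(group_counts.items())]
    rows.append(("total", "classified", sum(fam_counts.values())))
    rows.append(("total", "none", n_none))
    return pd.DataFrame(rows, columns=["level", "name", "count"])
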