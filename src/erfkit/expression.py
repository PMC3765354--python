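"""EST-to-CDS mapping and tissue expression profiling.

ESTs are mapped to coding sequences with a seed-and-extend strategy (k-mer
seeds, banded edit-distance extension); a hit is eligible when its identity
clears the gate over a minimum overlap and its E-value surrogate is under
the gate, and each EST is assigned to its single best CDS (ties go to the
alphabetically first id). Raw eligible-hit counts per tissue are the
expression proxy — no library-size normalization by default, matching how
EST tag counts are conventionally read.
"""

from __future__ import annotations

import dataclasses
import re
from itertools import combinations

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import DNA, TISSUES, round_half_up, substream
from .calibrate import TailFit, fit_tail

MATCH_SCORE = 2.0
MISMATCH_PENALTY = 3.0


@dataclasses.dataclass(frozen=True)
class ESTHit:
    est_id: str
    cds_id: str
    identity: float
    overlap: int
    score: float
    evalue_surrogate: float


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_DNA_TAIL: TailFit | None = None
_DNA_REF_SPACE = 200 * 1000


def _cigar_stats(cigar: str, edit_distance: int) -> tuple[int, int, int]:
    """(matches, columns, query_span) from an edlib cigar."""
    counts = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for n, op in _CIGAR_RE.findall(cigar):
        counts[op] += int(n)
    m_total = counts["M"] + counts["="] + counts["X"]
    indels = counts["I"] + counts["D"]
    mismatches = edit_distance - indels
    matches = m_total - mismatches
    columns = m_total + indels
    query_span = m_total + counts["I"]
    return matches, columns, query_span


def _dna_score_tail() -> tuple[TailFit, int]:
    """Lazy decoy calibration of the nucleotide score tail (fixed internal
    decoy stream; deterministic)."""
    global _DNA_TAIL
    if _DNA_TAIL is None:
        rng = substream(20130824, "dna-decoys")
        bases = list(DNA)
        scores = np.empty(400)
        for i in range(400):
            q = "".join(rng.choice(bases, 200))
            t = "".join(rng.choice(bases, 1000))
            res = edlib.align(q, t, mode="HW", task="path")
            m, cols, _ = _cigar_stats(res["cigar"], res["editDistance"])
            scores[i] = MATCH_SCORE * m - MISMATCH_PENALTY * (cols - m)
        _DNA_TAIL = fit_tail(scores)
    return _DNA_TAIL, _DNA_REF_SPACE


def _kmer_index(cds: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for cid, seq in cds.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], set()).add(cid)
    return index


def map_cds_to_ests(
    cds: dict[str, str],
    ests: dict[str, str],
    manifest: dict[str, str],
    min_identity: float = 90.0,
    max_e: float = 1e-5,
    min_overlap_bp: int = 100,
    k: int = 11,
    band: int = 15,
) -> tuple[list[ESTHit], list[ESTHit]]:
    """Map every EST against the CDS set.

    Returns (assignments, eligible): `eligible` holds every (EST, CDS) hit
    passing the identity/overlap/E gates; `assignments` keeps one best CDS
    per EST (highest score; ties -> alphabetical CDS id)."""
    missing = [e for e in ests if e not in manifest]
    if missing:
        raise KeyError(f"ESTs missing a tissue label: {missing[:3]}")
    index = _kmer_index(cds, k)
    tail, ref_space = _dna_score_tail()
    total_cds_bp = sum(len(s) for s in cds.values())
    eligible: list[ESTHit] = []
    assignments: list[ESTHit] = []
    for eid in sorted(ests):
        read = ests[eid]
        if len(read) < k:
            continue
        candidates: set[str] = set()
        for i in range(len(read) - k + 1):
            candidates |= index.get(read[i:i + k], set())
        hits = []
        for cid in sorted(candidates):
            # band: allowed edit distance for the identity gate plus slack
            k_ed = int(np.ceil(len(read) * (1 - min_identity / 100.0))) + band
            res = edlib.align(read, cds[cid], mode="HW", task="path", k=k_ed)
            if res["editDistance"] < 0:
                continue
            matches, cols, qspan = _cigar_stats(res["cigar"], res["editDistance"])
            identity = 100.0 * matches / cols if cols else 0.0
            score = MATCH_SCORE * matches - MISMATCH_PENALTY * (cols - matches)
            evalue = (len(read) * total_cds_bp / ref_space) * tail.tail_prob(score)
            if identity >= min_identity and qspan >= min_overlap_bp \
                    and evalue <= max_e:
                hits.append(ESTHit(eid, cid, identity, qspan, score, evalue))
        eligible.extend(hits)
        if hits:
            best = max(hits, key=lambda h: (h.score, [-ord(c) for c in h.cds_id]))
            assignments.append(best)
    return assignments, eligible


def tissue_counts(assignments: list[ESTHit], manifest: dict[str, str],
                  all_genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene eligible-EST counts per tissue (full table; genes with zero
    total are retained so callers can split expressed vs silent)."""
    genes = sorted(set(h.cds_id for h in assignments) | set(all_genes or []))
    table = pd.DataFrame(0, index=genes, columns=list(TISSUES))
    for h in assignments:
        tissue = manifest.get(h.est_id)
        if tissue is None:
            raise KeyError(f"EST {h.est_id!r} not in manifest")
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r} for EST {h.est_id!r}")
        table.loc[h.cds_id, tissue] += 1
    table.index.name = "gene_id"
    return table


def expressed(profiles: pd.DataFrame) -> pd.DataFrame:
    return profiles[profiles.sum(axis=1) > 0]


def tissue_totals(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue transcript totals and percent of grand total (2 dp,
    round half up)."""
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    totals = profiles.sum(axis=0)
    grand = int(totals.sum())
    if grand == 0:
        raise ValueError("all-zero expression table: percentages undefined")
    out = pd.DataFrame({
        "tissue": list(TISSUES),
        "total": [int(totals[t]) for t in TISSUES],
        "percent": [round_half_up(100.0 * totals[t] / grand, 2) for t in TISSUES],
    })
    return out


def sharing_table(profiles: pd.DataFrame,
                  family_by_gene: dict[str, str] | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Tissue-subset sharing counts over expressed genes, plus an optional
    family-level summary.

    Subset percentages use 2 dp; the family table (per-tissue expressed-gene
    counts, type-num, percentage of expressed genes) uses 1 dp, both round
    half up."""
    expr = expressed(profiles)
    n_expr = len(expr)
    subset_of = {g: frozenset(t for t in TISSUES if expr.loc[g, t] > 0)
                 for g in expr.index}
    rows = []
    for r in range(1, 7):
        for combo in combinations(TISSUES, r):
            key = frozenset(combo)
            count = sum(1 for s in subset_of.values() if s == key)
            rows.append(("+".join(combo), count,
                         round_half_up(100.0 * count / n_expr, 2) if n_expr else 0.0))
    subsets = pd.DataFrame(rows, columns=["tissues", "genes", "percent"])
    family_table = None
    if family_by_gene is not None:
        fams = sorted({family_by_gene[g] for g in expr.index
                       if g in family_by_gene})
        frows = []
        for fam in fams:
            members = [g for g in expr.index if family_by_gene.get(g) == fam]
            per_tissue = [sum(1 for g in members if expr.loc[g, t] > 0)
                          for t in TISSUES]
            frows.append((fam, *per_tissue, len(members),
                          round_half_up(100.0 * len(members) / n_expr, 1)))
        frows.append(("Total",
                      *[sum(1 for g in expr.index if expr.loc[g, t] > 0)
                        for t in TISSUES],
                      n_expr, 100.0))
        family_table = pd.DataFrame(
            frows, columns=["family", *[t.capitalize() for t in TISSUES],
                            "type_num", "percent"])
    return subsets, family_table


def pcc(x, y) -> float:
    """Pearson product-moment correlation; undefined (raises) on zero
    variance rather than silently returning 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pcc needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pcc undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclasses.dataclass
class ClusterResult:
    linkage: np.ndarray
    ids: list[str]            # ids actually clustered, input order
    leaf_order: list[str]     # dendrogram flattening order
    newick: str
    excluded: list[str]       # constant profiles (PCC undefined)


def cluster_profiles(profiles: pd.DataFrame, method: str = "average") -> ClusterResult:
    """Agglomerative clustering of expression profiles at distance 1 - PCC.

    Constant (zero-variance) profiles are excluded with a warning entry;
    merge order is scipy's deterministic ordering."""
    ids = [g for g in profiles.index if np.std(profiles.loc[g].to_numpy()) > 0]
    excluded = [g for g in profiles.index if g not in set(ids)]
    if len(ids) < 2:
        raise ValueError("need >= 2 profiles with variance")
    mat = profiles.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - pcc(mat[i], mat[j])
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    order = [ids[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(linkage=z, ids=ids, leaf_order=order,
                         newick=_linkage_to_newick(z, ids), excluded=excluded)


def top_split(result: ClusterResult) -> tuple[set[str], set[str]]:
    """Leaf membership of the two clusters below the final merge."""
    labels = hierarchy.fcluster(result.linkage, 2, criterion="maxclust")
    a = {g for g, lab in zip(result.ids, labels) if lab == 1}
    b = {g for g, lab in zip(result.ids, labels) if lab == 2}
    return a, b


def _linkage_to_newick(z: np.ndarray, ids: list[str]) -> str:
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return ids[node]
        left, right, height, _ = z[node - n]
        left, right = int(left), int(right)
        bl = height - heights[left]
        br = height - heights[right]
        return f"({render(left)}:{bl:.6g},{render(right)}:{br:.6g})"

    for idx, (l, r, h, _) in enumerate(z):
        heights[n + idx] = h
    return render(n + len(z) - 1) + ";"
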