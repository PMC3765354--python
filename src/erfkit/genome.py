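"""Chromosome distribution tables, tandem-cluster detection, and synteny
link tables.

Coordinates are 1-based inclusive throughout. Genes on unrecognized or
unanchored sequence carry the chromosome name 'scaffold': they are excluded
from per-chromosome counts but always reported, never dropped.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .classify import FamilyCall
from .homology import HomologyPair
from .io import GeneLocus

FAMILY_COLUMNS = ("DREB", "ERF", "AP2", "RAV", "Soloist")


def _family_column(call: FamilyCall) -> str | None:
    """Table column for a call: ERF-family genes split by subfamily."""
    if call.family == "ERF":
        return call.subfamily if call.subfamily in ("DREB", "ERF") else None
    if call.family in ("AP2", "RAV", "Soloist"):
        return call.family
    return None


@dataclasses.dataclass
class DistributionResult:
    table: pd.DataFrame          # chromosome x family counts with totals
    scaffold: pd.DataFrame       # same shape, scaffold genes only
    exclusions: list[str]        # loci without a usable family call


def distribution_table(calls: list[FamilyCall],
                       loci: list[GeneLocus]) -> DistributionResult:
    """Per-chromosome family counts with row/column totals.

    Scaffold genes are tallied in a separate one-row table; loci whose gene
    has no family call (or family 'none') go to the exclusions list."""
    call_by_id = {c.gene_id: c for c in calls}
    chroms = sorted({l.chromosome for l in loci if l.placed})
    counts = pd.DataFrame(0, index=chroms, columns=list(FAMILY_COLUMNS))
    scaffold = pd.DataFrame(0, index=["scaffold"], columns=list(FAMILY_COLUMNS))
    exclusions = []
    for locus in sorted(loci, key=lambda l: l.gene_id):
        call = call_by_id.get(locus.gene_id)
        col = _family_column(call) if call else None
        if col is None:
            exclusions.append(locus.gene_id)
            continue
        if locus.placed:
            counts.loc[locus.chromosome, col] += 1
        else:
            scaffold.loc["scaffold", col] += 1
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    scaffold["Total"] = scaffold.sum(axis=1)
    counts.index.name = "Chromosome"
    return DistributionResult(table=counts, scaffold=scaffold,
                              exclusions=exclusions)


def tandem_clusters(loci: list[GeneLocus], group_calls: dict[str, str],
                    max_intervening: int = 1,
                    max_span_kb: float = 100.0) -> list[list[str]]:
    """Maximal runs of >= 2 same-group genes on one chromosome.

    Genes are ordered by start per chromosome; two same-group genes chain
    when at most `max_intervening` other surveyed genes lie between them
    and their spacing (start-to-start) is <= max_span_kb. Output order and
    content are invariant to input ordering and per-chromosome coordinate
    translation."""
    placed = [l for l in loci if l.placed and l.gene_id in group_calls]
    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in placed:
        by_chrom.setdefault(l.chromosome, []).append(l)
    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda l: (l.start, l.gene_id))
        n = len(genes)
        used = [False] * n
        for i in range(n):
            if used[i]:
                continue
            grp = group_calls[genes[i].gene_id]
            run = [i]
            last = i
            while True:
                nxt = None
                for j in range(last + 1, min(n, last + 2 + max_intervening)):
                    if (not used[j]
                            and group_calls[genes[j].gene_id] == grp
                            and genes[j].start - genes[last].start
                            <= max_span_kb * 1000):
                        nxt = j
                        break
                if nxt is None:
                    break
                run.append(nxt)
                last = nxt
            if len(run) >= 2:
                for k in run:
                    used[k] = True
                clusters.append([genes[k].gene_id for k in run])
    return clusters


def synteny_links(pairs: list[HomologyPair], lociA: list[GeneLocus],
                  lociB: list[GeneLocus]) -> pd.DataFrame:
    """One row per homology pair with both coordinates, Circos-style.

    Scaffold genes are flagged, not dropped; a pair naming an unknown gene
    raises with the id."""
    locA = {l.gene_id: l for l in lociA}
    locB = {l.gene_id: l for l in lociB}
    rows = []
    for p in pairs:
        if p.idA not in locA:
            raise KeyError(f"unknown gene id {p.idA!r} in link table")
        if p.idB not in locB:
            raise KeyError(f"unknown gene id {p.idB!r} in link table")
        a, b = locA[p.idA], locB[p.idB]
        rows.append((p.idA, a.chromosome, a.start, a.end,
                     p.idB, b.chromosome, b.start, b.end,
                     p.relation, round(p.identity, 2),
                     (not a.placed) or (not b.placed)))
    return pd.DataFrame(rows, columns=[
        "idA", "chromA", "startA", "endA", "idB", "chromB", "startB", "endB",
        "relation", "identity", "scaffold_flag"])
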