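"""Deterministic conserved-block and consensus-element analysis of family
alignments.

Instead of EM-based motif discovery, conservation is scored per alignment
column (frequency of the modal non-gap residue) and the conserved motif is
the longest contiguous run of columns clearing a conservation threshold
and a gap-fraction ceiling. This reproduces comparative motif-length
statements (e.g. which family carries the longest conserved block) without
a motif-discovery dependency.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

GAP = "-"


@dataclasses.dataclass
class ConservationProfile:
    alignment_id: str
    scores: np.ndarray        # per-column modal-residue frequency, [0, 1]
    gap_fractions: np.ndarray


@dataclasses.dataclass(frozen=True)
class MotifBlock:
    start: int   # 0-based column
    length: int
    consensus: str
    mean_conservation: float


class EmptyBlockError(ValueError):
    """No alignment column satisfies the block criteria."""


def _columns(alignment: dict[str, str]) -> np.ndarray:
    if len(alignment) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    return np.array([list(s) for s in alignment.values()])


def column_conservation(alignment: dict[str, str],
                        alignment_id: str = "aln") -> ConservationProfile:
    """Per column: modal non-gap residue count / non-gap count (0 for
    all-gap columns), plus the gap fraction."""
    arr = _columns(alignment)
    n, L = arr.shape
    scores = np.zeros(L)
    gaps = np.zeros(L)
    for c in range(L):
        col = arr[:, c]
        residues = col[col != GAP]
        gaps[c] = 1.0 - residues.size / n
        if residues.size:
            scores[c] = Counter(residues).most_common(1)[0][1] / residues.size
    return ConservationProfile(alignment_id, scores, gaps)


def block_consensus(alignment: dict[str, str], start: int, length: int) -> str:
    arr = _columns(alignment)
    out = []
    for c in range(start, start + length):
        col = arr[:, c]
        residues = col[col != GAP]
        out.append(Counter(residues).most_common(1)[0][0] if residues.size else GAP)
    return "".join(out)


def conserved_block(profile: ConservationProfile, alignment: dict[str, str],
                    score_threshold: float = 0.8,
                    max_gap_fraction: float = 0.2) -> MotifBlock:
    """Longest contiguous qualifying run (ties -> leftmost); raises
    EmptyBlockError when no column qualifies."""
    ok = (profile.scores >= score_threshold) & (profile.gap_fractions <= max_gap_fraction)
    if not ok.any():
        raise EmptyBlockError(
            f"{profile.alignment_id}: no column meets score >= {score_threshold} "
            f"and gap fraction <= {max_gap_fraction}")
    best_start, best_len = 0, 0
    run_start = None
    for c, good in enumerate(list(ok) + [False]):
        if good and run_start is None:
            run_start = c
        elif not good and run_start is not None:
            if c - run_start > best_len:
                best_start, best_len = run_start, c - run_start
            run_start = None
    cons = block_consensus(alignment, best_start, best_len)
    mean_cons = float(profile.scores[best_start:best_start + best_len].mean())
    return MotifBlock(start=best_start, length=best_len, consensus=cons,
                      mean_conservation=mean_cons)


def element_presence(alignment: dict[str, str],
                     elements: list[str]) -> dict[str, dict]:
    """Per element: fraction of (ungapped) sequences containing it, plus the
    modal best-matching variant across sequences.

    The variant is each sequence's highest-match window against the element
    (leftmost on ties), so a set where WLG has uniformly drifted to HLG
    reports fraction 0.0 with modal variant 'HLG'."""
    for el in elements:
        if not 2 <= len(el) <= 6:
            raise ValueError(f"element {el!r} must be 2-6 residues")
    report: dict[str, dict] = {}
    seqs = {k: s.replace(GAP, "") for k, s in alignment.items()}
    for el in elements:
        k = len(el)
        present = 0
        variants = []
        for s in seqs.values():
            if len(s) < k:
                continue
            if el in s:
                present += 1
                variants.append(el)
                continue
            best_w, best_m = None, -1
            for i in range(len(s) - k + 1):
                m = sum(1 for a, b in zip(s[i:i + k], el) if a == b)
                if m > best_m:
                    best_w, best_m = s[i:i + k], m
            variants.append(best_w)
        report[el] = {
            "fraction": present / len(seqs) if seqs else 0.0,
            "modal_variant": (Counter(variants).most_common(1)[0][0]
                              if variants else None),
        }
    return report
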