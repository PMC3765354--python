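"""Global pairwise alignment, percent identity, and threshold-based
ortholog/paralog/duplicate calling.

Identity convention: matches divided by alignment columns after trimming
terminal gap overhangs; internal gaps stay in the denominator. This is the
closest desk-scale analogue of the local-alignment identity a BLAST-based
survey reports, and it is used unchanged at every identity gate (inclusive
">=" at each bar).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._util import AMINO_ACIDS
from .calibrate import TailFit, fit_tail


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0,
                  gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    idA: str
    idB: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float  # percent, 0..100
    evalue_surrogate: float


@dataclasses.dataclass(frozen=True)
class HomologyPair:
    idA: str
    idB: str
    relation: str  # ortholog | paralog | duplicate
    identity: float
    evalue_surrogate: float


# Lazily fitted decoy score tails, keyed by (matrix, gap_open, gap_extend).
_TAIL_CACHE: dict[tuple, tuple[TailFit, int]] = {}
_DECOY_LEN = 150
_N_DECOYS = 600
_DECOY_SEED = 20130823  # fixed internal decoy stream; results deterministic


def _score_tail(matrix: str, gap_open: float, gap_extend: float) -> tuple[TailFit, int]:
    key = (matrix, gap_open, gap_extend)
    if key not in _TAIL_CACHE:
        rng = np.random.default_rng(_DECOY_SEED)
        aligner = _make_aligner(matrix, gap_open, gap_extend)
        aa = np.array(list(AMINO_ACIDS))
        scores = np.empty(_N_DECOYS)
        for i in range(_N_DECOYS):
            a = "".join(rng.choice(aa, _DECOY_LEN))
            b = "".join(rng.choice(aa, _DECOY_LEN))
            scores[i] = aligner.score(a, b)
        _TAIL_CACHE[key] = (fit_tail(scores), _DECOY_LEN * _DECOY_LEN)
    return _TAIL_CACHE[key]


def _surrogate_evalue(score: float, len_a: int, len_b: int, matrix: str,
                      gap_open: float, gap_extend: float) -> float:
    """Search-space-scaled expected decoy count at this score or better."""
    fit, ref_space = _score_tail(matrix, gap_open, gap_extend)
    return (len_a * len_b / ref_space) * fit.tail_prob(score)


def global_align(a: str, b: str, idA: str = "A", idB: str = "B",
                 matrix: str = "BLOSUM62", gap_open: float = 11.0,
                 gap_extend: float = 1.0) -> AlignmentResult:
    """Optimal affine-gap global alignment with deterministic traceback.

    The pair is aligned in a canonical orientation (lexicographic by
    sequence, then id) so identity(a, b) == identity(b, a) exactly.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    swapped = (b, idB) < (a, idA)
    s1, s2 = (b, a) if swapped else (a, b)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(s1, s2)[0]
    row1, row2 = str(aln[0]), str(aln[1])
    if swapped:
        row1, row2 = row2, row1
    identity = _percent_identity(row1, row2)
    ev = _surrogate_evalue(aln.score, len(a), len(b), matrix, gap_open, gap_extend)
    return AlignmentResult(idA=idA, idB=idB, aligned_a=row1, aligned_b=row2,
                           score=float(aln.score), identity=identity,
                           evalue_surrogate=ev)


def _percent_identity(row_a: str, row_b: str) -> float:
    """Matches / columns after trimming terminal gap overhangs, in percent."""
    cols = [(x, y) for x, y in zip(row_a, row_b)]
    first = next(i for i, (x, y) in enumerate(cols) if x != "-" and y != "-")
    last = next(i for i, (x, y) in reversed(list(enumerate(cols)))
                if x != "-" and y != "-")
    core = cols[first:last + 1]
    matches = sum(1 for x, y in core if x == y and x != "-")
    return 100.0 * matches / len(core)


def percent_identity(a: str, b: str, **kwargs) -> float:
    return global_align(a, b, **kwargs).identity


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidates(seqsA: dict[str, str], seqsB: dict[str, str], k: int = 5,
                min_shared: int = 3):
    """Seed prefilter: pairs sharing >= min_shared k-mers. Pairs anywhere
    near an identity gate share far more, so the filter never clips them."""
    kmersB = {gid: _kmer_set(s, k) for gid, s in seqsB.items()}
    for ga, sa in seqsA.items():
        ka = _kmer_set(sa, k)
        for gb, kb in kmersB.items():
            if len(ka & kb) >= min_shared:
                yield ga, gb


def find_orthologs(speciesA: dict[str, str], speciesB: dict[str, str],
                   min_identity: float = 75.0, max_e: float = 1e-10,
                   prefilter: bool = True) -> list[HomologyPair]:
    """Best cross-species hit per A-gene kept above the identity/E gates.

    Many-to-one mapping is allowed: several A genes may share one B partner,
    as expected after whole-genome multiplication.
    """
    overlap = set(speciesA) & set(speciesB)
    if overlap:
        raise ValueError(f"id namespaces overlap: {sorted(overlap)[:3]}")
    cand: dict[str, list[str]] = {}
    if prefilter:
        for ga, gb in _candidates(speciesA, speciesB):
            cand.setdefault(ga, []).append(gb)
    else:
        cand = {ga: list(speciesB) for ga in speciesA}
    pairs = []
    for ga in speciesA:
        best = None
        for gb in cand.get(ga, []):
            res = global_align(speciesA[ga], speciesB[gb], ga, gb)
            if best is None or res.score > best.score:
                best = res
        if best is not None and best.identity >= min_identity \
                and best.evalue_surrogate <= max_e:
            pairs.append(HomologyPair(best.idA, best.idB, "ortholog",
                                      best.identity, best.evalue_surrogate))
    return pairs


def _best_within(species: dict[str, str], min_identity: float, max_e: float,
                 relation: str, prefilter: bool) -> list[HomologyPair]:
    ids = list(species)
    cand: dict[str, set[str]] = {g: set() for g in ids}
    if prefilter:
        kmers = {g: _kmer_set(s, 5) for g, s in species.items()}
        for ga, gb in itertools.combinations(ids, 2):
            if len(kmers[ga] & kmers[gb]) >= 3:
                cand[ga].add(gb)
                cand[gb].add(ga)
    else:
        for ga in ids:
            cand[ga] = set(ids) - {ga}
    aln_cache: dict[tuple, AlignmentResult] = {}

    def aligned(x, y):
        key = (x, y) if x < y else (y, x)
        if key not in aln_cache:
            aln_cache[key] = global_align(species[key[0]], species[key[1]], *key)
        return aln_cache[key]

    pairs = []
    for ga in ids:
        best, best_partner = None, None
        for gb in sorted(cand[ga]):
            res = aligned(ga, gb)
            if best is None or res.score > best.score:
                best, best_partner = res, gb
        if best is not None and best.identity >= min_identity \
                and best.evalue_surrogate <= max_e:
            pairs.append(HomologyPair(ga, best_partner, relation,
                                      best.identity, best.evalue_surrogate))
    return pairs


def find_paralogs(species: dict[str, str], min_identity: float = 80.0,
                  max_e: float = 1e-10, prefilter: bool = True) -> list[HomologyPair]:
    """Within-species best partner per gene at the paralogy identity gate."""
    return _best_within(species, min_identity, max_e, "paralog", prefilter)


def find_duplicates(species: dict[str, str], min_identity: float = 95.0,
                    max_e: float = 1e-10, dedupe: bool = False,
                    prefilter: bool = True) -> list[HomologyPair]:
    """Near-identical duplicate calling; both orientations reported unless
    `dedupe` collapses reciprocal pairs to one row."""
    pairs = [HomologyPair(p.idA, p.idB, "duplicate", p.identity, p.evalue_surrogate)
             for p in _best_within(species, min_identity, max_e, "duplicate",
                                   prefilter)]
    if dedupe:
        seen, out = set(), []
        for p in pairs:
            key = frozenset((p.idA, p.idB))
            if key not in seen:
                seen.add(key)
                out.append(p)
        return out
    return pairs
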