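# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions that make the pipeline deterministic.

## Domain detection

Domains (AP2, ~58 aa; B3, ~70 aa here) are modelled as position frequency
matrices over the 20 amino acids. Scanning slides the log-odds matrix
(bits, log2 of pseudocounted column frequency over a background
composition, default uniform 1/20) across the protein; unknown residues
('X') contribute 0 bits per column. Overlapping above-threshold windows are
resolved greedily by descending score, ties to the leftmost start — within
one model and across models on the same protein.

The detection threshold is calibrated empirically rather than taken from
alignment-statistics theory: `n_decoys` (default 10,000) background windows
are scored, an exponential tail is fitted above the 95th percentile
(peaks-over-threshold with the mean-excess scale estimator), and the
threshold is the score whose expected decoy count in a database of
`database_size` windows (default 100,000) equals the target E-value
(default 1e-4). The same fit supplies each hit's E-value surrogate. A model
whose decoy scores have no spread (zero-information columns) raises a
calibration error instead of returning a meaningless threshold. Doubling
the database size raises the threshold monotonically, as it must.

The protein- and nucleotide-alignment E-value surrogates use the same
machinery: a tail fitted once on internally seeded random decoy pairs,
scaled by the query × database search space. These surrogates reproduce
the *role* of BLAST's E gates (1e-10 homology, 1e-5 EST eligibility)
without reproducing Karlin–Altschul constants; every gate decision in the
pipeline is far from the fitted region's edge, so the approximation is
never load-bearing.

## Classification

Rule order is fixed: architecture → Soloist check → single-domain AP2
rescue → group assignment. Architecture alone decides AP2 (two AP2
domains), RAV (AP2 + B3) and "none"; single-AP2 genes are ERF candidates.
A candidate whose best exemplar hit is the divergent Soloist reference (at
identity ≥ 50%) becomes the Soloist; otherwise, a candidate with
full-length global identity ≥ 60% to any two-domain AP2 reference is
rescued into the AP2 family (the rescue bar is a package default — set
below the 75% ortholog bar and above the 40% group floor — because
"high similarity" has no standard numeric value). Remaining candidates are
ERF-family genes grouped by nearest exemplar (best identity, ties by
alignment score then exemplar id; DREB-A* sets subfamily DREB, ERF-B* sets
ERF). All identity comparisons in the package are inclusive (≥).

Group names follow the DREB-A1..A6 / ERF-B1..B6 scheme; the mapping from
Roman-numeral clade labels (I–VI ERF, VII–XII DREB, XIII–XV AP2/RAV/
Soloist) is recorded in `config.GROUP_ROMAN_MAP`.

## Pairwise homology

`global_align` is an affine-gap global alignment (BLOSUM62, gap open 11 /
extend 1, the standard protein defaults; the opening charge covers the
first gap residue). Pairs are aligned in a canonical orientation so
identity is exactly symmetric. Percent identity = matches / alignment
columns after trimming terminal gap overhangs, internal gaps counted in
the denominator — the closest global-alignment analogue of the
local-alignment identity a BLAST-based survey reports. Ortholog calling
keeps each query's best-scoring cross-species hit at identity ≥ 75% and
E ≤ 1e-10; the map is deliberately many-to-one (whole-genome-multiplied
genomes map several genes onto one ortholog). Paralogs (≥ 80%) and
duplicates (≥ 95%) are within-species best hits; both gates exist because
survey practice quotes both numbers for "duplication". A k-mer prefilter
(shared 5-mers ≥ 3) skips hopeless pairs; any pair near an identity gate
shares dozens of 5-mers, so the filter cannot change a call.

## Phylogeny

Distances are amino-acid p-distances with pairwise deletion: per pair,
mismatches over columns where neither sequence has a gap; a pair with no
comparable columns is an error naming the pair, never an infinite
distance. (A Poisson correction is available behind a flag; p-distance is
the declared default.) Neighbor joining uses the Q criterion with
Studier–Keppler updates; ties in Q break to the smallest (i, j) index
pair, and negative branch-length estimates are clamped to zero with the
total deficit recorded on the tree. The result is unrooted (the returned
root is the final degree-3 junction). Bootstrap resamples alignment
columns with replacement, rebuilds the tree per replicate, and reports
each original bipartition's frequency as an integer percentage; supports
≤ 50 are written but flagged, following the display convention for such
trees. NJ is exactly consistent on additive matrices, which the tests
exploit as an oracle (random additive trees up to 12 taxa, plus an
independent NJ implementation as cross-check).

## Motif blocks

Conservation is per alignment column: frequency of the modal non-gap
residue among non-gap entries (0 for all-gap columns). The conserved motif
is the longest contiguous run of columns with conservation ≥ 0.8 and gap
fraction ≤ 0.2 (ties leftmost; both knobs configurable — no standard
numeric criterion exists, so the defaults are declared). This
deterministic block caller reproduces comparative motif-length statements
(e.g. the RAV family's 50-aa block vs the ERF subfamily's 27-aa block)
without EM-based motif discovery, which is out of scope. Short element
reporting (WLG, AYD and their family variants YLG/HLG/LYD) searches each
ungapped sequence for the element, and reports the modal best-matching
window across sequences, so a family where the element has drifted
uniformly reports presence 0 with the drifted variant named.

## Genome map

Coordinates are 1-based inclusive; genes on unrecognized sequence are
"scaffold" — excluded from per-chromosome counts, tallied separately,
never dropped. Tandem clusters are maximal runs of same-group genes on one
chromosome where consecutive members are separated by at most one other
surveyed gene and at most 100 kb (start-to-start). The proximity rule has
no published numeric form; these defaults are chosen so that runs of
consecutively numbered same-group genes qualify, and both knobs are in the
config. Synteny links are one row per homology pair with both coordinate
sets and a scaffold flag — the table a Circos-style plot would consume
(rendering is out of scope).

## Expression

ESTs map to coding sequences by seed-and-extend: 11-mer seeds index the
CDS set; candidates are aligned with banded infix edit-distance
(band = allowed mismatches for the identity gate + 15), and a hit is
eligible at identity ≥ 90% over ≥ 100 bp with E ≤ 1e-5. Each EST counts
once, for its best CDS (ties to the alphabetically first id) — multi-
mapping policy is a declared choice. Expression is the raw eligible-hit
count per tissue (bud, flower, leaf, root, seed, silique), as EST tag
counts are conventionally read; no library-size normalization by default.
Tissue totals report percentages at 2 decimals, the family summary at 1,
both rounding half up so printed-table arithmetic reproduces exactly.
Profile clustering uses average-linkage agglomeration at distance
1 − PCC; zero-variance profiles are excluded with a warning because PCC is
undefined for them (the pcc function raises rather than returning 0).

## The synthetic generator

The generator fabricates the statistical structure the survey's decision
rules consume, with truth tables for everything it plants:

- **Domain models**: per-column Dirichlet draws peaked on a consensus
  (concentration `diversity`, default 20, on the consensus residue; 0.4 on
  the rest, so columns admit a handful of alternatives — the sparse shape
  conserved columns actually have). The AP2 consensus carries WLG and AYD
  elements at fixed positions.
- **Proteome**: default census 248 ERF (109 DREB / 139 ERF-subfamily,
  spread round-robin over six groups each) / 29 AP2 (9 single-domain) /
  14 RAV / 1 Soloist. Group identity is planted by deriving each gene's
  domain from its group exemplar at 10% divergence; flanks and linkers are
  uniform-background residues. The Soloist exemplar is drawn at sampling
  temperature 1.3, keeping the draw whose model score is nearest 90 bits:
  clearly above any calibrated threshold, clearly below typical hits —
  the "low conservation, single copy" profile that defines a Soloist.
  (Hotter sampling pushes most draws below the detection threshold, which
  would contradict the Soloist being detectable at all.)
- **mutate_copy**: exactly round(len·(1−identity)) substitutions at
  distinct positions, no indels, so planted identities are exact to 1/len.
  An indel-free design keeps every identity-threshold test sharp.
- **Within/between-species homologs**: planted by overwriting genes with
  mutated copies at drawn identities (duplicates 96–100%, paralogs 83–93%,
  orthologs 78–95% into a second id namespace). Pairs are drawn from the
  single-AP2 groups, where surveyed duplications concentrate.
- **Genome layout**: 10 chromosomes, non-overlapping 1-based intervals;
  planted clusters are placed consecutively with 5–20 kb internal gaps
  while unrelated neighbours sit 150–400 kb apart, so planted runs are the
  only qualifying clusters; 3 genes are left unanchored by default.
- **EST libraries**: per gene × tissue, a negative-binomial count
  (dispersion 0.3 — any overdispersed count model suffices to exercise the
  counting logic) of reads drawn as contiguous CDS substrings (150–400 bp)
  with per-base substitution errors (default 1%). CDS are independent
  random DNA: codon structure, introns and library-size imbalance are not
  modelled, and none of the counting rules depend on them.

What passing tests show, and what they do not: recovery of planted truth
demonstrates that every decision rule implements its stated threshold
semantics and that the stage couplings are correct. It does not
demonstrate performance on real proteomes, where domain instances are not
PFM draws, homologs have indels, and EST libraries are biased; the
generator's non-goals are exactly those realism dimensions.

Note on rank recovery: with negative-binomial dispersion 0.3, the sampling
noise alone caps the Spearman correlation between planted means and *any*
recovered counts near 0.90. The expression tests therefore check rank
agreement between recovered and realized library counts (≥ 0.95, with
≥ 95% exact count agreement), which is the part the mapper and counter
control.

## Determinism and problem sizes

All randomness flows from one config seed through named substreams (a
stable FNV-1a hash of the stage name folded into the numpy SeedSequence),
so reruns are byte-identical, which the tests assert file-by-file. The
default test suite runs the survey at a 34-gene census with 40–50
bootstrap replicates; the acceptance script runs the full 292-gene census
with 1000 bootstrap replicates, 100 additive-matrix draws, and 100
two-block clustering designs — sizes chosen so each suite completes in
minutes on one core while every statistical check retains its power.

## Known limitations

- The PSSM scan has no insert/delete states; domains with indels relative
  to the model would score below a profile-HMM's sensitivity. The
  generator plants indel-free domains accordingly.
- E-values are empirical surrogates; absolute values are not comparable to
  BLAST's, only the gate decisions are.
- The center-star/progressive alignment fallback is not implemented:
  phylogeny and motif stages take pre-aligned input (planted domains share
  the model length, so generator output is natively aligned).
- Best-hit orthology is not reciprocal-best; with planted near-duplicates
  a gene may best-hit its sibling's partner, which the truth comparisons
  account for.
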