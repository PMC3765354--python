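"""Synthetic inputs with known ground truth for the whole survey pipeline.

The generator emulates the statistical structure a genome-wide AP2/ERF
survey assumes: a proteome with planted domain architectures in realistic
family proportions (ERF/AP2/RAV/Soloist), group identities derived from a
labelled exemplar panel, a 10-chromosome layout with tandem clusters and a
few unanchored scaffold genes, a diverged second species with known
ortholog pairs, and tissue-labelled EST libraries drawn from known
per-gene expression means. Everything is deterministic for a fixed seed.

It does not attempt realistic triplication history, codon structure,
introns, or EST library-size imbalance — only the features the pipeline's
decision rules actually consume.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from ._util import AMINO_ACIDS, DNA, TISSUES, check_protein, substream
from .domains import DomainModel
from .io import GeneLocus

AP2_LEN = 58
B3_LEN = 70

DREB_GROUPS = tuple(f"DREB-A{i}" for i in range(1, 7))
ERF_GROUPS = tuple(f"ERF-B{i}" for i in range(1, 7))
AP2_GROUPS = ("AP2-R1", "AP2-R2")
ALL_GROUPS = DREB_GROUPS + ERF_GROUPS + AP2_GROUPS + ("RAV", "Soloist")

#: Default family census: the composition of a crucifer AP2/ERF superfamily
#: (248 single-domain ERF incl. 109 DREB + 139 ERF-subfamily genes, 29 AP2
#: of which 9 carry a single domain, 14 RAV, 1 Soloist; 291 genes total).
DEFAULT_CENSUS = {"ERF": 248, "AP2": 29, "RAV": 14, "Soloist": 1}
DEFAULT_DREB_TOTAL = 109
DEFAULT_ERFSUB_TOTAL = 139
DEFAULT_RESCUE_COUNT = 9  # AP2-family genes carrying only one AP2 domain

#: Short conserved elements planted inside the AP2 domain consensus, at
#: fixed domain-relative positions (0-based): the WLG element and the AYD
#: element, whose family-specific variants (YLG in AP2, HLG/LYD in Soloist)
#: the motif stage is expected to recover.
WLG_POS = 20
AYD_POS = 40


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth for one generated bundle."""

    architectures: dict[str, list[tuple[str, int, int]]]  # 1-based intervals
    family_labels: dict[str, str]
    group_labels: dict[str, str]
    ortholog_pairs: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    tandem_clusters: list[list[str]] = dataclasses.field(default_factory=list)
    expression_means: pd.DataFrame | None = None
    rng_seed: int = 0

    def to_json(self, path) -> None:
        obj = {
            "architectures": self.architectures,
            "family_labels": self.family_labels,
            "group_labels": self.group_labels,
            "ortholog_pairs": self.ortholog_pairs,
            "tandem_clusters": self.tandem_clusters,
            "expression_means": (
                None if self.expression_means is None
                else {g: [float(x) for x in row]
                      for g, row in self.expression_means.iterrows()}
            ),
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        em = obj["expression_means"]
        return cls(
            architectures={g: [tuple(h) for h in v] for g, v in obj["architectures"].items()},
            family_labels=obj["family_labels"],
            group_labels=obj["group_labels"],
            ortholog_pairs=[tuple(p) for p in obj["ortholog_pairs"]],
            tandem_clusters=obj["tandem_clusters"],
            expression_means=(None if em is None else
                              pd.DataFrame.from_dict(em, orient="index",
                                                     columns=list(TISSUES))),
            rng_seed=obj["rng_seed"],
        )


# ---------------------------------------------------------------------------
# domain models and sequence sampling


def make_domain_model(consensus: str, diversity: float, seed: int,
                      name: str = "AP2") -> DomainModel:
    """Build a PFM peaked at `consensus`, one Dirichlet draw per column.

    `diversity` is the concentration placed on the consensus residue;
    off-consensus residues get a sparse concentration (0.4), so each column
    admits a handful of plausible alternatives rather than a uniform smear
    — the shape conserved domain columns actually have. diversity ->
    infinity collapses each column onto the consensus.
    """
    check_protein(consensus, allow_x=False)
    if len(consensus) < 10:
        raise ValueError("consensus must be >= 10 residues")
    if diversity <= 0:
        raise ValueError("diversity must be positive")
    rng = np.random.default_rng(seed)
    pfm = np.empty((len(consensus), 20))
    for i, aa in enumerate(consensus):
        alpha = np.full(20, 0.4)
        alpha[AMINO_ACIDS.index(aa)] = diversity
        pfm[i] = rng.dirichlet(alpha)
        # guarantee the column is peaked at the consensus residue
        j = AMINO_ACIDS.index(aa)
        if pfm[i].argmax() != j:
            k = pfm[i].argmax()
            pfm[i][j], pfm[i][k] = pfm[i][k], pfm[i][j]
    return DomainModel(name=name, pfm=pfm)


def sample_from_model(model: DomainModel, rng: np.random.Generator,
                      temperature: float = 1.0) -> str:
    """Draw one domain sequence column-wise from the PFM; temperature > 1
    flattens the columns (more divergent draws)."""
    p = model.pfm ** (1.0 / temperature)
    p /= p.sum(axis=1, keepdims=True)
    return "".join(AMINO_ACIDS[rng.choice(20, p=row)] for row in p)


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Background residues: uniform over the 20 amino acids (configurable
    at the model level; the survey's rules are insensitive to composition)."""
    return "".join(rng.choice(list(AMINO_ACIDS), length))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), length))


def default_models(diversity: float = 20.0, seed: int = 101) -> dict[str, DomainModel]:
    """The bundle's AP2 and B3 domain models, with the WLG/AYD elements
    planted in the AP2 consensus."""
    rng = np.random.default_rng(seed)
    ap2_cons = list(random_protein(rng, AP2_LEN))
    ap2_cons[WLG_POS:WLG_POS + 3] = "WLG"
    ap2_cons[AYD_POS:AYD_POS + 3] = "AYD"
    b3_cons = random_protein(rng, B3_LEN)
    return {
        "AP2": make_domain_model("".join(ap2_cons), diversity, seed + 1, name="AP2"),
        "B3": make_domain_model(b3_cons, diversity, seed + 2, name="B3"),
    }


def mutate_copy(seq: str, target_identity: float, seed: int | np.random.Generator) -> str:
    """Copy with floor-rounded len*(1 - target_identity) substitutions at
    distinct positions (no indels); substitutes uniformly over the 19
    alternative residues, so realized identity equals the target to 1/len."""
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(round(len(seq) * (1.0 - target_identity)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = alternatives[rng.integers(19)]
    return "".join(out)


# ---------------------------------------------------------------------------
# reference panel


@dataclasses.dataclass
class ReferencePanel:
    """Labelled exemplar domain sequences per group plus full-length AP2
    references (for the single-domain rescue rule) and the Soloist reference."""

    group_exemplars: dict[str, str]  # group -> domain sequence
    ap2_full_refs: dict[str, str]    # ref id -> full-length two-domain protein
    soloist_id: str = "SoloistRef"
    # layout of the full AP2 references: (d1_start, d2_start) 0-based
    ap2_ref_layout: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)

    @property
    def soloist_domain(self) -> str:
        return self.group_exemplars["Soloist"]

    def exemplar_fasta(self) -> dict[str, str]:
        """Headers carry group labels as `id|group`."""
        return {f"{g}-ex|{g}": s for g, s in self.group_exemplars.items()}


def build_reference_panel(models: dict[str, DomainModel], seed: int = 202,
                          flank: int = 40, linker: int = 20) -> ReferencePanel:
    """Sample one exemplar AP2 domain per group from the AP2 model.

    The Soloist exemplar is sampled at an elevated temperature (1.3): of a
    batch of draws, the one scoring nearest 90 bits against the AP2 model
    is kept, so it sits comfortably above any calibrated detection
    threshold yet well below typical group exemplars — the low-conservation
    single-domain outlier a Soloist is. It carries the HLG/LYD element
    variants; the AP2-R2 exemplar carries YLG.
    """
    rng = substream(seed, "panel")
    ap2 = models["AP2"]
    exemplars: dict[str, str] = {}
    for group in DREB_GROUPS + ERF_GROUPS + AP2_GROUPS + ("RAV",):
        exemplars[group] = sample_from_model(ap2, rng)
    from .domains import score_window
    solo_draws = [sample_from_model(ap2, rng, temperature=1.3) for _ in range(30)]
    solo = list(min(solo_draws, key=lambda s: abs(score_window(ap2, s) - 90.0)))
    solo[WLG_POS:WLG_POS + 3] = "HLG"
    solo[AYD_POS:AYD_POS + 3] = "LYD"
    exemplars["Soloist"] = "".join(solo)
    r2 = list(exemplars["AP2-R2"])
    r2[WLG_POS:WLG_POS + 3] = "YLG"
    exemplars["AP2-R2"] = "".join(r2)

    ap2_full, layout = {}, {}
    for group in AP2_GROUPS:
        d2 = sample_from_model(ap2, rng)
        fl1 = random_protein(rng, flank)
        lk = random_protein(rng, linker)
        fl2 = random_protein(rng, flank)
        ap2_full[f"{group}-ref"] = fl1 + exemplars[group] + lk + d2 + fl2
        layout[f"{group}-ref"] = (flank, flank + AP2_LEN + linker)
    return ReferencePanel(group_exemplars=exemplars, ap2_full_refs=ap2_full,
                          ap2_ref_layout=layout)


# ---------------------------------------------------------------------------
# proteome generation


def _expand_census(n_per_family: dict[str, int]) -> dict[str, int]:
    """Family-level counts expanded round-robin to group-level counts;
    group-level keys pass through."""
    out: dict[str, int] = {}
    for key, n in n_per_family.items():
        if n < 0:
            raise ValueError(f"negative count for {key}")
        if key in ALL_GROUPS:
            out[key] = out.get(key, 0) + n
        elif key == "ERF":
            dreb = round(n * DEFAULT_DREB_TOTAL / (DEFAULT_DREB_TOTAL + DEFAULT_ERFSUB_TOTAL))
            for i, g in enumerate(DREB_GROUPS):
                out[g] = out.get(g, 0) + dreb // 6 + (1 if i < dreb % 6 else 0)
            erfs = n - dreb
            for i, g in enumerate(ERF_GROUPS):
                out[g] = out.get(g, 0) + erfs // 6 + (1 if i < erfs % 6 else 0)
        elif key == "AP2":
            out["AP2-R1"] = out.get("AP2-R1", 0) + (n + 1) // 2
            out["AP2-R2"] = out.get("AP2-R2", 0) + n // 2
        elif key in ("RAV", "Soloist"):
            out[key] = out.get(key, 0) + n
        else:
            raise ValueError(f"unknown family/group key {key!r}")
    return out


def _family_of_group(group: str) -> str:
    if group.startswith("DREB-") or group.startswith("ERF-"):
        return "ERF"
    if group.startswith("AP2-"):
        return "AP2"
    return group


def generate_proteome(
    n_per_family: dict[str, int] | None = None,
    models: dict[str, DomainModel] | None = None,
    background_len: tuple[int, int] = (30, 90),
    seed: int = 0,
    divergence: float = 0.10,
    rescue_count: int | None = None,
    panel: ReferencePanel | None = None,
    id_prefix: str = "Br",
) -> tuple[dict[str, str], SyntheticTruth, ReferencePanel]:
    """Emit a proteome with planted architectures and its ground truth.

    Single-AP2 genes (ERF/DREB groups) carry one domain derived from their
    group exemplar at the stated divergence; AP2-family genes are diverged
    copies of a two-domain full-length reference (`rescue_count` of them
    with the second domain excised); RAV genes carry one AP2 plus one B3
    domain; the Soloist is a lightly diverged copy of the divergent Soloist
    reference. Inter-domain and flanking residues are background draws.
    """
    if models is None:
        models = default_models()
    if not models:
        raise ValueError("empty model set")
    if n_per_family is None:
        n_per_family = dict(DEFAULT_CENSUS)
    counts = _expand_census(n_per_family)
    if panel is None:
        panel = build_reference_panel(models, seed=substream(seed, "panel-seed").integers(2**31))
    if rescue_count is None:
        n_ap2 = counts.get("AP2-R1", 0) + counts.get("AP2-R2", 0)
        rescue_count = min(DEFAULT_RESCUE_COUNT, n_ap2) if n_ap2 >= DEFAULT_CENSUS["AP2"] else 0

    rng = substream(seed, "proteome")
    proteome: dict[str, str] = {}
    truth = SyntheticTruth(architectures={}, family_labels={}, group_labels={},
                           rng_seed=seed)
    idents = 1.0 - divergence
    counter = 1
    ap2_made = 0

    def flank() -> str:
        return random_protein(rng, int(rng.integers(background_len[0], background_len[1] + 1)))

    for group in ALL_GROUPS:
        for _ in range(counts.get(group, 0)):
            gid = f"{id_prefix}{counter:03d}"
            counter += 1
            fam = _family_of_group(group)
            if fam == "ERF" and group != "Soloist":
                dom = mutate_copy(panel.group_exemplars[group], idents, rng)
                fl1, fl2 = flank(), flank()
                proteome[gid] = fl1 + dom + fl2
                arch = [("AP2", len(fl1) + 1, len(fl1) + AP2_LEN)]
            elif fam == "AP2":
                ref_id = f"{group}-ref"
                full = mutate_copy(panel.ap2_full_refs[ref_id], idents, rng)
                d1s, d2s = panel.ap2_ref_layout[ref_id]
                ap2_made += 1
                if ap2_made <= rescue_count:
                    # single-domain AP2 gene: second domain excised
                    full = full[:d2s] + full[d2s + AP2_LEN:]
                    arch = [("AP2", d1s + 1, d1s + AP2_LEN)]
                else:
                    arch = [("AP2", d1s + 1, d1s + AP2_LEN),
                            ("AP2", d2s + 1, d2s + AP2_LEN)]
                proteome[gid] = full
            elif group == "RAV":
                ap2_dom = mutate_copy(panel.group_exemplars["RAV"], idents, rng)
                b3_dom = mutate_copy(models["B3"].consensus, idents, rng) \
                    if "B3" in models else None
                if b3_dom is None:
                    raise ValueError("model set must contain B3 to generate RAV genes")
                fl1, lk, fl2 = flank(), random_protein(rng, 15), flank()
                proteome[gid] = fl1 + ap2_dom + lk + b3_dom + fl2
                a1 = len(fl1)
                a2 = a1 + AP2_LEN + len(lk)
                arch = [("AP2", a1 + 1, a1 + AP2_LEN), ("B3", a2 + 1, a2 + B3_LEN)]
            else:  # Soloist
                dom = mutate_copy(panel.soloist_domain, 0.95, rng)
                fl1, fl2 = flank(), flank()
                proteome[gid] = fl1 + dom + fl2
                arch = [("AP2", len(fl1) + 1, len(fl1) + AP2_LEN)]
            truth.architectures[gid] = arch
            truth.family_labels[gid] = fam
            truth.group_labels[gid] = group
    return proteome, truth, panel


def plant_intraspecies_pairs(
    proteome: dict[str, str],
    truth: SyntheticTruth,
    n_pairs: int,
    identity_range: tuple[float, float],
    seed: int = 0,
    stream: str = "duplicates",
    exclude: set[str] | None = None,
) -> list[tuple[str, str, float]]:
    """Overwrite `n_pairs` genes with near-copies of a same-group partner at
    planted identities, creating known within-species homolog pairs.

    The copied gene keeps its id but inherits the partner's sequence,
    architecture and labels (substitutions only, so domain intervals carry
    over). Pairs are drawn from the single-AP2 DREB/ERF groups — where
    surveyed duplications actually concentrate — which also keeps the
    stacked divergence away from the AP2 single-domain rescue rule.
    Returns [(source_id, copy_id, identity), ...]."""
    rng = substream(seed, stream)
    by_group: dict[str, list[str]] = {}
    for gid, grp in sorted(truth.group_labels.items()):
        if grp in DREB_GROUPS + ERF_GROUPS:
            by_group.setdefault(grp, []).append(gid)
    eligible_groups = [g for g in sorted(by_group) if len(by_group[g]) >= 2]
    pairs: list[tuple[str, str, float]] = []
    used: set[str] = set(exclude or ())
    gi = 0
    while len(pairs) < n_pairs and gi < 10 * n_pairs:
        grp = eligible_groups[gi % len(eligible_groups)]
        gi += 1
        pool = [g for g in by_group[grp] if g not in used]
        if len(pool) < 2:
            continue
        src, dst = (str(x) for x in rng.choice(pool, size=2, replace=False))
        ident = float(rng.uniform(*identity_range))
        proteome[dst] = mutate_copy(proteome[src], ident, rng)
        truth.architectures[dst] = list(truth.architectures[src])
        used.update((src, dst))
        pairs.append((src, dst, ident))
    return pairs


def generate_ortholog_set(
    proteome: dict[str, str],
    n_pairs: int,
    identity_range: tuple[float, float] = (0.78, 0.95),
    seed: int = 0,
    id_prefix: str = "At",
) -> tuple[dict[str, str], list[tuple[str, str, float]]]:
    """A diverged second species: `n_pairs` genes get a partner produced by
    mutate_copy at a planted identity drawn from `identity_range`."""
    if n_pairs > len(proteome):
        raise ValueError("more pairs requested than genes available")
    rng = substream(seed, "orthologs")
    chosen = sorted(str(x) for x in
                    rng.choice(sorted(proteome), size=n_pairs, replace=False))
    species_b, pairs = {}, []
    for i, gid in enumerate(chosen, 1):
        ident = float(rng.uniform(*identity_range))
        bid = f"{id_prefix}{i:03d}"
        species_b[bid] = mutate_copy(proteome[gid], ident, rng)
        pairs.append((gid, bid, ident))
    return species_b, pairs


# ---------------------------------------------------------------------------
# genome layout


def generate_genome_layout(
    gene_ids: list[str],
    n_chromosomes: int = 10,
    cluster_spec: list[list[str]] | None = None,
    seed: int = 0,
    n_scaffold: int = 0,
    gene_len: tuple[int, int] = (900, 3000),
    intra_cluster_gap: tuple[int, int] = (5_000, 20_000),
    inter_gene_gap: tuple[int, int] = (150_000, 400_000),
) -> tuple[list[GeneLocus], list[list[str]]]:
    """Assign chromosomes, strands and non-overlapping coordinates.

    Planted clusters are placed as consecutive genes with intra-cluster gaps
    far below the inter-gene spacing, so they are the only runs satisfying a
    physical-proximity rule; `n_scaffold` genes are left unanchored."""
    cluster_spec = cluster_spec or []
    clustered = [g for c in cluster_spec for g in c]
    if len(set(clustered)) != len(clustered):
        raise ValueError("gene appears in more than one planted cluster")
    missing = set(clustered) - set(gene_ids)
    if missing:
        raise ValueError(f"cluster members not in gene_ids: {sorted(missing)[:3]}")
    rng = substream(seed, "layout")
    singles = [g for g in gene_ids if g not in set(clustered)]
    rng.shuffle(singles)
    scaffold_genes = singles[:n_scaffold]
    singles = singles[n_scaffold:]

    # units: each planted cluster is one placement unit, each single its own
    units: list[list[str]] = [list(c) for c in cluster_spec] + [[g] for g in singles]
    order = rng.permutation(len(units))
    chrom_units: dict[int, list[list[str]]] = {i: [] for i in range(n_chromosomes)}
    for k, ui in enumerate(order):
        chrom_units[k % n_chromosomes].append(units[ui])

    loci: list[GeneLocus] = []
    for ci in range(n_chromosomes):
        pos = int(rng.integers(30_000, 80_000))
        chrom = f"A{ci + 1:02d}"
        for unit in chrom_units[ci]:
            for j, gid in enumerate(unit):
                if j > 0:
                    pos += int(rng.integers(*intra_cluster_gap))
                length = int(rng.integers(*gene_len))
                strand = "+" if rng.random() < 0.5 else "-"
                loci.append(GeneLocus(gid, chrom, pos, pos + length - 1, strand))
                pos += length
            pos += int(rng.integers(*inter_gene_gap))
    pos = 1000
    for gid in scaffold_genes:
        length = int(rng.integers(*gene_len))
        loci.append(GeneLocus(gid, "scaffold", pos, pos + length - 1, "+"))
        pos += length + 10_000
    return loci, [list(c) for c in cluster_spec]


def default_cluster_spec(truth: SyntheticTruth, seed: int = 0) -> list[list[str]]:
    """Tandem-cluster plan mirroring a realistic survey: ten runs of sizes
    5/3/3/3/3/3/2/2/2/2 drawn from single-AP2 groups with enough members."""
    sizes = [5, 3, 3, 3, 3, 3, 2, 2, 2, 2]
    rng = substream(seed, "cluster-spec")
    by_group: dict[str, list[str]] = {}
    for gid, grp in truth.group_labels.items():
        if grp in DREB_GROUPS + ERF_GROUPS:
            by_group.setdefault(grp, []).append(gid)
    groups = sorted(g for g, members in by_group.items() if len(members) >= 2)
    if not groups:
        return []
    spec, used = [], set()
    for i, size in enumerate(sizes):
        grp = groups[i % len(groups)]
        pool = [g for g in by_group[grp] if g not in used]
        size = min(size, len(pool))
        if size < 2:
            continue
        members = sorted(str(x) for x in rng.choice(pool, size=size, replace=False))
        used.update(members)
        spec.append(members)
    return spec


# ---------------------------------------------------------------------------
# CDS and EST libraries


def generate_cds(gene_ids: list[str], length_range: tuple[int, int] = (600, 1500),
                 seed: int = 0) -> dict[str, str]:
    """Independent random DNA per gene (codon structure is a non-goal; the
    EST mapper only needs gene-distinct sequence)."""
    rng = substream(seed, "cds")
    return {g: random_dna(rng, int(rng.integers(*length_range))) for g in gene_ids}


def make_expression_design(gene_ids: list[str], expressed_fraction: float = 0.6,
                           mean_range: tuple[float, float] = (5.0, 50.0),
                           seed: int = 0) -> pd.DataFrame:
    """Per-gene expected EST counts over the six tissues: a random fraction
    of genes is expressed, each in a random non-empty tissue subset with
    log-uniform means."""
    rng = substream(seed, "design")
    rows = {}
    for g in gene_ids:
        means = np.zeros(6)
        if rng.random() < expressed_fraction:
            k = int(rng.integers(1, 7))
            tissues = rng.choice(6, size=k, replace=False)
            lo, hi = np.log(mean_range[0]), np.log(mean_range[1])
            means[tissues] = np.exp(rng.uniform(lo, hi, size=k))
        rows[g] = means
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TISSUES))


def generate_est_library(
    expression_means: pd.DataFrame,
    cds: dict[str, str],
    read_len: tuple[int, int] = (150, 400),
    error_rate: float = 0.01,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Per gene and tissue, a negative-binomial count of reads emitted as
    contiguous CDS substrings with per-base substitution errors.

    Returns (EST FASTA dict, read -> tissue manifest, realized counts)."""
    if error_rate >= 0.1:
        raise ValueError("error_rate must be < 0.1")
    if list(expression_means.columns) != list(TISSUES):
        raise ValueError(f"tissue set must be exactly {TISSUES}")
    missing = [g for g in expression_means.index if g not in cds]
    if missing:
        raise ValueError(f"genes without CDS: {missing[:3]}")
    rng = substream(seed, "est")
    ests: dict[str, str] = {}
    manifest: dict[str, str] = {}
    realized = pd.DataFrame(0, index=expression_means.index, columns=list(TISSUES))
    counter = 1
    bases = np.array(list(DNA))
    for gid, row in expression_means.iterrows():
        seq = cds[gid]
        for tissue, mean in zip(TISSUES, row):
            if mean <= 0:
                continue
            r = 1.0 / dispersion
            count = int(rng.negative_binomial(r, r / (r + mean)))
            realized.loc[gid, tissue] = count
            for _ in range(count):
                rl = min(int(rng.integers(read_len[0], read_len[1] + 1)), len(seq))
                start = int(rng.integers(0, len(seq) - rl + 1))
                read = list(seq[start:start + rl])
                if error_rate > 0:
                    errs = np.flatnonzero(rng.random(rl) < error_rate)
                    for p in errs:
                        alternatives = [b for b in DNA if b != read[p]]
                        read[p] = alternatives[rng.integers(3)]
                rid = f"E{counter:07d}"
                counter += 1
                ests[rid] = "".join(read)
                manifest[rid] = tissue
    return ests, manifest, realized


def make_two_block_design(n_per_block: int = 6, hi: float = 60.0, lo: float = 2.0,
                          seed: int = 0) -> pd.DataFrame:
    """Two gene blocks with opposed tissue preference (root-high vs
    seed-high) for testing dendrogram partition recovery."""
    rng = substream(seed, "two-block")
    rows = {}
    for i in range(n_per_block):
        m = np.full(6, lo) + rng.uniform(0, 1, 6)
        m[TISSUES.index("root")] = hi + rng.uniform(0, 10)
        rows[f"R{i + 1:02d}"] = m
    for i in range(n_per_block):
        m = np.full(6, lo) + rng.uniform(0, 1, 6)
        m[TISSUES.index("seed")] = hi + rng.uniform(0, 10)
        rows[f"S{i + 1:02d}"] = m
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TISSUES))


# ---------------------------------------------------------------------------
# alignment fixtures for the motif stage


def make_block_alignment(n_seqs: int, block_len: int, conservation: float = 0.95,
                         flank: tuple[int, int] = (12, 12), seed: int = 0,
                         ) -> tuple[dict[str, str], int]:
    """Gapless alignment with one conserved block of `block_len` columns,
    flanked by random columns. Within the block, each column has exactly
    round((1 - conservation) * n_seqs) deviant sequences, so the per-column
    modal-residue frequency is `conservation` by construction.
    Returns (alignment, 0-based block start column)."""
    rng = substream(seed, "block-aln")
    core = random_protein(rng, block_len)
    n_dev = int(round((1.0 - conservation) * n_seqs))
    rows = [list(random_protein(rng, flank[0] + block_len + flank[1]))
            for _ in range(n_seqs)]
    for p in range(block_len):
        col = flank[0] + p
        deviants = set(rng.choice(n_seqs, size=n_dev, replace=False))
        for i in range(n_seqs):
            if i in deviants:
                alternatives = [a for a in AMINO_ACIDS if a != core[p]]
                rows[i][col] = alternatives[rng.integers(19)]
            else:
                rows[i][col] = core[p]
    aln = {f"s{i + 1:02d}": "".join(rows[i]) for i in range(n_seqs)}
    return aln, flank[0]
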