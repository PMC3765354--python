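"""End-to-end survey: generate (or load) inputs, run every stage, emit a
report bundle.

Stages communicate only through serialized outputs written to the bundle
directory, so any stage can be re-run from the previous stage's files. All
randomness flows from the single config seed through named substreams; a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json

import pandas as pd

from . import classify as _classify
from . import domains as _domains
from . import expression as _expression
from . import genome as _genome
from . import homology as _homology
from . import motifs as _motifs
from . import phylogeny as _phylogeny
from . import synthetic as _synthetic
from ._util import substream
from .config import SurveyConfig
from .io import ensure_dir, write_fasta, write_locus_tsv, write_manifest, write_tsv

__version__ = "0.1.0"


@dataclasses.dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, with ground truth attached."""

    models: dict
    panel: _synthetic.ReferencePanel
    proteome: dict[str, str]
    truth: _synthetic.SyntheticTruth
    species_b: dict[str, str]
    duplicate_pairs: list
    paralog_pairs: list
    loci: list
    loci_b: list
    cds: dict[str, str]
    ests: dict[str, str]
    manifest: dict[str, str]
    realized_counts: pd.DataFrame


def build_bundle(config: SurveyConfig) -> SyntheticBundle:
    """Generate the full synthetic input set defined by the config."""
    seed = config.seed
    sc = config.synth
    models = _synthetic.default_models(
        diversity=sc.model_diversity,
        seed=int(substream(seed, "models").integers(2**31)))
    for m in models.values():
        _domains.calibrate_threshold(
            m, n_decoys=config.scan_n_decoys, target_evalue=config.scan_evalue,
            database_size=config.scan_database_size,
            seed=int(substream(seed, "calibration", m.name).integers(2**31)))
    panel = _synthetic.build_reference_panel(
        models, seed=int(substream(seed, "panel").integers(2**31)))
    proteome, truth, panel = _synthetic.generate_proteome(
        n_per_family=dict(sc.census), models=models, seed=seed,
        divergence=sc.divergence, panel=panel)
    dup_pairs = _synthetic.plant_intraspecies_pairs(
        proteome, truth, sc.n_duplicate_pairs, (0.96, 1.0), seed=seed,
        stream="duplicates")
    par_pairs = _synthetic.plant_intraspecies_pairs(
        proteome, truth, sc.n_paralog_pairs, (0.83, 0.93), seed=seed,
        stream="paralogs", exclude={g for p in dup_pairs for g in p[:2]})
    species_b, ortho_pairs = _synthetic.generate_ortholog_set(
        proteome, min(sc.n_ortholog_pairs, len(proteome)),
        identity_range=sc.ortholog_identity_range, seed=seed)
    truth.ortholog_pairs = ortho_pairs
    cluster_spec = _synthetic.default_cluster_spec(truth, seed=seed)
    loci, clusters = _synthetic.generate_genome_layout(
        sorted(proteome), n_chromosomes=sc.n_chromosomes,
        cluster_spec=cluster_spec, seed=seed, n_scaffold=sc.n_scaffold)
    truth.tandem_clusters = clusters
    loci_b, _ = _synthetic.generate_genome_layout(
        sorted(species_b), n_chromosomes=5, seed=seed + 1)
    cds = _synthetic.generate_cds(sorted(proteome), seed=seed)
    design = _synthetic.make_expression_design(
        sorted(proteome), expressed_fraction=sc.expressed_fraction,
        mean_range=sc.expression_mean_range, seed=seed)
    truth.expression_means = design
    ests, manifest, realized = _synthetic.generate_est_library(
        design, cds, error_rate=sc.est_error_rate,
        dispersion=sc.est_dispersion, seed=seed)
    return SyntheticBundle(models=models, panel=panel, proteome=proteome,
                           truth=truth, species_b=species_b,
                           duplicate_pairs=dup_pairs, paralog_pairs=par_pairs,
                           loci=loci, loci_b=loci_b, cds=cds, ests=ests,
                           manifest=manifest, realized_counts=realized)


def write_inputs(bundle: SyntheticBundle, out_dir) -> None:
    """Serialize every generated input (plus truth) for re-runnability."""
    out = ensure_dir(out_dir)
    write_fasta(bundle.proteome, out / "proteome.faa")
    write_fasta(bundle.species_b, out / "species_b.faa")
    write_fasta(bundle.panel.exemplar_fasta(), out / "panel.faa")
    write_fasta(bundle.cds, out / "cds.fna")
    write_fasta(bundle.ests, out / "ests.fna")
    write_manifest(bundle.manifest, out / "manifest.tsv")
    write_locus_tsv(bundle.loci, out / "loci.tsv")
    write_locus_tsv(bundle.loci_b, out / "loci_b.tsv")
    bundle.truth.to_json(out / "truth.json")
    for m in bundle.models.values():
        m.write(out / f"model_{m.name}.txt")


def run_survey(config: SurveyConfig, out_dir,
               bundle: SyntheticBundle | None = None) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = ensure_dir(out_dir)
    if bundle is None:
        bundle = build_bundle(config)
    write_inputs(bundle, out)

    # ---- scan
    hits = _domains.scan_proteome(bundle.proteome, bundle.models.values())
    hit_rows = [(h.protein_id, h.domain_name, h.start, h.end,
                 round(h.bit_score, 3), f"{h.evalue_surrogate:.3e}")
                for pid in sorted(hits) for h in hits[pid]]
    write_tsv(pd.DataFrame(hit_rows, columns=[
        "protein_id", "domain", "start", "end", "bits", "evalue"]),
        out / "scan.tsv")

    # ---- classify
    calls = _classify.classify_proteome(
        bundle.proteome, hits, bundle.panel,
        rescue_identity=config.rescue_identity,
        soloist_floor=config.soloist_floor, group_floor=config.group_floor)
    write_tsv(pd.DataFrame(
        [(c.gene_id, c.family, c.subfamily, c.group, c.evidence) for c in calls],
        columns=["gene_id", "family", "subfamily", "group", "evidence"]),
        out / "calls.tsv")
    census = _classify.census(calls)
    write_tsv(census, out / "census.tsv")

    # ---- homology
    orthologs = _homology.find_orthologs(
        bundle.proteome, bundle.species_b,
        min_identity=config.ortholog_identity, max_e=config.ortholog_evalue)
    paralogs = _homology.find_paralogs(
        bundle.proteome, min_identity=config.paralog_identity,
        max_e=config.ortholog_evalue)
    duplicates = _homology.find_duplicates(
        bundle.proteome, min_identity=config.duplicate_identity,
        max_e=config.ortholog_evalue)
    for name, pairs in (("orthologs", orthologs), ("paralogs", paralogs),
                        ("duplicates", duplicates)):
        write_tsv(pd.DataFrame(
            [(p.idA, p.idB, p.relation, round(p.identity, 2),
              f"{p.evalue_surrogate:.3e}") for p in pairs],
            columns=["idA", "idB", "relation", "identity", "evalue"]),
            out / f"{name}.tsv")

    # ---- phylogeny: AP2-domain alignment of sampled genes per group
    aln = _domain_alignment(bundle, config)
    if len(aln) >= 4:
        tree, supports = _phylogeny.bootstrap_support(
            aln, n_replicates=config.bootstrap_replicates,
            seed=int(substream(config.seed, "bootstrap").integers(2**31)))
        _phylogeny.write_newick(tree, out / "tree.nwk")
        sup_rows = [(";".join(sorted(p)), s, s <= config.bootstrap_display_floor)
                    for p, s in sorted(supports.items(),
                                       key=lambda kv: sorted(kv[0]))]
        write_tsv(pd.DataFrame(sup_rows,
                               columns=["bipartition", "support", "below_floor"]),
                  out / "supports.tsv")

    # ---- motifs per family alignment
    motif_rows = []
    for family, fam_aln in _family_alignments(bundle).items():
        if len(fam_aln) < 2:
            continue
        profile = _motifs.column_conservation(fam_aln, family)
        try:
            block = _motifs.conserved_block(
                profile, fam_aln, score_threshold=config.motif_score_threshold,
                max_gap_fraction=config.motif_max_gap_fraction)
            motif_rows.append((family, block.start + 1, block.length,
                               block.consensus,
                               round(block.mean_conservation, 4)))
        except _motifs.EmptyBlockError:
            motif_rows.append((family, 0, 0, "", 0.0))
    write_tsv(pd.DataFrame(motif_rows, columns=[
        "family", "start", "length", "consensus", "mean_conservation"]),
        out / "motifs.tsv")

    # ---- genome map
    dist = _genome.distribution_table(calls, bundle.loci)
    dist.table.reset_index().to_csv(out / "distribution.tsv", sep="\t", index=False)
    group_by_gene = {c.gene_id: c.group for c in calls
                     if c.group not in ("unassigned",)}
    clusters = _genome.tandem_clusters(
        bundle.loci, group_by_gene,
        max_intervening=config.cluster_max_intervening,
        max_span_kb=config.cluster_max_span_kb)
    write_tsv(pd.DataFrame(
        [(i + 1, len(c), ";".join(c)) for i, c in enumerate(clusters)],
        columns=["cluster", "size", "members"]), out / "clusters.tsv")
    links = _genome.synteny_links(orthologs, bundle.loci, bundle.loci_b)
    write_tsv(links, out / "links.tsv")

    # ---- expression
    assignments, _eligible = _expression.map_cds_to_ests(
        bundle.cds, bundle.ests, bundle.manifest,
        min_identity=config.est_identity, max_e=config.est_evalue,
        min_overlap_bp=config.est_min_overlap_bp)
    profiles = _expression.tissue_counts(assignments, bundle.manifest,
                                         all_genes=sorted(bundle.proteome))
    profiles.reset_index().to_csv(out / "profiles.tsv", sep="\t", index=False)
    totals = _expression.tissue_totals(profiles)
    write_tsv(totals, out / "tissue_totals.tsv")
    family_by_gene = {c.gene_id: (c.subfamily if c.family == "ERF" else c.family)
                      for c in calls if c.family != "none"}
    subsets, family_table = _expression.sharing_table(profiles, family_by_gene)
    write_tsv(subsets, out / "sharing.tsv")
    if family_table is not None:
        write_tsv(family_table, out / "expression_families.tsv")
    expr = _expression.expressed(profiles)
    if len(expr) >= 2:
        clust = _expression.cluster_profiles(expr)
        (out / "expression_dendrogram.nwk").write_text(clust.newick + "\n")
        write_tsv(expr.loc[clust.leaf_order].reset_index(),
                  out / "expression_ordered.tsv")

    # ---- summary + provenance
    summary = {
        "n_genes": len(bundle.proteome),
        "census": {r.name: int(r.count) for r in census.itertuples()
                   if r.level == "family"},
        "subfamilies": {r.name: int(r.count) for r in census.itertuples()
                        if r.level == "subfamily"},
        "total_classified": int(census.loc[
            (census.level == "total") & (census.name == "classified"), "count"
        ].iloc[0]),
        "n_orthologs": len(orthologs),
        "n_paralogs": len(paralogs),
        "n_duplicate_rows": len(duplicates),
        "placed_genes": int(dist.table.loc["Total", "Total"]),
        "n_tandem_clusters": len(clusters),
        "n_expressed_genes": int((profiles.sum(axis=1) > 0).sum()),
        "assigned_ests": len(assignments),
        "tissue_totals": {t: int(n) for t, n in
                          zip(totals.tissue, totals.total)},
        "provenance": {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "erfkit_version": __version__,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return summary


def _domain_alignment(bundle: SyntheticBundle, config: SurveyConfig) -> dict[str, str]:
    """Gapless AP2-domain alignment: group exemplars plus a per-group gene
    sample (planted domains share the model length, so columns align)."""
    truth = bundle.truth
    aln = {f"{g}|ref": s for g, s in sorted(bundle.panel.group_exemplars.items())}
    per_group: dict[str, list[str]] = {}
    for gid in sorted(truth.group_labels):
        per_group.setdefault(truth.group_labels[gid], []).append(gid)
    for group in sorted(per_group):
        for gid in per_group[group][:config.synth.taxa_per_group]:
            arch = [a for a in truth.architectures[gid] if a[0] == "AP2"]
            if arch:
                _, s, e = arch[0]
                aln[gid] = bundle.proteome[gid][s - 1:e]
    return aln


def _family_alignments(bundle: SyntheticBundle) -> dict[str, dict[str, str]]:
    """Per-family gapless AP2-domain alignments from the planted intervals."""
    out: dict[str, dict[str, str]] = {}
    for gid, fam in sorted(bundle.truth.family_labels.items()):
        arch = [a for a in bundle.truth.architectures[gid] if a[0] == "AP2"]
        if not arch:
            continue
        _, s, e = arch[0]
        out.setdefault(fam, {})[gid] = bundle.proteome[gid][s - 1:e]
    return out
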