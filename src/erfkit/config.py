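"""Single configuration object holding every numeric gate in the survey.

All thresholds the pipeline compares against live here, with the
conventional printed defaults (domain scan E 1e-4; EST eligibility E 1e-5
at 90% identity; orthologs E 1e-10 at 75%; paralogs 80%; duplicates 95%;
1000 bootstrap replicates with a 50% display floor). Identity comparisons
are inclusive (>=) throughout the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

#: Roman-numeral clade labels mapped onto the group naming used in outputs
#: (I-VI: ERF subfamily; VII-XII: DREB; XIII AP2, XIV RAV, XV Soloist).
GROUP_ROMAN_MAP = {
    "I": "ERF-B1", "II": "ERF-B2", "III": "ERF-B3", "IV": "ERF-B4",
    "V": "ERF-B5", "VI": "ERF-B6",
    "VII": "DREB-A1", "VIII": "DREB-A2", "IX": "DREB-A3", "X": "DREB-A4",
    "XI": "DREB-A5", "XII": "DREB-A6",
    "XIII": "AP2", "XIV": "RAV", "XV": "Soloist",
}


@dataclasses.dataclass
class SynthScale:
    """Scale of the synthetic bundle the `survey` command generates."""

    census: dict = dataclasses.field(
        default_factory=lambda: {"ERF": 248, "AP2": 29, "RAV": 14, "Soloist": 1})
    divergence: float = 0.10
    n_ortholog_pairs: int = 214
    ortholog_identity_range: tuple = (0.78, 0.95)
    n_duplicate_pairs: int = 8
    n_paralog_pairs: int = 12
    n_scaffold: int = 3
    n_chromosomes: int = 10
    expressed_fraction: float = 0.6
    expression_mean_range: tuple = (5.0, 50.0)
    est_error_rate: float = 0.01
    est_dispersion: float = 0.3
    taxa_per_group: int = 2
    model_diversity: float = 20.0


@dataclasses.dataclass
class SurveyConfig:
    seed: int = 0
    # domain scan
    scan_evalue: float = 1e-4
    scan_database_size: int = 100_000
    scan_n_decoys: int = 10_000
    # classification
    rescue_identity: float = 60.0
    soloist_floor: float = 50.0
    group_floor: float = 40.0
    # homology gates
    ortholog_identity: float = 75.0
    ortholog_evalue: float = 1e-10
    paralog_identity: float = 80.0
    duplicate_identity: float = 95.0
    # phylogeny
    bootstrap_replicates: int = 1000
    bootstrap_display_floor: int = 50
    # motifs
    motif_score_threshold: float = 0.8
    motif_max_gap_fraction: float = 0.2
    # genome map
    cluster_max_intervening: int = 1
    cluster_max_span_kb: float = 100.0
    # expression
    est_identity: float = 90.0
    est_evalue: float = 1e-5
    est_min_overlap_bp: int = 100
    # rounding precisions (decimal places, round half up)
    subset_pct_dp: int = 2
    family_pct_dp: int = 1
    synth: SynthScale = dataclasses.field(default_factory=SynthScale)

    def __post_init__(self):
        if isinstance(self.synth, dict):
            self.synth = SynthScale(**self.synth)
        checks = [
            (0 < self.scan_evalue <= 1, "scan_evalue in (0, 1]"),
            (0 < self.est_evalue <= 1, "est_evalue in (0, 1]"),
            (0 < self.ortholog_evalue <= 1, "ortholog_evalue in (0, 1]"),
            (0 <= self.rescue_identity <= 100, "rescue_identity in [0, 100]"),
            (0 <= self.group_floor <= 100, "group_floor in [0, 100]"),
            (0 <= self.ortholog_identity <= 100, "ortholog_identity in [0, 100]"),
            (0 <= self.paralog_identity <= 100, "paralog_identity in [0, 100]"),
            (0 <= self.duplicate_identity <= 100, "duplicate_identity in [0, 100]"),
            (self.bootstrap_replicates >= 1, "bootstrap_replicates >= 1"),
            (0 <= self.motif_score_threshold <= 1, "motif_score_threshold in [0, 1]"),
            (self.cluster_max_intervening >= 0, "cluster_max_intervening >= 0"),
            (0 <= int(self.seed) < 2**31, "seed in [0, 2^31)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config out of range: {msg}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["ortholog_identity_range"] = list(self.synth.ortholog_identity_range)
        d["synth"]["expression_mean_range"] = list(self.synth.expression_mean_range)
        d["group_roman_map"] = dict(GROUP_ROMAN_MAP)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SurveyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("group_roman_map", None)
        synth = d.pop("synth", {})
        for key in ("ortholog_identity_range", "expression_mean_range"):
            if key in synth:
                synth[key] = tuple(synth[key])
        return cls(synth=SynthScale(**synth), **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
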