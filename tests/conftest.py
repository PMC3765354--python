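"""Shared fixtures: calibrated domain models and a small classified bundle."""

import numpy as np
import pytest

from erfkit import classify as cls
from erfkit import domains as dom
from erfkit import synthetic as syn

SMALL_CENSUS = {"ERF": 24, "AP2": 6, "RAV": 3, "Soloist": 1}


@pytest.fixture(scope="session")
def models():
    ms = syn.default_models()
    for m in ms.values():
        dom.calibrate_threshold(m, n_decoys=5000, seed=11)
    return ms


@pytest.fixture(scope="session")
def small_bundle(models):
    """34-gene proteome with scan hits, panel and truth (divergence 10%)."""
    proteome, truth, panel = syn.generate_proteome(
        dict(SMALL_CENSUS), models=models, seed=3, rescue_count=2)
    hits = dom.scan_proteome(proteome, models.values())
    return {"proteome": proteome, "truth": truth, "panel": panel,
            "hits": hits, "models": models}


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    return cls.classify_proteome(small_bundle["proteome"],
                                 small_bundle["hits"],
                                 small_bundle["panel"])


def hit_covers(hit, interval, min_overlap_frac=0.8) -> bool:
    name, s, e = interval
    if hit.domain_name != name:
        return False
    ov = max(0, min(e, hit.end) - max(s, hit.start) + 1)
    return ov >= min_overlap_frac * (e - s + 1)
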