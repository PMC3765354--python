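"""Empirical score-tail calibration shared by the scan and homology stages.

All E-value-like quantities in the package are surrogates: an exponential
tail is fitted to scores of shuffled/random decoys (peaks-over-threshold,
mean-excess estimator for the scale), and the expected decoy count in a
search space of a stated size plays the role BLAST's Karlin-Altschul E
plays. The fit is empirical and model-agnostic, which keeps the decision
function (hit above/below an E gate) faithful without a BLAST dependency.
"""

from __future__ import annotations

import dataclasses

import numpy as np


class CalibrationError(RuntimeError):
    """Raised when decoy scores carry no usable tail (degenerate model)."""


@dataclasses.dataclass(frozen=True)
class TailFit:
    """Exponential upper-tail fit to decoy scores.

    P(S > s) = p_u * exp(-(s - u) / beta) for s >= u, with u the anchor
    quantile, p_u its empirical exceedance probability, beta the mean excess.
    """

    u: float
    beta: float
    p_u: float
    n_decoys: int

    def tail_prob(self, s: float) -> float:
        if s <= self.u:
            # conservative: cap at the anchor probability below the fit range
            return min(1.0, self.p_u * float(np.exp(-(s - self.u) / self.beta)))
        return self.p_u * float(np.exp(-(s - self.u) / self.beta))

    def score_at_prob(self, p: float) -> float:
        """Invert the tail: the score whose exceedance probability is p."""
        if p <= 0:
            raise ValueError("probability must be positive")
        return self.u + self.beta * float(np.log(self.p_u / p))


def fit_tail(scores: np.ndarray, anchor_quantile: float = 0.95) -> TailFit:
    """Fit an exponential tail to decoy scores above their `anchor_quantile`."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 100:
        raise CalibrationError(f"need >= 100 decoy scores, got {scores.size}")
    if float(np.std(scores)) < 1e-12:
        raise CalibrationError("degenerate decoy score distribution (zero spread)")
    u = float(np.quantile(scores, anchor_quantile))
    exc = scores[scores > u] - u
    if exc.size < 10 or float(np.mean(exc)) < 1e-12:
        raise CalibrationError("empty or degenerate score tail above anchor")
    return TailFit(u=u, beta=float(np.mean(exc)), p_u=exc.size / scores.size,
                   n_decoys=int(scores.size))
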