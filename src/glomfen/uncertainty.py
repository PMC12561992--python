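"""Monte-Carlo uncertainty propagation from the multi-start fit ensemble.

Fits whose SSE lies within 20% of the best SSE form the acceptable subset.
Each parameter is then resampled independently (uniformly, with replacement)
from its values in that subset to build 100 parameter vectors — marginals are
preserved, joint correlations deliberately broken — and the model is rerun
for each vector; 95% equal-tail credible bands come from the 2.5%/97.5%
empirical quantiles of the predictions at each time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import FitResult

__all__ = [
    "acceptable_subset",
    "resample_posterior",
    "credible_interval",
    "PosteriorEnsemble",
    "propagate",
]

SSE_TOLERANCE = 0.2  # fits within 20% of the lowest SSE are acceptable
N_SAMPLES = 100


def acceptable_subset(fits: list[FitResult]) -> list[FitResult]:
    """Converged fits with SSE <= 1.2 * min SSE."""
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to subset")
    best = min(f.sse for f in ok)
    return [f for f in ok if f.sse <= (1.0 + SSE_TOLERANCE) * best]


def resample_posterior(
    subset: list[FitResult], n: int = N_SAMPLES, seed: int = 0
) -> pd.DataFrame:
    """Per-parameter independent uniform resampling (with replacement)."""
    if not subset:
        raise ValueError("empty acceptable subset")
    names = list(subset[0].estimates)
    pools = {k: np.array([f.estimates[k] for f in subset]) for k in names}
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {k: rng.choice(pools[k], size=n, replace=True) for k in names}
    )


def credible_interval(
    predictions: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tail interval from ensemble predictions (n_members, n_time).

    Quantiles use linear interpolation between order statistics.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.ndim == 1:
        predictions = predictions[None, :]
    if predictions.shape[0] < 2:
        raise ValueError("need at least 2 ensemble members")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must lie in (0, 1]")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(predictions, alpha, axis=0)
    hi = np.quantile(predictions, 1.0 - alpha, axis=0)
    return lo, hi


@dataclass
class PosteriorEnsemble:
    """Resampled parameter vectors, their predictions, and credible bands."""

    parameter_samples: pd.DataFrame
    t: np.ndarray
    number: np.ndarray  # (n_samples, n_t)
    diameter: np.ndarray
    level: float = 0.95

    @property
    def n(self) -> int:
        return len(self.parameter_samples)

    def bands(self) -> pd.DataFrame:
        lo_n, hi_n = credible_interval(self.number, self.level)
        lo_d, hi_d = credible_interval(self.diameter, self.level)
        return pd.DataFrame(
            {
                "time_h": np.concatenate([self.t, self.t]),
                "quantity": ["number"] * len(self.t) + ["diameter_nm"] * len(self.t),
                "lo": np.concatenate([lo_n, lo_d]),
                "hi": np.concatenate([hi_n, hi_d]),
                "median": np.concatenate(
                    [np.median(self.number, axis=0), np.median(self.diameter, axis=0)]
                ),
            }
        )


def propagate(
    samples: pd.DataFrame,
    predict_fn,
    level: float = 0.95,
) -> PosteriorEnsemble:
    """Run ``predict_fn(params_row) -> (t, number, diameter)`` per sample."""
    numbers, diameters, t = [], [], None
    for _, row in samples.iterrows():
        t, num, dia = predict_fn(row.to_dict())
        numbers.append(num)
        diameters.append(dia)
    return PosteriorEnsemble(
        parameter_samples=samples,
        t=np.asarray(t),
        number=np.vstack(numbers),
        diameter=np.vstack(diameters),
        level=level,
    )
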