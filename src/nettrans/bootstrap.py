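"""Parametric bootstrap confidence intervals for net transition probabilities.

Spline coefficients are resampled from their asymptotic multivariate normal
distribution (mean = fitted coefficients, covariance = cluster-robust
sandwich).  Each draw is pushed through the inverse-logit map — which keeps
every replicate surface a proper probability surface — and through the
closed-form net-flow map, and percentile intervals are taken per (age,
boundary, direction).  Sampling in coefficient space rather than
probability space is what makes renormalization a no-op rather than a
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prevalence import PrevalenceCurve
from .transport import (
    BOUNDARIES,
    DIRECTIONS,
    CostMatrix,
    net_prob_array,
    net_table_from_curve,
)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    method: str = "percentile"

    def __post_init__(self):
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.method != "percentile":
            raise ValueError(f"unsupported interval method {self.method!r}")
        if self.replicates < 100:
            warnings.warn(
                f"{self.replicates} bootstrap replicates is below the 100 recommended "
                "for reported confidence intervals",
                stacklevel=2,
            )


def psd_sqrt(vcov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric square root of a covariance, repairing tiny negative eigenvalues.

    Eigenvalues below ``-tol * max_eig`` trigger a warning (nearest-PSD
    repair); small negative values from round-off are silently clipped.
    """
    vcov = 0.5 * (vcov + vcov.T)
    if vcov.size == 0:
        return vcov
    vals, vecs = np.linalg.eigh(vcov)
    floor = -tol * max(vals.max(), 1e-300)
    if vals.min() < floor:
        warnings.warn(
            f"covariance not PSD (min eigenvalue {vals.min():.3e}); "
            "projecting to nearest PSD matrix",
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def sample_coefficients(curve: PrevalenceCurve, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Draw coefficient vectors from the curve's asymptotic normal distribution."""
    L = psd_sqrt(curve.vcov)
    z = rng.standard_normal((replicates, L.shape[1] if L.size else 0))
    if L.size == 0:
        return np.tile(curve.coef, (replicates, 1)) if curve.coef.size else np.zeros((replicates, 0))
    return curve.coef + z @ L.T


def bootstrap_surfaces(curve: PrevalenceCurve, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Replicate prevalence surfaces, shape (replicates, n_ages, 3)."""
    if curve.coef.size == 0:  # degenerate stratum: no sampling distribution
        return np.tile(curve.P, (replicates, 1, 1))
    draws = sample_coefficients(curve, replicates, rng)
    return curve.surface(draws)


def bootstrap_nets(
    curve: PrevalenceCurve,
    cost: CostMatrix | None = None,
    cfg: BootstrapConfig | None = None,
) -> pd.DataFrame:
    """Net transition table with percentile bootstrap confidence intervals.

    Point estimates are the plug-in values from the fitted surface (via the
    LP solver); ``ci_low``/``ci_high`` come from ``cfg.replicates`` draws of
    the spline coefficients.  Identical seeds give identical intervals.
    """
    cost = cost or CostMatrix()
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)

    table = net_table_from_curve(curve.ages, curve.P, stratum=curve.stratum, use_lp=True)
    surfaces = bootstrap_surfaces(curve, cfg.replicates, rng)
    # (R, n_ages-1, 2 boundaries, 2 directions); closed-form nets equal the LP nets
    rep_probs = np.stack([net_prob_array(s) for s in surfaces])
    alpha = 1.0 - cfg.ci_level
    lo = np.quantile(rep_probs, alpha / 2, axis=0)
    hi = np.quantile(rep_probs, 1 - alpha / 2, axis=0)

    ci_low = np.empty(len(table))
    ci_high = np.empty(len(table))
    for r, row in enumerate(table.itertuples(index=False)):
        t = int(row.age) - int(curve.ages[0])
        b = BOUNDARIES.index(row.boundary)
        dr = DIRECTIONS.index(row.direction)
        ci_low[r] = lo[t, b, dr]
        ci_high[r] = hi[t, b, dr]
    table["ci_low"] = ci_low
    table["ci_high"] = ci_high
    return table


def prevalence_se(curve: PrevalenceCurve, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap standard error of the prevalence surface, shape (n_ages, 3)."""
    return bootstrap_surfaces(curve, replicates, rng).std(axis=0, ddof=1)
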