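"""Model evaluation: ROC/c-statistic, threshold calibration, NOS profiling.

Covers the performance and clinical-implementation analyses around the
subtyping model:

* the concordance statistic (c-statistic / AUC) and accuracy at a
  probability threshold;
* specificity-targeted dual-threshold calibration — find the tightest
  (theta_luad, theta_lusc) pair such that each confident call reaches a
  required specificity, and report what fraction of samples can then be
  auto-called without pathologist review;
* events-per-variable, the sample-size-per-predictor overfitting guardrail;
* distribution profiling of NOS cases (ECDF, kernel density, two-sample
  Kolmogorov-Smirnov tests against the typical LUAD and LUSC cases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import gaussian_kde, rankdata
from statsmodels.distributions.empirical_distribution import ECDF

from .classify import ThresholdPair

__all__ = [
    "RocResult",
    "KsResult",
    "CalibrationResult",
    "roc_curve",
    "c_statistic",
    "accuracy_at_threshold",
    "calibrate_thresholds",
    "events_per_variable",
    "ks_two_sample",
    "nos_profile",
]


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":  # label strings
        y = (y == "LUAD").astype(float)
    y = y.astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary (1/LUAD vs 0/LUSC)")
    return y


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    c_statistic: float


@dataclass(frozen=True)
class KsResult:
    d_statistic: float
    p_value: float


@dataclass(frozen=True)
class CalibrationResult:
    thresholds: ThresholdPair
    coverage: float
    luad_call_specificity: float
    lusc_call_specificity: float
    luad_feasible: bool
    lusc_feasible: bool


def c_statistic(p, y) -> float:
    """Tie-corrected pairwise concordance probability (the ROC AUC).

    Equals ``(#concordant + 0.5 #tied) / (n_LUAD * n_LUSC)`` over all
    cross-class pairs; computed via the rank-sum (Mann-Whitney) identity,
    with average ranks handling ties.
    """
    p = np.asarray(p, dtype=float)
    y = _as_binary(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(p, y) -> RocResult:
    """Sensitivity/specificity at every observed threshold, plus the AUC."""
    p = np.asarray(p, dtype=float)
    y = _as_binary(y)
    thresholds = np.unique(np.concatenate([[0.0], np.unique(p), [1.0]]))
    sens = np.array([(p[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(p[y == 0] < t).mean() for t in thresholds])
    return RocResult(thresholds, sens, spec, c_statistic(p, y))


def accuracy_at_threshold(p, y, theta: float) -> float:
    """Fraction of samples whose p >= theta call matches the true subtype."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    p = np.asarray(p, dtype=float)
    y = _as_binary(y)
    return float(((p >= theta).astype(float) == y).mean())


def _candidate_grid(p: np.ndarray) -> np.ndarray:
    """Observed probabilities, midpoints between neighbors, and {0, 1}.

    Every achievable (specificity, coverage) operating point is realized at
    one of these values.
    """
    obs = np.unique(p)
    mids = (obs[:-1] + obs[1:]) / 2.0
    return np.unique(np.concatenate([[0.0], obs, mids, [1.0]]))


def calibrate_thresholds(p, y, target_specificity: float) -> CalibrationResult:
    """Tightest dual thresholds reaching a per-call specificity target.

    ``theta_luad`` is the smallest candidate such that the LUAD call
    (p >= theta_luad) has specificity >= target among true-LUSC samples;
    ``theta_lusc`` the largest such that the LUSC call (p <= theta_lusc) has
    specificity >= target among true-LUAD samples. Coverage is the fraction
    of all samples confidently called. If a side has no feasible candidate,
    its extreme threshold (1 or 0) is returned with the feasibility flag
    cleared.
    """
    if not 0.5 < target_specificity <= 1.0:
        raise ValueError("target_specificity must be in (0.5, 1]")
    p = np.asarray(p, dtype=float)
    y = _as_binary(y)
    p_luad, p_lusc = p[y == 1], p[y == 0]
    if len(p_luad) == 0 or len(p_lusc) == 0:
        raise ValueError("both classes must be present")
    grid = _candidate_grid(p)

    luad_ok = np.array([(p_lusc < t).mean() >= target_specificity for t in grid])
    if luad_ok.any():
        theta_luad, luad_feasible = float(grid[luad_ok][0]), True
    else:
        theta_luad, luad_feasible = 1.0, False

    lusc_ok = np.array([(p_luad > t).mean() >= target_specificity for t in grid])
    if lusc_ok.any():
        theta_lusc, lusc_feasible = float(grid[lusc_ok][-1]), True
    else:
        theta_lusc, lusc_feasible = 0.0, False

    # At modest targets the two feasible regions can overlap; every sample in
    # the overlap is confidently callable either way, so the indeterminate
    # zone collapses. Lowering theta_lusc is safe: the LUSC-side feasible set
    # is downward-closed.
    if luad_feasible and lusc_feasible and theta_lusc > theta_luad:
        theta_lusc = theta_luad

    pair = ThresholdPair(theta_luad=theta_luad, theta_lusc=theta_lusc)
    coverage = float(((p >= theta_luad) | (p <= theta_lusc)).mean())
    return CalibrationResult(
        thresholds=pair,
        coverage=coverage,
        luad_call_specificity=float((p_lusc < theta_luad).mean()),
        lusc_call_specificity=float((p_luad > theta_lusc).mean()),
        luad_feasible=luad_feasible,
        lusc_feasible=lusc_feasible,
    )


def events_per_variable(n_samples: int, n_model_genes: int) -> float:
    """Samples per model predictor; values near 5 are the accepted minimum."""
    if n_model_genes < 1:
        raise ValueError("n_model_genes must be >= 1")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    return n_samples / n_model_genes


def ks_two_sample(x1, x2) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the ECDF difference over the pooled sample points;
    the two-sided p-value uses the asymptotic Kolmogorov distribution at
    ``sqrt(n1 n2 / (n1 + n2)) * D``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x1, x2])
    e1, e2 = ECDF(x1), ECDF(x2)
    d = float(np.max(np.abs(e1(pooled) - e2(pooled))))
    ne = len(x1) * len(x2) / (len(x1) + len(x2))
    p = float(kolmogorov(np.sqrt(ne) * d))
    return KsResult(d_statistic=d, p_value=min(max(p, np.finfo(float).tiny), 1.0))


def nos_profile(p_luad, p_lusc, p_nos, grid_size: int = 256) -> dict:
    """Distribution profile of NOS probabilities against the typical subtypes.

    Returns, per group, the ECDF (right-continuous step function evaluated on
    a [0, 1] grid) and a Gaussian kernel density (Silverman bandwidth), plus
    Kolmogorov-Smirnov comparisons of NOS against each typical subtype.
    """
    groups = {"LUAD": np.asarray(p_luad, float), "LUSC": np.asarray(p_lusc, float),
              "NOS": np.asarray(p_nos, float)}
    for name, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {name} is empty")
    grid = np.linspace(0.0, 1.0, grid_size)
    ecdfs = {name: ECDF(v)(grid) for name, v in groups.items()}
    densities = {}
    for name, v in groups.items():
        if len(v) > 1 and np.ptp(v) > 0:
            densities[name] = gaussian_kde(v, bw_method="silverman")(grid)
        else:  # degenerate group: a point mass has no finite density estimate
            densities[name] = np.full_like(grid, np.nan)
    return {
        "grid": grid,
        "ecdf": ecdfs,
        "density": densities,
        "ks_nos_vs_luad": ks_two_sample(groups["NOS"], groups["LUAD"]),
        "ks_nos_vs_lusc": ks_two_sample(groups["NOS"], groups["LUSC"]),
    }
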