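"""Probability prediction and three-way subtype calling.

The classifier is a plain logistic model on normalized profiles:
``logit(p) = beta0 + sum_g beta_g * z_g`` with ``p`` the probability the
sample is LUAD. Calling supports two modes:

* single-threshold (the default reporting rule): LUAD iff ``p >= 0.5``,
  otherwise LUSC;
* dual-threshold for confident clinical calling: LUAD iff ``p >= theta_luad``,
  LUSC iff ``p <= theta_lusc``, and INDETERMINATE in between — those samples
  are referred to pathologist review.

A probability exactly at a confident threshold yields the confident call,
mirroring the closed ``>=`` convention of the default rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .normalize import NormalizedMatrix
from .panel_io import SubtypeModel

__all__ = [
    "ThresholdPair",
    "SubtypeCall",
    "predict_proba",
    "predict_matrix",
    "call_subtype",
    "classify_profiles",
]

LUAD, LUSC, INDETERMINATE = "LUAD", "LUSC", "INDETERMINATE"


@dataclass(frozen=True)
class ThresholdPair:
    """Confident-calling bounds: theta_lusc <= theta_luad, both in [0, 1]."""

    theta_luad: float
    theta_lusc: float

    def __post_init__(self) -> None:
        for name, v in (("theta_luad", self.theta_luad), ("theta_lusc", self.theta_lusc)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.theta_lusc > self.theta_luad:
            raise ValueError(
                f"theta_lusc ({self.theta_lusc}) must not exceed "
                f"theta_luad ({self.theta_luad})"
            )


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    probability: float
    call: str


def predict_proba(z: Mapping[str, float] | pd.Series, model: SubtypeModel) -> float:
    """LUAD probability of one normalized profile under a logistic model.

    ``p = expit(beta0 + sum_g beta_g * z_g)``; the profile must supply every
    model coefficient gene. Evaluation is numerically stable for any logit.
    """
    z = pd.Series(z, dtype=float)
    missing = [g for g in model.genes if g not in z.index]
    if missing:
        raise KeyError(f"profile is missing model genes: {missing}")
    beta = np.array([model.coefficients[g] for g in model.genes])
    logit = model.intercept + float(z[model.genes].to_numpy() @ beta)
    return float(expit(logit))


def predict_matrix(nm: NormalizedMatrix, model: SubtypeModel) -> pd.Series:
    """LUAD probabilities for every sample of a normalized matrix."""
    missing = [g for g in model.genes if g not in nm.z.index]
    if missing:
        raise KeyError(f"normalized matrix is missing model genes: {missing}")
    beta = np.array([model.coefficients[g] for g in model.genes])
    logits = model.intercept + nm.z.loc[model.genes].to_numpy().T @ beta
    return pd.Series(expit(logits), index=nm.z.columns, name="probability")


def call_subtype(p: float, thresholds: ThresholdPair | None = None) -> str:
    """Map a LUAD probability to a call.

    Default single-threshold mode: LUAD iff ``p >= 0.5`` else LUSC. With a
    :class:`ThresholdPair`, probabilities strictly between ``theta_lusc`` and
    ``theta_luad`` are INDETERMINATE.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if thresholds is None:
        return LUAD if p >= 0.5 else LUSC
    if p >= thresholds.theta_luad:
        return LUAD
    if p <= thresholds.theta_lusc:
        return LUSC
    return INDETERMINATE


def classify_profiles(
    nm: NormalizedMatrix,
    model: SubtypeModel,
    thresholds: ThresholdPair | None = None,
) -> pd.DataFrame:
    """Predict and call every sample; returns sample_id, probability, call."""
    p = predict_matrix(nm, model)
    calls = [call_subtype(float(pi), thresholds) for pi in p]
    return pd.DataFrame(
        {"sample_id": p.index, "probability": p.to_numpy(), "call": calls}
    ).reset_index(drop=True)
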