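"""Synthetic respondent cohorts for evaluating stopping rules.

No public dataset pairs completed SOAPP-R questionnaires with
prescription-monitoring-program outcomes, so evaluation runs on
synthetic cohorts with the structure those data have: ordinal 0-4 item
responses that are positively correlated with a binary high-risk label
through a shared latent trait.

Generative model, per respondent r with latent trait theta_r ~ N(0, 1):

    score_ri ~ min_i + Binomial(max_i - min_i, logistic(a_i * theta_r + b_i))
    label_r  ~ Bernoulli(logistic(g * theta_r + h))

Because the screener total and the label share only the latent trait,
the screener is an informative but imperfect test for the label — the
regime in which sensitivity and specificity are non-degenerate.  The
default parameters are calibrated so a default cohort on the 24-item
instrument resembles the emergency-department cohorts this toolkit
targets: mean total near 14 (SD ~12), roughly a quarter of respondents
at or above the cutoff of 18, and label prevalence near 17%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .instrument import Instrument, ResponseMatrix

__all__ = ["SimulationConfig", "generate_cohort", "summarize_cohort", "CohortSummary"]


def _per_item(value: Union[float, Sequence[float]], n_items: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(n_items, float(arr))
    if arr.shape != (n_items,):
        raise ValueError(f"{name} must be a scalar or length-{n_items} sequence")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the latent-trait cohort generator.

    discrimination
        Per-item slope a_i on the latent trait (scalar broadcasts to all
        items); larger values tie item scores more tightly to the trait.
    difficulty
        Per-item intercept b_i; more negative values shift item scores
        toward 0.
    label_slope / label_intercept
        Slope g and intercept h of the label's logistic link to the
        trait; g controls how informative the screener can be about the
        label, h the label prevalence.
    """

    n: int
    seed: int
    discrimination: Union[float, Sequence[float]] = 1.0
    difficulty: Union[float, Sequence[float]] = -2.1
    label_slope: float = 2.0
    label_intercept: float = -2.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size n must be >= 1, got {self.n}")
        if np.any(np.asarray(self.discrimination, dtype=np.float64) <= 0):
            raise ValueError("discrimination must be positive")


def generate_cohort(config: SimulationConfig, instrument: Instrument) -> ResponseMatrix:
    """Draw a labelled cohort; bit-identical for identical seeds."""
    n_items = instrument.n_items
    a = _per_item(config.discrimination, n_items, "discrimination")
    b = _per_item(config.difficulty, n_items, "difficulty")
    if np.any(a <= 0):
        raise ValueError("discrimination must be positive")
    rng = np.random.default_rng(config.seed)
    theta = rng.standard_normal(config.n)
    eta = theta[:, None] * a[None, :] + b[None, :]
    p_item = 1.0 / (1.0 + np.exp(-eta))
    n_cat = np.array([it.max_score - it.min_score for it in instrument.items])
    mins = np.array([it.min_score for it in instrument.items])
    scores = rng.binomial(n_cat[None, :], p_item) + mins[None, :]
    p_label = 1.0 / (1.0 + np.exp(-(config.label_slope * theta + config.label_intercept)))
    labels = (rng.random(config.n) < p_label).astype(np.int64)
    width = max(4, len(str(config.n)))
    ids = tuple(f"r{i + 1:0{width}d}" for i in range(config.n))
    return ResponseMatrix(ids, scores, labels).validate(instrument)


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_total: float
    sd_total: float
    prop_at_or_above_cutoff: float
    label_prevalence: Optional[float]


def summarize_cohort(matrix: ResponseMatrix, instrument: Instrument) -> CohortSummary:
    """Descriptive statistics of a cohort's total scores and labels."""
    matrix.validate(instrument)
    totals = matrix.totals()
    return CohortSummary(
        n=matrix.n,
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)) if matrix.n > 1 else 0.0,
        prop_at_or_above_cutoff=float((totals >= instrument.cutoff).mean()),
        label_prevalence=(
            float(matrix.labels.mean()) if matrix.labels is not None else None
        ),
    )
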