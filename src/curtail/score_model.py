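"""Item response-probability model behind stochastic curtailment.

Stochastic curtailment needs, after each administered item, the
probability that the *completed* instrument would classify the respondent
as high risk given the score accumulated so far.  Under the model used
here the not-yet-administered items are independent categorical variables
with per-item probability mass functions estimated from a training
cohort (optionally Laplace-smoothed), and the distribution of their sum
is obtained by exact dynamic-programming convolution.

The conditional probability of an eventual high-risk classification is
then the upper tail of that remaining-sum distribution:

    P(final total >= cutoff | S_k) = P(R_k >= cutoff - S_k),

where ``S_k`` is the cumulative score after ``k`` items and ``R_k`` the
sum of the remaining ``N - k`` items.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .instrument import Instrument, InstrumentError, ResponseMatrix, _check_k

__all__ = [
    "ItemProbabilityModel",
    "RemainingSumDistribution",
    "fit_item_model",
    "remaining_sum_pmf",
    "prob_high",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_RENORM_TOL = 1e-12


@dataclass
class ItemProbabilityModel:
    """Per-item categorical score distributions for one instrument.

    ``pmfs[i]`` is a probability vector over the scores
    ``min_score_i .. max_score_i`` of item ``i``.  Suffix (remaining-sum)
    distributions are cached on first use and reused across respondents.
    """

    instrument_name: str
    pmfs: tuple[np.ndarray, ...]
    smoothing_alpha: float
    n_train: int
    _suffix_cache: Optional[list["RemainingSumDistribution"]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        pmfs = []
        for i, p in enumerate(self.pmfs):
            p = np.asarray(p, dtype=np.float64)
            if p.ndim != 1 or len(p) < 1:
                raise ValueError(f"pmf for item {i + 1} must be a 1-D vector")
            if (p < 0).any():
                raise ValueError(f"pmf for item {i + 1} has negative entries")
            if abs(p.sum() - 1.0) > _RENORM_TOL:
                raise ValueError(
                    f"pmf for item {i + 1} sums to {p.sum():.17g}, expected 1"
                )
            pmfs.append(p)
        self.pmfs = tuple(pmfs)

    @property
    def n_items(self) -> int:
        return len(self.pmfs)

    def check_instrument(self, instrument: Instrument) -> None:
        if self.n_items != instrument.n_items:
            raise InstrumentError(
                f"model has {self.n_items} items but instrument "
                f"{instrument.name!r} has {instrument.n_items}"
            )
        for i, (p, it) in enumerate(zip(self.pmfs, instrument.items)):
            if len(p) != it.n_categories:
                raise InstrumentError(
                    f"model pmf for item {i + 1} has {len(p)} categories, "
                    f"instrument item has {it.n_categories}"
                )

    def suffix_distributions(
        self, instrument: Instrument
    ) -> list["RemainingSumDistribution"]:
        """Remaining-sum distribution for every k = 0..N, computed once."""
        if self._suffix_cache is None:
            self.check_instrument(instrument)
            self._suffix_cache = _suffix_table(self, instrument)
        return self._suffix_cache


@dataclass(frozen=True)
class RemainingSumDistribution:
    """Distribution of the summed score of items not yet administered."""

    k: int
    support_min: int
    support_max: int
    pmf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=np.float64))
        if len(self.pmf) != self.support_max - self.support_min + 1:
            raise ValueError("pmf length inconsistent with support bounds")

    def tail_prob(self, threshold: int) -> float:
        """P(remaining sum >= threshold), exact on the integer support."""
        if threshold <= self.support_min:
            return 1.0
        if threshold > self.support_max:
            return 0.0
        p = float(self.pmf[threshold - self.support_min :].sum())
        return min(max(p, 0.0), 1.0)


def fit_item_model(
    training: ResponseMatrix,
    instrument: Instrument,
    smoothing_alpha: float = 1.0,
) -> ItemProbabilityModel:
    """Fit per-item categorical pmfs from a training cohort.

    Each item's pmf is the Laplace-smoothed empirical frequency:
    ``(count(s) + alpha) / (n + alpha * K)`` over its ``K`` score
    categories.  The default ``alpha = 1`` keeps every category's
    probability strictly positive, so sparse training data cannot make a
    merely-improbable final classification look impossible; ``alpha = 0``
    gives the raw empirical frequencies.
    """
    if smoothing_alpha < 0:
        raise ValueError(f"smoothing_alpha must be >= 0, got {smoothing_alpha}")
    training.validate(instrument)
    if training.n < 1:
        raise ValueError("training matrix is empty")
    pmfs = []
    for j, it in enumerate(instrument.items):
        counts = np.bincount(
            training.scores[:, j] - it.min_score, minlength=it.n_categories
        ).astype(np.float64)
        pmf = (counts + smoothing_alpha) / (training.n + smoothing_alpha * it.n_categories)
        pmf /= pmf.sum()  # guard against float drift in the normalizer
        pmfs.append(pmf)
    return ItemProbabilityModel(
        instrument_name=instrument.name,
        pmfs=tuple(pmfs),
        smoothing_alpha=float(smoothing_alpha),
        n_train=training.n,
    )


def _suffix_table(
    model: ItemProbabilityModel, instrument: Instrument
) -> list[RemainingSumDistribution]:
    """Convolve item pmfs back-to-front: entry k covers items k+1..N."""
    n = instrument.n_items
    table: list[Optional[RemainingSumDistribution]] = [None] * (n + 1)
    table[n] = RemainingSumDistribution(n, 0, 0, np.array([1.0]))
    for k in range(n - 1, -1, -1):
        it = instrument.items[k]
        nxt = table[k + 1]
        pmf = np.convolve(model.pmfs[k], nxt.pmf)
        drift = abs(pmf.sum() - 1.0)
        if drift > _RENORM_TOL:
            logger.debug("renormalizing suffix pmf at k=%d (drift %.3g)", k, drift)
            pmf = pmf / pmf.sum()
        table[k] = RemainingSumDistribution(
            k=k,
            support_min=it.min_score + nxt.support_min,
            support_max=it.max_score + nxt.support_max,
            pmf=pmf,
        )
    return table  # type: ignore[return-value]


def remaining_sum_pmf(
    model: ItemProbabilityModel, instrument: Instrument, k: int
) -> RemainingSumDistribution:
    """Exact distribution of the sum of items ``k+1..N`` under the model."""
    _check_k(instrument, k)
    return model.suffix_distributions(instrument)[k]


def prob_high(
    model: ItemProbabilityModel,
    instrument: Instrument,
    k: int,
    cumulative: int,
) -> float:
    """P(final total >= cutoff) given cumulative score after ``k`` items.

    Returns exactly 1.0 when the cutoff is already guaranteed by score
    arithmetic and exactly 0.0 when it is unreachable, independent of the
    fitted probabilities.
    """
    _check_k(instrument, k)
    if not (instrument.min_remaining(0) - instrument.min_remaining(k) <= cumulative):
        raise ValueError(f"cumulative score {cumulative} not achievable after {k} items")
    if cumulative > sum(it.max_score for it in instrument.items[:k]):
        raise ValueError(f"cumulative score {cumulative} not achievable after {k} items")
    dist = remaining_sum_pmf(model, instrument, k)
    return dist.tail_prob(instrument.cutoff - cumulative)


def save_model(model: ItemProbabilityModel, path: str | Path) -> None:
    """Serialize a fitted model as JSON (lossless float round-trip)."""
    doc = {
        "instrument_name": model.instrument_name,
        "smoothing_alpha": model.smoothing_alpha,
        "n_train": model.n_train,
        "pmfs": [[float(x) for x in p] for p in model.pmfs],
    }
    Path(path).write_text(json.dumps(doc) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> ItemProbabilityModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return ItemProbabilityModel(
        instrument_name=str(doc["instrument_name"]),
        pmfs=tuple(np.asarray(p, dtype=np.float64) for p in doc["pmfs"]),
        smoothing_alpha=float(doc["smoothing_alpha"]),
        n_train=int(doc["n_train"]),
    )
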