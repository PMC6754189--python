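"""Administration engines: full-length, curtailment, stochastic curtailment, short form.

Each engine replays one complete response vector item by item and
decides when the administration would have stopped had the stopping rule
been applied live ("real-data simulation": the responses were collected
on the full-length instrument and the variable-length outcome is
determined post hoc).

Stopping rules
--------------
* **Full length** — administer every item; classify high iff the total
  reaches the cutoff.
* **Curtailment** — stop as soon as the full-length classification is
  mathematically determined: either the cumulative score already reaches
  the cutoff, or it cannot reach the cutoff even if every remaining item
  scored its maximum.  Curtailment always reproduces the full-length
  classification exactly.
* **Stochastic curtailment (SC)** — additionally stop once the
  *probability* that the completed instrument would classify high (or
  low) reaches a threshold gamma, computed from a fitted item model.
  SC-95 uses gamma = 0.95, SC-99 gamma = 0.99.  gamma = 1.0 degenerates
  to the curtailment rule.
* **Short form** — a fixed subset of items with its own cutoff (for the
  SOAPP-R: 12 items, cutoff 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .instrument import Instrument, ResponseMatrix, ResponseError
from .score_model import ItemProbabilityModel

__all__ = [
    "AdministrationOutcome",
    "administer_full",
    "administer_curtailed",
    "administer_sc",
    "administer_short_form",
    "administer_cohort",
    "outcomes_to_frame",
    "write_outcomes",
]

HIGH = "high"
LOW = "low"

COMPLETED = "completed"
CERTAIN_HIGH = "certain_high"
CERTAIN_LOW = "certain_low"
PROBABLE_HIGH = "probable_high"
PROBABLE_LOW = "probable_low"


@dataclass(frozen=True)
class AdministrationOutcome:
    """Result of administering one instrument to one respondent."""

    respondent_id: str
    classification: str
    administered_length: int
    score_at_stop: int
    stopping_reason: str
    probability_trace: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.classification not in (HIGH, LOW):
            raise ValueError(f"bad classification {self.classification!r}")
        if self.stopping_reason in (CERTAIN_HIGH, PROBABLE_HIGH) and self.classification != HIGH:
            raise ValueError("high-side stopping reason with low classification")
        if self.stopping_reason in (CERTAIN_LOW, PROBABLE_LOW) and self.classification != LOW:
            raise ValueError("low-side stopping reason with high classification")


def _validated_vector(responses: Sequence[int], instrument: Instrument) -> np.ndarray:
    vec = np.asarray(responses)
    if vec.shape != (instrument.n_items,):
        raise ResponseError(
            f"response vector has shape {vec.shape}, expected "
            f"({instrument.n_items},) for instrument {instrument.name!r}"
        )
    if not np.issubdtype(vec.dtype, np.integer):
        if not np.array_equal(vec, vec.astype(np.int64)):
            raise ResponseError("response vector must contain integers")
    vec = vec.astype(np.int64)
    for j, it in enumerate(instrument.items):
        if not (it.min_score <= vec[j] <= it.max_score):
            raise ResponseError(
                f"score {vec[j]} out of range [{it.min_score}, {it.max_score}] "
                f"at item_{j + 1}"
            )
    return vec


def administer_full(
    responses: Sequence[int],
    instrument: Instrument,
    respondent_id: str = "",
) -> AdministrationOutcome:
    """Administer every item; classify on the total score."""
    vec = _validated_vector(responses, instrument)
    total = int(vec.sum())
    return AdministrationOutcome(
        respondent_id=respondent_id,
        classification=HIGH if total >= instrument.cutoff else LOW,
        administered_length=instrument.n_items,
        score_at_stop=total,
        stopping_reason=COMPLETED,
    )


def administer_curtailed(
    responses: Sequence[int],
    instrument: Instrument,
    respondent_id: str = "",
) -> AdministrationOutcome:
    """Stop at the first item where the final classification is certain.

    After item k with cumulative score S_k, administration ends high if
    S_k >= cutoff, or low if S_k plus the maximum obtainable from the
    remaining items still falls short of the cutoff.  If neither
    certainty occurs before the last item, the outcome equals the
    full-length administration.
    """
    vec = _validated_vector(responses, instrument)
    n = instrument.n_items
    cutoff = instrument.cutoff
    cum = 0
    for k in range(1, n):
        cum += int(vec[k - 1])
        if cum >= cutoff:
            return AdministrationOutcome(respondent_id, HIGH, k, cum, CERTAIN_HIGH)
        if cum + instrument.max_remaining(k) < cutoff:
            return AdministrationOutcome(respondent_id, LOW, k, cum, CERTAIN_LOW)
    return administer_full(vec, instrument, respondent_id)


def administer_sc(
    responses: Sequence[int],
    instrument: Instrument,
    model: ItemProbabilityModel,
    gamma: float,
    respondent_id: str = "",
) -> AdministrationOutcome:
    """Stochastic curtailment: stop once a classification is near-certain.

    After item k < N with cumulative score S_k, the engine computes
    p_k = P(final total >= cutoff | S_k) under the fitted item model and
    stops high when p_k >= gamma, or low when p_k <= 1 - gamma
    (threshold comparisons are inclusive).  The stop is labelled
    ``certain_*`` when it is forced by score arithmetic — the remaining
    items' support alone decides the classification — and ``probable_*``
    otherwise, so certainty never rests on floating-point equality.
    ``probability_trace`` records p_1..p_stop.

    gamma must satisfy 0.5 < gamma <= 1; at or below 0.5 both stop
    conditions could fire at once.  gamma = 1.0 reproduces the
    curtailment rule exactly: only support-certain stops fire.
    """
    if not (0.5 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0.5, 1.0], got {gamma}")
    vec = _validated_vector(responses, instrument)
    model.check_instrument(instrument)
    suffix = model.suffix_distributions(instrument)
    n = instrument.n_items
    cutoff = instrument.cutoff
    trace: list[float] = []
    cum = 0
    for k in range(1, n):
        cum += int(vec[k - 1])
        dist = suffix[k]
        need = cutoff - cum
        p = dist.tail_prob(need)
        trace.append(p)
        certain_high = need <= dist.support_min
        certain_low = need > dist.support_max
        if gamma == 1.0:
            # short-circuit to the curtailment rule's exact conditions
            if cum >= cutoff:
                return AdministrationOutcome(
                    respondent_id, HIGH, k, cum, CERTAIN_HIGH, tuple(trace)
                )
            if certain_low:
                return AdministrationOutcome(
                    respondent_id, LOW, k, cum, CERTAIN_LOW, tuple(trace)
                )
            continue
        if p >= gamma:
            reason = CERTAIN_HIGH if certain_high else PROBABLE_HIGH
            return AdministrationOutcome(
                respondent_id, HIGH, k, cum, reason, tuple(trace)
            )
        if p <= 1.0 - gamma:
            reason = CERTAIN_LOW if certain_low else PROBABLE_LOW
            return AdministrationOutcome(
                respondent_id, LOW, k, cum, reason, tuple(trace)
            )
    full = administer_full(vec, instrument, respondent_id)
    trace.append(1.0 if full.classification == HIGH else 0.0)
    return AdministrationOutcome(
        respondent_id,
        full.classification,
        n,
        full.score_at_stop,
        COMPLETED,
        tuple(trace),
    )


def administer_short_form(
    responses: Sequence[int],
    instrument: Instrument,
    subset: Sequence[int],
    short_cutoff: int,
    respondent_id: str = "",
) -> AdministrationOutcome:
    """Fixed-length short form over a subset of the full instrument's items.

    ``subset`` holds 1-based item indices into the full instrument, in
    administration order.  Classification is high iff the subset total
    reaches ``short_cutoff``.
    """
    vec = _validated_vector(responses, instrument)
    idx = list(subset)
    if len(idx) == 0:
        raise ValueError("subset must contain at least one item index")
    if len(set(idx)) != len(idx):
        raise ValueError("subset contains duplicate item indices")
    for i in idx:
        if not (1 <= i <= instrument.n_items):
            raise ValueError(
                f"subset index {i} out of range 1..{instrument.n_items}"
            )
    max_subtotal = sum(instrument.items[i - 1].max_score for i in idx)
    if not (1 <= short_cutoff <= max_subtotal):
        raise ValueError(
            f"short_cutoff {short_cutoff} outside [1, {max_subtotal}] for this subset"
        )
    total = int(sum(vec[i - 1] for i in idx))
    return AdministrationOutcome(
        respondent_id=respondent_id,
        classification=HIGH if total >= short_cutoff else LOW,
        administered_length=len(idx),
        score_at_stop=total,
        stopping_reason=COMPLETED,
    )


def administer_cohort(
    matrix: ResponseMatrix,
    instrument: Instrument,
    method: str,
    model: Optional[ItemProbabilityModel] = None,
    gamma: Optional[float] = None,
    subset: Optional[Sequence[int]] = None,
    short_cutoff: Optional[int] = None,
) -> list[AdministrationOutcome]:
    """Replay every respondent of a cohort through one stopping rule.

    ``method`` is one of ``full``, ``curtailment``, ``sc`` (requires
    ``model`` and ``gamma``) or ``short_form`` (requires ``subset`` and
    ``short_cutoff``).
    """
    matrix.validate(instrument)
    if method == "full":
        return [
            administer_full(row, instrument, rid)
            for rid, row in zip(matrix.respondent_ids, matrix.scores)
        ]
    if method == "curtailment":
        return [
            administer_curtailed(row, instrument, rid)
            for rid, row in zip(matrix.respondent_ids, matrix.scores)
        ]
    if method == "sc":
        if model is None or gamma is None:
            raise ValueError("method 'sc' requires a fitted model and gamma")
        model.suffix_distributions(instrument)  # precompute once for the cohort
        return [
            administer_sc(row, instrument, model, gamma, rid)
            for rid, row in zip(matrix.respondent_ids, matrix.scores)
        ]
    if method == "short_form":
        if subset is None or short_cutoff is None:
            raise ValueError("method 'short_form' requires subset and short_cutoff")
        return [
            administer_short_form(row, instrument, subset, short_cutoff, rid)
            for rid, row in zip(matrix.respondent_ids, matrix.scores)
        ]
    raise ValueError(
        f"unknown method {method!r}; expected full, curtailment, sc or short_form"
    )


def outcomes_to_frame(
    outcomes: Iterable[AdministrationOutcome], method: str
) -> pd.DataFrame:
    """Tabulate outcomes, one row per respondent."""
    return pd.DataFrame(
        {
            "respondent_id": [o.respondent_id for o in outcomes],
            "method": method,
            "classification": [o.classification for o in outcomes],
            "administered_length": [o.administered_length for o in outcomes],
            "score_at_stop": [o.score_at_stop for o in outcomes],
            "stopping_reason": [o.stopping_reason for o in outcomes],
        }
    )


def write_outcomes(
    outcomes: Sequence[AdministrationOutcome], method: str, path: str | Path
) -> None:
    outcomes_to_frame(outcomes, method).to_csv(path, index=False)
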