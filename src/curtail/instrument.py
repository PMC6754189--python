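"""Instrument definitions and response-matrix input/output.

An :class:`Instrument` is an ordered list of polytomously scored items
together with a high-risk cutoff on the summed total score.  The built-in
definitions cover the SOAPP-R (Screener and Opioid Assessment for Patients
with Pain-Revised): 24 items scored 0-4 with a total of 18 or more
classified as high risk, and its 12-item short form with cutoff 9.

Respondent data live in a :class:`ResponseMatrix`: one complete integer
score per item per respondent, plus an optional binary gold-standard label
(in the opioid-screening setting, the prescription-monitoring-program
criterion of at least four opioid prescriptions from at least four
providers in twelve months).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemSpec",
    "Instrument",
    "ResponseMatrix",
    "InstrumentError",
    "ResponseError",
    "builtin_instrument",
    "load_instrument",
    "save_instrument",
    "read_responses",
    "write_responses",
    "max_remaining",
    "min_remaining",
    "BUILTIN_INSTRUMENTS",
]


class InstrumentError(ValueError):
    """An instrument definition violates its invariants."""


class ResponseError(ValueError):
    """A response matrix is malformed or inconsistent with its instrument."""


@dataclass(frozen=True)
class ItemSpec:
    """Score range of a single item (inclusive integer bounds)."""

    min_score: int
    max_score: int

    def __post_init__(self) -> None:
        if self.min_score < 0 or self.max_score < 0:
            raise InstrumentError(
                f"item score bounds must be non-negative, got "
                f"[{self.min_score}, {self.max_score}]"
            )
        if self.min_score > self.max_score:
            raise InstrumentError(
                f"item min_score {self.min_score} exceeds max_score {self.max_score}"
            )

    @property
    def n_categories(self) -> int:
        return self.max_score - self.min_score + 1


@dataclass(frozen=True)
class Instrument:
    """A summed-score instrument with a high-risk cutoff.

    Classification is "high" iff the total score over all items is at
    least ``cutoff``.  The cutoff must be reachable but not trivially
    guaranteed, i.e. ``1 <= cutoff <= sum(max_score)``; otherwise one of
    the two classes could never occur.
    """

    name: str
    items: tuple[ItemSpec, ...]
    cutoff: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) < 1:
            raise InstrumentError("instrument must have at least one item")
        if not all(isinstance(it, ItemSpec) for it in self.items):
            raise InstrumentError("items must be ItemSpec instances")
        if not (1 <= self.cutoff <= self.max_total):
            raise InstrumentError(
                f"cutoff {self.cutoff} outside [1, {self.max_total}] "
                f"(one classification would be unreachable)"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return sum(it.max_score for it in self.items)

    @property
    def min_total(self) -> int:
        return sum(it.min_score for it in self.items)

    def max_remaining(self, k: int) -> int:
        """Largest score still obtainable from items after the first ``k``."""
        return max_remaining(self, k)

    def min_remaining(self, k: int) -> int:
        """Smallest score still obtainable from items after the first ``k``."""
        return min_remaining(self, k)


def _check_k(instrument: Instrument, k: int) -> None:
    if not (0 <= k <= instrument.n_items):
        raise InstrumentError(
            f"k={k} out of range [0, {instrument.n_items}] for instrument "
            f"{instrument.name!r}"
        )


def max_remaining(instrument: Instrument, k: int) -> int:
    """Sum of max scores of the items not yet administered after item ``k``.

    This is the pivot of the deterministic curtailment rule: once the
    cumulative score plus ``max_remaining`` falls short of the cutoff, a
    low-risk classification is guaranteed.
    """
    _check_k(instrument, k)
    return sum(it.max_score for it in instrument.items[k:])


def min_remaining(instrument: Instrument, k: int) -> int:
    _check_k(instrument, k)
    return sum(it.min_score for it in instrument.items[k:])


BUILTIN_INSTRUMENTS = ("soappr24", "soappr12")


def builtin_instrument(name: str) -> Instrument:
    """Return a built-in instrument definition.

    ``soappr24``
        Full-length SOAPP-R: 24 items scored 0-4, high risk at total >= 18.
    ``soappr12``
        12-item SOAPP-R short form: items scored 0-4, high risk at
        total >= 9.  Only score ranges and cutoff are defined; which 12
        of the 24 original items it contains must be supplied by the
        caller when mapping columns of a full-length response matrix.
    """
    if name == "soappr24":
        return Instrument("soappr24", tuple(ItemSpec(0, 4) for _ in range(24)), 18)
    if name == "soappr12":
        return Instrument("soappr12", tuple(ItemSpec(0, 4) for _ in range(12)), 9)
    raise InstrumentError(
        f"unknown instrument {name!r}; known built-ins: {', '.join(BUILTIN_INSTRUMENTS)}"
    )


def save_instrument(instrument: Instrument, path: str | Path) -> None:
    """Write an instrument definition as JSON."""
    doc = {
        "name": instrument.name,
        "items": [
            {"min": it.min_score, "max": it.max_score} for it in instrument.items
        ],
        "cutoff": instrument.cutoff,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def load_instrument(path: str | Path) -> Instrument:
    """Read an instrument definition from JSON, validating all invariants."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise InstrumentError(f"malformed instrument JSON at {path}: {exc}") from exc
    for key in ("name", "items", "cutoff"):
        if key not in doc:
            raise InstrumentError(f"instrument JSON missing key {key!r}")
    try:
        items = tuple(ItemSpec(int(d["min"]), int(d["max"])) for d in doc["items"])
    except (KeyError, TypeError) as exc:
        raise InstrumentError(
            f"instrument items must be objects with integer 'min' and 'max': {exc}"
        ) from exc
    return Instrument(str(doc["name"]), items, int(doc["cutoff"]))


@dataclass
class ResponseMatrix:
    """Complete item responses for a cohort, with optional binary labels.

    ``scores`` has one row per respondent and one column per item, in the
    instrument's declared item order.  Labels, if present, encode the
    gold-standard outcome (1 = high risk).
    """

    respondent_ids: tuple[str, ...]
    scores: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.respondent_ids = tuple(str(r) for r in self.respondent_ids)
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2:
            raise ResponseError("scores must be a 2-D array (respondents x items)")
        if len(self.respondent_ids) != self.scores.shape[0]:
            raise ResponseError(
                f"{len(self.respondent_ids)} respondent ids for "
                f"{self.scores.shape[0]} score rows"
            )
        if len(set(self.respondent_ids)) != len(self.respondent_ids):
            seen: set[str] = set()
            dup = next(r for r in self.respondent_ids if r in seen or seen.add(r))
            raise ResponseError(f"duplicate respondent id {dup!r}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.scores.shape[0],):
                raise ResponseError("labels must have one entry per respondent")
            bad = ~np.isin(self.labels, (0, 1))
            if bad.any():
                i = int(np.argmax(bad))
                raise ResponseError(
                    f"label for respondent {self.respondent_ids[i]!r} is "
                    f"{self.labels[i]}, expected 0 or 1"
                )

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def validate(self, instrument: Instrument) -> "ResponseMatrix":
        """Check shape and per-item score ranges against an instrument."""
        if self.n_items != instrument.n_items:
            raise ResponseError(
                f"matrix has {self.n_items} item columns but instrument "
                f"{instrument.name!r} has {instrument.n_items} items"
            )
        for j, it in enumerate(instrument.items):
            col = self.scores[:, j]
            bad = (col < it.min_score) | (col > it.max_score)
            if bad.any():
                i = int(np.argmax(bad))
                raise ResponseError(
                    f"score {col[i]} out of range [{it.min_score}, {it.max_score}] "
                    f"at respondent {self.respondent_ids[i]!r}, column item_{j + 1}"
                )
        return self

    def totals(self) -> np.ndarray:
        return self.scores.sum(axis=1)


def _item_columns(n_items: int) -> list[str]:
    return [f"item_{j + 1}" for j in range(n_items)]


def read_responses(
    path: str | Path,
    instrument: Instrument,
    label_column: Optional[str] = "label",
) -> ResponseMatrix:
    """Read and validate a response CSV.

    Expected header: ``respondent_id,item_1,...,item_N`` with an optional
    trailing label column.  Missing cells, out-of-range scores, duplicate
    ids and shape mismatches are all rejected with the offending row and
    column named.  Pass ``label_column=None`` to ignore any label column.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str})
    cols = _item_columns(instrument.n_items)
    if "respondent_id" not in df.columns:
        raise ResponseError(f"{path}: missing 'respondent_id' column")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ResponseError(
            f"{path}: expected {instrument.n_items} item columns for instrument "
            f"{instrument.name!r}; missing {missing[:3]}"
        )
    for c in cols:
        col = df[c]
        if col.isna().any():
            row = df.loc[col.isna(), "respondent_id"].iloc[0]
            raise ResponseError(f"{path}: missing value in column {c} (respondent {row!r})")
        as_num = pd.to_numeric(col, errors="coerce")
        bad = as_num.isna() | (as_num % 1 != 0)
        if bad.any():
            row = df.loc[bad, "respondent_id"].iloc[0]
            raise ResponseError(
                f"{path}: non-integer value in column {c} (respondent {row!r})"
            )
        df[c] = as_num.astype(np.int64)
    labels = None
    if label_column is not None and label_column in df.columns:
        lab = pd.to_numeric(df[label_column], errors="coerce")
        if lab.isna().any() or (lab % 1 != 0).any():
            raise ResponseError(f"{path}: label column must contain integers 0/1")
        labels = lab.to_numpy(dtype=np.int64)
    matrix = ResponseMatrix(
        respondent_ids=tuple(df["respondent_id"].astype(str)),
        scores=df[cols].to_numpy(dtype=np.int64),
        labels=labels,
    )
    return matrix.validate(instrument)


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write a response matrix as CSV (round-trips through read_responses)."""
    df = pd.DataFrame(matrix.scores, columns=_item_columns(matrix.n_items))
    df.insert(0, "respondent_id", list(matrix.respondent_ids))
    if matrix.labels is not None:
        df["label"] = matrix.labels
    df.to_csv(path, index=False)
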