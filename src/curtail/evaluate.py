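"""Operating-characteristic evaluation of administration methods.

Replays a labelled cohort through each requested stopping rule and
reports, per method: sensitivity and specificity against the
gold-standard label, mean and SD of administered test length, the
percentage of administrations that ended before the final item of the
full-length instrument, and the concordance of each method's
classification with the full-length classification.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import HIGH, AdministrationOutcome, administer_cohort
from .instrument import Instrument, ResponseMatrix
from .score_model import ItemProbabilityModel, fit_item_model

__all__ = [
    "Method",
    "ConfusionCounts",
    "MethodReport",
    "EvaluationReport",
    "confusion_counts",
    "evaluate_methods",
]


@dataclass(frozen=True)
class Method:
    """Specification of one administration method to evaluate."""

    kind: str  # full | curtailment | sc | short_form
    gamma: Optional[float] = None
    subset: Optional[tuple[int, ...]] = None
    short_cutoff: Optional[int] = None

    @classmethod
    def full(cls) -> "Method":
        return cls("full")

    @classmethod
    def curtailment(cls) -> "Method":
        return cls("curtailment")

    @classmethod
    def sc(cls, gamma: float) -> "Method":
        if not (0.5 < gamma <= 1.0):
            raise ValueError(f"gamma must be in (0.5, 1.0], got {gamma}")
        return cls("sc", gamma=gamma)

    @classmethod
    def short_form(cls, subset: Sequence[int], short_cutoff: int) -> "Method":
        return cls("short_form", subset=tuple(subset), short_cutoff=short_cutoff)

    @property
    def label(self) -> str:
        if self.kind == "sc":
            return f"sc_{self.gamma:g}"
        return self.kind


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        """TP / (TP + FN); None when there are no positives."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> Optional[float]:
        """TN / (TN + FP); None when there are no negatives."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else None


def confusion_counts(
    classifications: Sequence[str], labels: Sequence[int]
) -> ConfusionCounts:
    """Cross-tabulate test classifications against gold-standard labels.

    Positive means label 1; test-positive means classification "high".
    """
    if len(classifications) != len(labels):
        raise ValueError(
            f"{len(classifications)} classifications vs {len(labels)} labels"
        )
    cls = np.asarray([c == HIGH for c in classifications])
    lab = np.asarray(labels, dtype=np.int64)
    if not np.isin(lab, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    lab = lab.astype(bool)
    return ConfusionCounts(
        tp=int((cls & lab).sum()),
        fp=int((cls & ~lab).sum()),
        tn=int((~cls & ~lab).sum()),
        fn=int((~cls & lab).sum()),
    )


@dataclass(frozen=True)
class MethodReport:
    """One evaluated method's operating characteristics."""

    method: str
    sensitivity: Optional[float]
    specificity: Optional[float]
    mean_length: float
    sd_length: float
    pct_shortened: float
    concordance_with_full: float
    n: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-method operating characteristics for one cohort."""

    rows: tuple[MethodReport, ...]
    n: int
    sd_mode: str  # "sample" (n-1) or "population" (n)

    def to_frame(self, display: bool = False) -> pd.DataFrame:
        """Tabulate the report; ``display=True`` rounds proportions to 2
        decimals and lengths/percentages to 1."""
        df = pd.DataFrame(
            {
                "method": [r.method for r in self.rows],
                "sensitivity": [r.sensitivity for r in self.rows],
                "specificity": [r.specificity for r in self.rows],
                "mean_n_questions": [r.mean_length for r in self.rows],
                "sd_test_length": [r.sd_length for r in self.rows],
                "pct_shortened": [r.pct_shortened for r in self.rows],
                "concordance": [r.concordance_with_full for r in self.rows],
                "n": [r.n for r in self.rows],
            }
        )
        if display:
            for c in ("sensitivity", "specificity", "concordance"):
                df[c] = df[c].round(2)
            for c in ("mean_n_questions", "sd_test_length", "pct_shortened"):
                df[c] = df[c].round(1)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        doc = {
            "n": self.n,
            "sd_mode": self.sd_mode,
            "methods": [
                {
                    "method": r.method,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "mean_length": r.mean_length,
                    "sd_length": r.sd_length,
                    "pct_shortened": r.pct_shortened,
                    "concordance_with_full": r.concordance_with_full,
                    "n": r.n,
                }
                for r in self.rows
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _sd(lengths: np.ndarray, mode: str) -> float:
    if mode not in ("sample", "population"):
        raise ValueError(f"sd_mode must be 'sample' or 'population', got {mode!r}")
    if mode == "sample":
        return float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    return float(lengths.std(ddof=0))


def evaluate_methods(
    matrix: ResponseMatrix,
    instrument: Instrument,
    methods: Sequence[Method],
    model: Optional[ItemProbabilityModel] = None,
    train_matrix: Optional[ResponseMatrix] = None,
    smoothing_alpha: float = 1.0,
    sd_mode: str = "sample",
) -> EvaluationReport:
    """Replay the cohort under each method and compute report rows.

    Stochastic-curtailment methods need an item model: pass a fitted
    ``model``, or a ``train_matrix`` to fit one on.  If neither is given
    the model is fitted on the evaluation cohort itself — the
    retrospective same-cohort design — and a leakage warning is issued.

    ``sd_mode`` selects the test-length SD convention: "sample" (n-1
    denominator, the default) or "population" (n).
    """
    if not methods:
        raise ValueError("methods list is empty")
    if matrix.labels is None:
        raise ValueError("evaluation requires a labelled cohort")
    matrix.validate(instrument)
    _sd(np.zeros(2), sd_mode)  # validate mode up front

    needs_model = any(m.kind == "sc" for m in methods)
    if needs_model and model is None:
        if train_matrix is not None:
            model = fit_item_model(train_matrix, instrument, smoothing_alpha)
        else:
            warnings.warn(
                "fitting the stochastic-curtailment item model on the "
                "evaluation cohort itself (retrospective design): expect "
                "optimistic calibration",
                UserWarning,
                stacklevel=2,
            )
            model = fit_item_model(matrix, instrument, smoothing_alpha)

    full_cls = [
        o.classification for o in administer_cohort(matrix, instrument, "full")
    ]
    n_items = instrument.n_items
    rows = []
    for m in methods:
        outcomes = administer_cohort(
            matrix,
            instrument,
            m.kind,
            model=model,
            gamma=m.gamma,
            subset=m.subset,
            short_cutoff=m.short_cutoff,
        )
        cls = [o.classification for o in outcomes]
        lengths = np.array([o.administered_length for o in outcomes], dtype=np.float64)
        counts = confusion_counts(cls, matrix.labels)
        concord = float(np.mean([a == b for a, b in zip(cls, full_cls)]))
        rows.append(
            MethodReport(
                method=m.label,
                sensitivity=counts.sensitivity,
                specificity=counts.specificity,
                mean_length=float(lengths.mean()),
                sd_length=_sd(lengths, sd_mode),
                pct_shortened=float(100.0 * (lengths < n_items).mean()),
                concordance_with_full=concord,
                n=matrix.n,
            )
        )
    return EvaluationReport(rows=tuple(rows), n=matrix.n, sd_mode=sd_mode)
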