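"""Jackknife evaluation with locative accounting and the absolute-true metric.

Two complementary success rates are reported:

* **Locative success** — each (protein, location) membership is scored
  separately: location i of a protein is a hit when i appears in both the
  truth and the prediction.  The denominator is the number of locative
  proteins (1,456 for the Gram-negative benchmark, not 1,392), so a
  two-location protein contributes two chances to succeed or fail.
* **Absolute-true rate** — the fraction of proteins whose predicted label
  set equals the true set *exactly*; any over- or under-prediction scores
  zero.  The denominator is the number of distinct proteins.

The jackknife (leave-one-out) test removes each protein in turn from the
training pool — including, in GO mode, from the usable-GO term union —
before predicting it.  It is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .dataset_io import MultiLabelDataset, LOCATION_NAMES
from .mlknn import LOCATION_CODES, Prediction, TrainedModel, predict
from .representation import FeatureContext, represent

logger = logging.getLogger(__name__)


def delta_score(pred: frozenset[int] | set[int],
                truth: frozenset[int] | set[int]) -> int:
    """1 iff the predicted set equals the true set exactly, else 0.

    A protein with two locations of which only one is predicted, or whose
    prediction contains an extra location, scores 0.
    """
    if not pred or not truth:
        raise ValueError("label sets must be non-empty")
    return 1 if set(pred) == set(truth) else 0


def absolute_true(preds: Sequence[frozenset[int]],
                  truths: Sequence[frozenset[int]]) -> float:
    """Fraction of proteins predicted exactly right (the harshest scale)."""
    if len(preds) != len(truths):
        raise ValueError("prediction/truth lists must be aligned")
    if not preds:
        raise ValueError("need at least one protein")
    return sum(delta_score(p, t) for p, t in zip(preds, truths)) / len(preds)


def locative_success(
    preds: Sequence[frozenset[int]], truths: Sequence[frozenset[int]]
) -> tuple[dict[int, tuple[int, int]], tuple[int, int]]:
    """Per-location and overall locative success counts.

    For location i: total_i = #proteins with i in the truth; correct_i =
    #proteins with i in both truth and prediction.  The overall rate is
    sum(correct_i) / sum(total_i), i.e. per-locative-protein accounting.
    Returns ({code: (correct, total)}, (overall_correct, overall_total)).
    """
    if len(preds) != len(truths):
        raise ValueError("prediction/truth lists must be aligned")
    per_location = {code: [0, 0] for code in LOCATION_CODES}
    for pred, truth in zip(preds, truths):
        for code in truth:
            per_location[code][1] += 1
            if code in pred:
                per_location[code][0] += 1
    totals = (
        sum(c for c, _ in per_location.values()),
        sum(t for _, t in per_location.values()),
    )
    return {c: (v[0], v[1]) for c, v in per_location.items()}, totals


@dataclass
class ProteinResult:
    accession: str
    truth: frozenset[int]
    predicted: frozenset[int]
    mode: str
    delta: int


@dataclass
class EvaluationReport:
    """Aggregate jackknife results in the benchmark's accounting scheme."""

    per_location_locative: dict[int, tuple[int, int]]
    per_location_exact: dict[int, tuple[int, int]]
    n_locative_correct: int
    n_locative: int
    n_exact: int
    n_proteins: int
    records: list[ProteinResult] = field(default_factory=list, repr=False)
    location_names: dict[int, str] = field(
        default_factory=lambda: dict(LOCATION_NAMES)
    )

    @property
    def overall_locative_rate(self) -> float:
        return self.n_locative_correct / self.n_locative

    @property
    def absolute_true_rate(self) -> float:
        return self.n_exact / self.n_proteins

    def check_identities(self) -> None:
        """Internal accounting identities; raises on violation."""
        if sum(c for c, _ in self.per_location_locative.values()) != \
                self.n_locative_correct:
            raise AssertionError("locative numerator mismatch")
        if sum(t for _, t in self.per_location_locative.values()) != \
                self.n_locative:
            raise AssertionError("locative denominator mismatch")
        if self.records:
            if sum(r.delta for r in self.records) != self.n_exact:
                raise AssertionError("absolute-true numerator mismatch")
            if len(self.records) != self.n_proteins:
                raise AssertionError("protein count mismatch")
        for rate in (self.overall_locative_rate, self.absolute_true_rate):
            if not (0.0 <= rate <= 1.0):
                raise AssertionError(f"rate {rate} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_locative_proteins": self.n_locative,
            "overall_locative": {
                "correct": self.n_locative_correct,
                "total": self.n_locative,
                "rate": self.overall_locative_rate,
            },
            "absolute_true": {
                "correct": self.n_exact,
                "total": self.n_proteins,
                "rate": self.absolute_true_rate,
            },
            "per_location": {
                str(code): {
                    "name": self.location_names[code],
                    "locative_correct": self.per_location_locative[code][0],
                    "exact_correct": self.per_location_exact[code][0],
                    "total": self.per_location_locative[code][1],
                }
                for code in sorted(self.per_location_locative)
            },
        }

    def to_text(self) -> str:
        """Human-readable table: per-location 'correct/total = %'."""
        lines = [f"{'Code':<5}{'Subcellular location':<22}Success rate"]
        for code in sorted(self.per_location_locative):
            correct, total = self.per_location_locative[code]
            rate = f"{correct}/{total} = {100 * correct / total:.1f}%" \
                if total else "-/-"
            lines.append(f"{code:<5}{self.location_names[code]:<22}{rate}")
        lines.append(
            f"{'':<5}{'Overall (locative)':<22}"
            f"{self.n_locative_correct}/{self.n_locative} = "
            f"{100 * self.overall_locative_rate:.1f}%"
        )
        lines.append(
            f"{'':<5}{'Absolute true':<22}"
            f"{self.n_exact}/{self.n_proteins} = "
            f"{100 * self.absolute_true_rate:.1f}%"
        )
        return "\n".join(lines)


def evaluate(
    predictions: Sequence[Prediction],
    truths: Sequence[frozenset[int]],
) -> EvaluationReport:
    """Aggregate aligned predictions and truths into a report."""
    pred_sets = [p.labels for p in predictions]
    per_loc, (correct, total) = locative_success(pred_sets, truths)
    per_exact = {code: [0, 0] for code in LOCATION_CODES}
    records = []
    for p, truth in zip(predictions, truths):
        d = delta_score(p.labels, truth)
        records.append(ProteinResult(p.accession, truth, p.labels,
                                     p.mode.value, d))
        for code in truth:
            per_exact[code][1] += 1
            per_exact[code][0] += d
    report = EvaluationReport(
        per_location_locative=per_loc,
        per_location_exact={c: (v[0], v[1]) for c, v in per_exact.items()},
        n_locative_correct=correct,
        n_locative=total,
        n_exact=sum(r.delta for r in records),
        n_proteins=len(records),
        records=records,
    )
    report.check_identities()
    return report


def jackknife(
    dataset: MultiLabelDataset | None,
    ctx: FeatureContext,
    k: int | None = None,
) -> EvaluationReport:
    """Leave-one-out test: predict each protein with itself removed.

    The held-out protein is excluded from the neighbor candidate pool and,
    for GO-mode queries, from the usable-GO training union before the
    representation fallback decision.  ``dataset`` supplies the protein
    order and truth labels; when ``None``, the context's own accessions and
    labels are used (e.g. when evaluating straight from a feature store).
    """
    if dataset is None:
        items = [(acc, ctx.labels[acc]) for acc in ctx.accessions]
    else:
        items = [(rec.accession, rec.labels) for rec in dataset.records]
    if len(items) < 2:
        raise ValueError("jackknife needs at least 2 proteins")
    model = TrainedModel(ctx=ctx, k=k)
    predictions: list[Prediction] = []
    truths: list[frozenset[int]] = []
    for accession, labels in items:
        held_out = frozenset({accession})
        q = represent(accession, ctx, exclude=held_out)
        predictions.append(predict(q, model, exclude=held_out))
        truths.append(labels)
    return evaluate(predictions, truths)
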