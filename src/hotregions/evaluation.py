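"""Evaluation of hot-spot/hot-region predictions against annotations.

Provides residue-level confusion counting, precision/recall/F1, Cohen's
kappa, and the set arithmetic used for worked per-complex examples where a
prediction is reported as printed residue-id lists (predicted, missed and
false hot spots before optimization; recovered and removed ids after).

Precision is TP/(TP+FP) and recall TP/(TP+FN); both are *undefined* (not
zero) when their denominator vanishes, and the report carries that flag
explicitly. F1 is the harmonic mean 2PR/(P+R). Kappa defaults to the
standard Cohen form (p0 - pe) / (1 - pe) with chance agreement
pe = sum_i a_i b_i / n^2 over per-class true counts a_i and predicted
counts b_i; a literal mode with denominator (1 - p0) is available but is
degenerate at perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np

from .structure_io import ResidueId


class EvaluationError(Exception):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float | None
    recall: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Half-up rounding for display, matching conventional table formats."""
        def _r(v: float | None) -> float | None:
            if v is None:
                return None
            return float(np.floor(v * 10**ndigits + 0.5) / 10**ndigits)

        return {"precision": _r(self.precision), "recall": _r(self.recall), "f1": _r(self.f1)}


@dataclass(frozen=True)
class AgreementStats:
    p0: float
    pe: float
    kappa: float
    true_counts: dict[Hashable, int]
    predicted_counts: dict[Hashable, int]
    n: int
    mode: str = "standard"


def confusion(
    predicted: Iterable[Hashable],
    truth: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> ConfusionCounts:
    """Confusion counts of a predicted set against a truth set over a universe."""
    pred, tru, uni = set(predicted), set(truth), set(universe)
    outside = (pred | tru) - uni
    if outside:
        raise EvaluationError(
            f"elements outside the evaluation universe: {sorted(map(str, outside))}"
        )
    tp = len(pred & tru)
    fp = len(pred - tru)
    fn = len(tru - pred)
    tn = len(uni) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise EvaluationError("precision and recall must be >= 0")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(counts: ConfusionCounts) -> MetricsReport:
    """Precision, recall and F1 from confusion counts; undefined values flagged."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = f1_from_pr(precision, recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    return MetricsReport(precision=precision, recall=recall, f1=f1)


def kappa(
    true_labels: Sequence[Hashable],
    predicted_labels: Sequence[Hashable],
    mode: str = "standard",
) -> AgreementStats:
    """Cohen's kappa agreement between two label sequences.

    ``mode="standard"`` computes (p0 - pe) / (1 - pe); ``mode="literal"``
    computes (p0 - pe) / (1 - p0), which divides by zero at p0 = 1.
    """
    if mode not in ("standard", "literal"):
        raise EvaluationError(f"unknown kappa mode {mode!r}")
    if len(true_labels) != len(predicted_labels):
        raise EvaluationError("label sequences must have equal length")
    n = len(true_labels)
    if n == 0:
        raise EvaluationError("empty label sequences")
    classes = sorted(set(true_labels) | set(predicted_labels), key=str)
    if len(classes) < 2:
        raise EvaluationError("kappa needs at least 2 classes")
    a = {c: 0 for c in classes}
    b = {c: 0 for c in classes}
    agree = 0
    for t, p in zip(true_labels, predicted_labels):
        a[t] += 1
        b[p] += 1
        agree += int(t == p)
    p0 = agree / n
    pe = sum(a[c] * b[c] for c in classes) / (n * n)
    if mode == "standard":
        k = 0.0 if pe == 1.0 else (p0 - pe) / (1.0 - pe)
    else:
        if p0 == 1.0:
            raise ZeroDivisionError(
                "literal kappa is undefined at perfect agreement (p0 = 1)"
            )
        k = (p0 - pe) / (1.0 - p0)
    return AgreementStats(
        p0=p0, pe=pe, kappa=float(k), true_counts=a, predicted_counts=b, n=n, mode=mode
    )


# ---------------------------------------------------------------------------
# Worked-example residue-list arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableArithmetic:
    """Before/after-optimization confusion counts from printed residue lists."""

    before: ConfusionCounts
    after: ConfusionCounts
    predicted_after: frozenset = field(default_factory=frozenset)
    false_after: frozenset = field(default_factory=frozenset)


def _as_ids(labels: Iterable[str | ResidueId]) -> set[ResidueId]:
    out = set()
    for lbl in labels:
        out.add(lbl if isinstance(lbl, ResidueId) else ResidueId.from_label(lbl))
    return out


def table_set_arithmetic(
    predicted: Iterable[str | ResidueId],
    unpredicted: Iterable[str | ResidueId],
    false_predicted: Iterable[str | ResidueId],
    recovered: Iterable[str | ResidueId],
    unrecovered: Iterable[str | ResidueId],
    false_recovered: Iterable[str | ResidueId],
) -> TableArithmetic:
    """Confusion counts before and after a recovery/removal optimization pass.

    Inputs are residue-id lists in "A16"-style notation (or ResidueId):
    hot spots predicted/missed/false before optimization, then the missed
    hot spots recovered vs not, and the false predictions removed
    ("false recovered"). Consistency is enforced:
    recovered + unrecovered must partition the missed set, and the removed
    false predictions must be a subset of the original false set.
    """
    P = _as_ids(predicted)
    U = _as_ids(unpredicted)
    F = _as_ids(false_predicted)
    R = _as_ids(recovered)
    UR = _as_ids(unrecovered)
    FR = _as_ids(false_recovered)

    problems = []
    if R | UR != U:
        problems.append(
            "recovered + unrecovered != unpredicted; offenders: "
            + ", ".join(sorted(i.label for i in (R | UR) ^ U))
        )
    if R & UR:
        problems.append(
            "recovered and unrecovered overlap: "
            + ", ".join(sorted(i.label for i in R & UR))
        )
    if not FR <= F:
        problems.append(
            "false-recovered ids not in the false-predicted list: "
            + ", ".join(sorted(i.label for i in FR - F))
        )
    if P & U:
        problems.append(
            "predicted and unpredicted overlap: "
            + ", ".join(sorted(i.label for i in P & U))
        )
    if problems:
        raise EvaluationError("inconsistent residue lists: " + "; ".join(problems))

    before = ConfusionCounts(tp=len(P), fp=len(F), fn=len(U))
    predicted_after = P | R
    false_after = F - FR
    after = ConfusionCounts(tp=len(predicted_after), fp=len(false_after), fn=len(UR))
    return TableArithmetic(
        before=before,
        after=after,
        predicted_after=frozenset(predicted_after),
        false_after=frozenset(false_after),
    )


def read_residue_list(path: str | Path) -> list[ResidueId]:
    """Read a residue-list file: one "A16"-style id per line; '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(ResidueId.from_label(line))
    return out
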