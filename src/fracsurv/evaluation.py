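"""Engine evaluation against human annotation: confusion counts, precision /
recall / F1, Cohen's kappa, and consensus adjudication.

Conventions: the positive class is "fracture affirmed". Metrics with an
undefined denominator (no predicted or no actual positives) are reported as
explicitly undefined (``None``), never silently 0, so aggregate means are
not corrupted. Displayed values are rounded half-up to 2 decimals; stored
values keep full precision. The overall engine score is the unweighted
arithmetic mean of per-year consensus F1 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .corpus import Label, LabelRecord, LabelSource

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "KappaResult",
    "labels_to_dict",
    "confusion_counts",
    "metrics",
    "cohens_kappa",
    "consensus_labels",
    "overall_f1",
    "display_round",
    "evaluation_table",
]

LabelMap = Mapping[str, Label]


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """2x2 counts for engine-vs-reference comparison (positive = affirmed)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True, slots=True)
class MetricSet:
    """Precision, recall, F1; ``None`` marks an undefined metric."""

    precision: float | None
    recall: float | None
    f1: float | None

    @property
    def defined(self) -> bool:
        return None not in (self.precision, self.recall, self.f1)


@dataclass(frozen=True, slots=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def display_round(x: float, decimals: int = 2) -> float:
    """Round half-up for display (0.805 -> 0.81), unlike banker's rounding.

    Binary float noise is absorbed at 10 decimals first, so a value that is
    exactly on a half in decimal arithmetic (e.g. mean(0.82, 0.79) = 0.805)
    rounds up as intended.
    """
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(x)).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def labels_to_dict(labels: Sequence[LabelRecord] | LabelMap) -> dict[str, Label]:
    if isinstance(labels, Mapping):
        return dict(labels)
    out: dict[str, Label] = {}
    for rec in labels:
        if rec.report_id in out:
            raise ValueError(f"duplicate label for report {rec.report_id!r}")
        out[rec.report_id] = rec.label
    return out


def _aligned(a, b) -> tuple[dict[str, Label], dict[str, Label]]:
    da, db = labels_to_dict(a), labels_to_dict(b)
    if da.keys() != db.keys():
        only_a = sorted(da.keys() - db.keys())
        only_b = sorted(db.keys() - da.keys())
        raise ValueError(
            f"label sets differ: {len(only_a)} only in first ({only_a[:5]}...), "
            f"{len(only_b)} only in second ({only_b[:5]}...)"
        )
    return da, db


def confusion_counts(pred, gold) -> ConfusionCounts:
    """Count TP/TN/FP/FN between predicted and reference labels.

    Raises on mismatched report-id sets, listing the symmetric difference.
    """
    dp, dg = _aligned(pred, gold)
    tp = tn = fp = fn = 0
    for rid, p in dp.items():
        g = dg[rid]
        if p is Label.affirmed and g is Label.affirmed:
            tp += 1
        elif p is Label.not_affirmed and g is Label.not_affirmed:
            tn += 1
        elif p is Label.affirmed:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(cc: ConfusionCounts) -> MetricSet:
    """Precision, recall, and F1 from confusion counts.

    Undefined denominators yield ``None`` components rather than 0.
    """
    precision = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp > 0 else None
    recall = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None if precision is None or recall is None else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(precision, recall, f1)


def cohens_kappa(a, b) -> KappaResult:
    """Chance-corrected agreement between two binary raters.

    kappa = (p_o − p_e) / (1 − p_e); identical vectors give kappa = 1 even
    when both raters are constant (p_e = 1); constant-and-identical
    marginals with any disagreement are rejected as undefined.
    """
    da, db = _aligned(a, b)
    n = len(da)
    if n == 0:
        raise ValueError("cannot compute kappa on empty label sets")
    ids = sorted(da)
    observed = sum(da[i] is db[i] for i in ids) / n
    expected = 0.0
    for cls in (Label.affirmed, Label.not_affirmed):
        pa = sum(da[i] is cls for i in ids) / n
        pb = sum(db[i] is cls for i in ids) / n
        expected += pa * pb
    if expected >= 1.0 - 1e-15:
        if observed >= 1.0:
            return KappaResult(1.0, observed, expected)
        raise ValueError("kappa undefined: expected agreement is 1 with disagreements")
    kappa = (observed - expected) / (1 - expected)
    return KappaResult(kappa, observed, expected)


def consensus_labels(a, b, adjudicator) -> list[LabelRecord]:
    """Merge two annotators with expert adjudication of their disagreements.

    The adjudicator must cover exactly the disagreement set; agreements pass
    through unchanged.
    """
    da, db = _aligned(a, b)
    dj = labels_to_dict(adjudicator)
    disagreements = {rid for rid in da if da[rid] is not db[rid]}
    if dj.keys() != disagreements:
        missing = sorted(disagreements - dj.keys())
        extra = sorted(dj.keys() - disagreements)
        raise ValueError(
            f"adjudicator must cover exactly the disagreement set; "
            f"missing {missing[:5]}, extraneous {extra[:5]}"
        )
    return [
        LabelRecord(rid, LabelSource.consensus, dj[rid] if rid in dj else da[rid])
        for rid in sorted(da)
    ]


def overall_f1(per_year_f1: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-year F1 values (full precision;
    round only at display)."""
    if not per_year_f1:
        raise ValueError("need at least one per-year F1 value")
    return sum(per_year_f1) / len(per_year_f1)


def evaluation_table(
    comparisons: Mapping[str, tuple[object, object]]
) -> pd.DataFrame:
    """Confusion counts and metrics for several (pred, reference) pairs.

    *comparisons* maps a row name (e.g. "engine_vs_consensus_2019") to a
    (pred, reference) label pair. Output columns mirror a standard
    performance table: TP, TN, FP, FN, precision, recall, F1.
    """
    rows = []
    for name, (pred, ref) in comparisons.items():
        cc = confusion_counts(pred, ref)
        m = metrics(cc)
        rows.append(
            {
                "comparison": name,
                "tp": cc.tp,
                "tn": cc.tn,
                "fp": cc.fp,
                "fn": cc.fn,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
            }
        )
    return pd.DataFrame(rows)
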