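"""Feature screening by two-sample t-test and confusion-matrix accuracy.

Each of the ten texture features is screened with an uncorrected two-sample
t-test (healthy vs calcified); features with p < 0.05 pass to the
classifier.  Running ten uncorrected tests inflates the family-wise error
rate — this is preserved deliberately as part of the protocol being modeled
(see docs/methods.md) rather than "fixed" with a multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "TTestResult",
    "ConfusionMatrix",
    "two_sample_t_test",
    "screen_features",
    "accuracy_from_cm",
    "pvalue_table",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    feature_name: str
    t_stat: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = calcified."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def two_sample_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
    feature_name: str = "",
) -> TTestResult:
    """Two-sided two-sample t-test for equal means.

    ``variant="pooled"`` is the classical Student test (equal variances,
    df = na + nb - 2); ``"welch"`` uses the Welch–Satterthwaite df.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateInputError("both groups have zero variance")
    na, nb = a.size, b.size
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    elif variant == "welch":
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        raise InvalidArgumentError("variant must be 'pooled' or 'welch'")
    t_stat = float((a.mean() - b.mean()) / se)
    p_value = float(2.0 * t_dist.sf(abs(t_stat), df))
    return TTestResult(
        feature_name=feature_name,
        t_stat=t_stat,
        p_value=p_value,
        significant=p_value < alpha,
    )


def screen_features(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    label_column: str = "label",
    feature_columns: Sequence[str] | None = None,
    variant: str = "pooled",
) -> list[TTestResult]:
    """Per-feature t-test between the two classes of a feature table.

    Missing values (degenerate ROIs) are handled per feature on complete
    cases.  Raises if the table does not contain both classes.
    """
    classes = sorted(table[label_column].unique())
    if len(classes) != 2:
        raise InvalidArgumentError(f"need exactly 2 classes, got {classes}")
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns
            if c != label_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    results = []
    for col in feature_columns:
        sub = table[[label_column, col]].dropna()
        ga = sub.loc[sub[label_column] == classes[0], col].to_numpy()
        gb = sub.loc[sub[label_column] == classes[1], col].to_numpy()
        if ga.size < 2 or gb.size < 2:
            raise InvalidArgumentError(
                f"feature {col!r}: fewer than 2 complete cases in a class"
            )
        results.append(
            two_sample_t_test(ga, gb, variant=variant, alpha=alpha, feature_name=col)
        )
    return results


def accuracy_from_cm(cm: ConfusionMatrix) -> float:
    """Classification accuracy 100 * (TP + TN) / (TP + FP + TN + FN), percent."""
    if cm.total == 0:
        raise InvalidArgumentError("confusion matrix is all zero")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def pvalue_table(results_by_method: dict[str, list[TTestResult]]) -> pd.DataFrame:
    """Rows = method (M1, M2), columns = feature names, cells = p-values."""
    rows = {
        method: {r.feature_name: r.p_value for r in results}
        for method, results in results_by_method.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
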