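"""Gene-signature scoring, median stratification, and group comparison.

Bulk samples are scored as the mean over signature genes of median-
centered normalized expression; single cells as the plain per-cell mean
(no centering by default).  Cohorts are split at the median score into
``high``/``low`` strata; groups are compared by Welch's unequal-variance
t-test.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from xenomet.normalize import NormalizedMatrix


def _present_signature(matrix_genes: pd.Index, signature: Iterable[str]) -> list[str]:
    sig = list(dict.fromkeys(signature))  # preserve order, dedupe
    if not sig:
        raise ValueError("empty signature")
    present = [g for g in sig if g in matrix_genes]
    missing = sorted(set(sig) - set(present))
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix and dropped: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}",
            stacklevel=3,
        )
    return present


def score_bulk(
    normalized: NormalizedMatrix | pd.DataFrame, signature: Iterable[str]
) -> pd.DataFrame:
    """Score each sample as the mean of median-centered signature-gene values.

    Each gene's cohort median (across samples) is subtracted before
    averaging, so gene-wise offsets cancel.  Returns a table indexed by
    sample id with a ``score`` column.
    """
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    present = _present_signature(values.index, signature)
    sub = values.loc[present]
    centered = sub.sub(sub.median(axis=1), axis=0)
    scores = centered.mean(axis=0)
    return pd.DataFrame({"score": scores.astype(float)})


def score_cells(
    expression: pd.DataFrame,
    signature: Iterable[str],
    groups: pd.Series | None = None,
    center: bool = False,
) -> pd.DataFrame:
    """Score each cell as the mean expression of signature genes.

    ``expression`` is cells x genes.  ``center=True`` median-centers each
    gene across cells first (off by default for per-cell average
    expression).  An optional per-cell ``groups`` series is attached as a
    ``group`` column.
    """
    present = _present_signature(expression.columns, signature)
    sub = expression[present]
    if center:
        sub = sub.sub(sub.median(axis=0), axis=1)
    out = pd.DataFrame({"score": sub.mean(axis=1).astype(float)})
    if groups is not None:
        out["group"] = groups.reindex(out.index)
    return out


def stratify_median(table: pd.DataFrame) -> pd.DataFrame:
    """Assign ``high``/``low`` strata by the cohort median score.

    Scores strictly above the median are ``high``; at or below, ``low``
    (deterministic tie rule).  Returns a copy with a ``stratum`` column.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 units to stratify")
    out = table.copy()
    med = out["score"].median()
    out["stratum"] = np.where(out["score"] > med, "high", "low")
    return out


def differential_mean_test(
    table: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float, float]:
    """Welch two-sided t-test of signature scores between two groups.

    Returns ``(mean_a - mean_b, t, p)`` with Satterthwaite degrees of
    freedom.  Exact-equality fast path: if both groups are constant and
    equal, returns ``(0, 0, 1)``.
    """
    if "group" not in table.columns:
        raise ValueError("table has no 'group' column")
    a = table.loc[table["group"] == group_a, "score"].to_numpy(dtype=float)
    b = table.loc[table["group"] == group_b, "score"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 units")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if diff == 0:
            return 0.0, 0.0, 1.0
        return diff, float(np.sign(diff)) * np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(t), float(p)
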