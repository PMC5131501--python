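"""Pearson co-expression statistics over an expression matrix.

The central product is the *correlation table*: Pearson's r (with a
two-sided Student-t p-value on n-2 degrees of freedom) between a target
gene's expression vector and every other gene, ranked by r. Also provides
the >5%-zeros expression filter, per-gene mean/sd/cv summaries, pairwise
correlation matrices for small gene panels, and correlation across two
matrices sharing samples (e.g. miRNA vs mRNA).

p-values are never reported as exactly zero: they are floored at the
smallest positive normal double (:data:`P_FLOOR`) so downstream ranking
and FDR keep strict positivity. Ties in r are broken by lexicographic
feature id everywhere, which makes every rank reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CorrelationTable, ExpressionMatrix, GeneSummary
from .errors import DegenerateInputError, MissingFeatureError, SizeError

log = logging.getLogger(__name__)

#: Lower bound applied to every reported p-value.
P_FLOOR = float(np.finfo(np.float64).tiny)

SORT_ORDERS = ("by_r_desc", "by_abs_r_desc", "unsorted")


def filter_low_expression(
    matrix: ExpressionMatrix, max_zero_fraction: float = 0.05
) -> ExpressionMatrix:
    """Drop genes whose zero fraction exceeds ``max_zero_fraction``.

    The boundary is strict: a gene with zeros in *exactly* the allowed
    fraction of samples is retained ("more than 5%" excluded). Zeros are
    exact equality to 0.0 — the normalized input has no epsilon ambiguity.
    Idempotent; the sample set is never altered.
    """
    zero_frac = (matrix.data.to_numpy() == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    removed = int((~keep).sum())
    log.info(
        "filter_low_expression: removed %d genes (> %.1f%% zeros), retained %d",
        removed,
        100 * max_zero_fraction,
        int(keep.sum()),
    )
    return ExpressionMatrix(matrix.data.loc[keep])


def _pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    p = _p_from_r(np.array([r]), n)[0]
    return r, float(p), n


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from Pearson r via the t transform, floored at P_FLOOR."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    t = np.where(np.abs(r) >= 1.0, np.inf, t)
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return np.clip(p, P_FLOOR, 1.0)


def correlation_test(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value (t distribution, n-2 df).

    Raises :class:`SizeError` for n < 3 or unequal lengths, and
    :class:`DegenerateInputError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise SizeError("correlation_test requires two equal-length 1-D vectors")
    if len(x) < 3:
        raise SizeError(f"need at least 3 observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return _pearson_r_p(x, y)


def _apply_sort(frame: pd.DataFrame, sort: str) -> pd.DataFrame:
    if sort == "by_r_desc":
        frame = frame.sort_values(
            ["r", "feature"], ascending=[False, True], kind="mergesort"
        )
    elif sort == "by_abs_r_desc":
        frame = frame.assign(_abs=frame["r"].abs()).sort_values(
            ["_abs", "feature"], ascending=[False, True], kind="mergesort"
        ).drop(columns="_abs")
    elif sort != "unsorted":
        raise ValueError(f"unknown sort order {sort!r}; expected one of {SORT_ORDERS}")
    frame = frame.reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def build_correlation_table(
    matrix: ExpressionMatrix, target_id: str, sort: str = "by_r_desc"
) -> CorrelationTable:
    """Correlate the target gene against every other gene in the matrix.

    The target's own row (r identically 1) is excluded. Constant genes,
    for which r is undefined, are dropped with a log line. Ties in r break
    lexicographically by feature id.
    """
    if target_id not in matrix.data.index:
        raise MissingFeatureError(f"target {target_id!r} not in matrix")
    if matrix.n_samples < 3:
        raise SizeError("need at least 3 samples to build a correlation table")
    values = matrix.data.to_numpy(dtype=float)
    features = np.asarray(matrix.feature_ids, dtype=object)
    n = matrix.n_samples

    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    t_idx = int(np.flatnonzero(features == target_id)[0])
    if norms[t_idx] == 0:
        raise DegenerateInputError(f"target {target_id!r} has constant expression")
    constant = norms == 0
    n_constant = int(constant.sum())
    if n_constant:
        log.warning(
            "build_correlation_table: dropping %d constant genes", n_constant
        )
    keep = ~constant
    keep[t_idx] = False
    with np.errstate(invalid="ignore"):
        r = (centered[keep] @ centered[t_idx]) / (norms[keep] * norms[t_idx])
    r = np.clip(r, -1.0, 1.0)
    frame = pd.DataFrame(
        {
            "feature": features[keep],
            "r": r,
            "p": _p_from_r(r, n),
            "n": n,
        }
    )
    frame = _apply_sort(frame, sort)
    return CorrelationTable(target_id=target_id, frame=frame, order=sort)


def correlation_matrix(
    matrix: ExpressionMatrix, gene_list: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p for a gene panel.

    Returns ``(r, p)`` DataFrames indexed by the panel in the given order.
    r is symmetric with unit diagonal; the diagonal of p is NaN (a gene's
    correlation with itself is not a test).
    """
    sub = matrix.subset_features(list(gene_list))
    if sub.n_samples < 3:
        raise SizeError("need at least 3 samples")
    values = sub.data.to_numpy(dtype=float)
    if (np.ptp(values, axis=1) == 0).any():
        bad = sub.data.index[np.ptp(values, axis=1) == 0][0]
        raise DegenerateInputError(f"gene {bad!r} has constant expression")
    n = sub.n_samples
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    p = _p_from_r(r, n)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, np.nan)
    idx = pd.Index(gene_list, name="gene")
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def gene_summary(matrix: ExpressionMatrix, feature_id: str) -> GeneSummary:
    """Mean, sample sd (n-1 denominator) and cv = sd/mean for one gene.

    cv is NaN-flagged when the mean is zero.
    """
    v = matrix.vector(feature_id)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    if mean == 0:
        log.warning("gene_summary: mean of %r is zero; cv undefined", feature_id)
        return GeneSummary(feature_id, mean, sd, float("nan"))
    return GeneSummary(feature_id, mean, sd, sd / mean)


def cross_feature_correlation(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    features_a: list[str],
    features_b: list[str],
) -> pd.DataFrame:
    """Correlate features of one matrix against features of another.

    The two matrices are aligned on their shared sample ids (sorted for a
    reproducible order); at least 3 shared samples are required. Returns a
    DataFrame with one row per (a, b) pair: columns a, b, r, p, n.
    """
    shared = sorted(set(matrix_a.sample_ids) & set(matrix_b.sample_ids))
    if len(shared) < 3:
        raise SizeError(
            f"matrices share only {len(shared)} samples; need at least 3"
        )
    sub_a = matrix_a.subset_features(list(features_a)).subset_samples(shared)
    sub_b = matrix_b.subset_features(list(features_b)).subset_samples(shared)
    rows = []
    for fa in features_a:
        va = sub_a.vector(fa)
        for fb in features_b:
            vb = sub_b.vector(fb)
            r, p, n = correlation_test(va, vb)
            rows.append({"a": fa, "b": fb, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
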