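"""Correlation statistics and the sign-constrained edge screens.

Two statistics drive the ceRNA screen:

* Spearman's rank correlation (SCC) for the two repressive layers
  (lncRNA-miRNA and miRNA-mRNA), gated at SCC < -0.5 and p < 0.05 —
  a negative monotone association is read as a candidate targeting
  relationship.
* Pearson's product-moment correlation (PCC) for the lncRNA-mRNA layer,
  gated at PCC > 0.85 with no p gate — strong positive co-expression is
  the signature of two transcripts competing for the same miRNA pool.

Both p-values use the exact-under-normality t transform
``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom, two-sided;
|r| = 1 maps to p = 0. Spearman is computed as the Pearson correlation of
mid-ranks, which handles ties correctly and coincides with the classical
``1 - 6*sum(d^2)/(n(n^2-1))`` formula when there are none.

All thresholds are strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, ValidationError

LAYER_PAIRS = ("lnc_mir", "mir_mrna", "lnc_mrna")

#: default edge-screen thresholds
RHO_MAX = -0.5
EDGE_ALPHA = 0.05
R_MIN = 0.85


class ConstantVectorError(ValueError):
    """A correlation is undefined because one input vector is constant."""


@dataclass
class CorrelationEdge:
    """A screened transcript pair with its statistic and pass/fail flag."""

    id_a: str
    id_b: str
    layer_pair: str
    method: str  # "spearman" | "pearson"
    coefficient: float
    p_value: float
    passed: bool

    def __post_init__(self) -> None:
        if self.layer_pair not in LAYER_PAIRS:
            raise ValidationError(f"unknown layer_pair {self.layer_pair!r}")
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise ValidationError(f"coefficient out of [-1, 1]: {self.coefficient}")


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def t_pvalue(r: float, n: int) -> float:
    """Two-sided p for a correlation coefficient via the t transform (df = n-2)."""
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-transform p.

    Requires n >= 3 and non-constant inputs.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("pearson undefined for a constant vector")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = float(np.clip(r, -1.0, 1.0))
    return r, t_pvalue(r, len(x))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with a t-transform p.

    Requires n >= 4 and non-constant inputs.
    """
    x, y = _as_vector(x, "x"), _as_vector(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return pearson(rx, ry)


def permutation_pvalue(x, y, method: str = "spearman", n_resamples: int = 20000,
                       seed: int | None = 0) -> float:
    """Two-sided permutation p-value for the chosen correlation (cross-check).

    Exhaustive over all pairings when n <= 7, Monte-Carlo otherwise.
    """
    stat_fn = spearman if method == "spearman" else pearson

    def _stat(xp, yp):
        return stat_fn(xp, yp)[0]

    res = stats.permutation_test(
        (x, y), _stat, permutation_type="pairings", n_resamples=n_resamples,
        alternative="two-sided", rng=seed,
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# vectorized batch screens
# ---------------------------------------------------------------------------

def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix between two (features × n) arrays.

    Rows with zero variance yield NaN (handled by the callers).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        an = ac / np.sqrt((ac * ac).sum(axis=1, keepdims=True))
        bn = bc / np.sqrt((bc * bc).sum(axis=1, keepdims=True))
        rho = an @ bn.T
    return np.clip(rho, -1.0, 1.0)


def _pvalue_matrix(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def _check_shared_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> None:
    if a.sample_ids != b.sample_ids:
        raise ValidationError("matrices must share an identical ordered sample set")


def _rank_rows(arr: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, arr)


def screen_negative_pairs(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    whitelist: Optional[Iterable[tuple[str, str]]] = None,
    rho_max: float = RHO_MAX,
    alpha: float = EDGE_ALPHA,
    layer_pair: str = "lnc_mir",
) -> list[CorrelationEdge]:
    """Spearman screen for negatively correlated (a, b) pairs.

    Candidates are all-vs-all, or the given whitelist of (id_a, id_b) pairs
    (e.g. sequence-predicted targets). An edge passes when
    ``rho < rho_max`` and ``p < alpha`` (both strict). Correlations are
    computed over the pooled LE+HE samples. Constant features are skipped
    with a warning; all computed edges are returned, passing or not.
    """
    _check_shared_samples(matrix_a, matrix_b)
    if not matrix_a.feature_ids or not matrix_b.feature_ids:
        return []
    n = len(matrix_a.sample_ids)
    ra = _rank_rows(matrix_a.values.to_numpy(dtype=float))
    rb = _rank_rows(matrix_b.values.to_numpy(dtype=float))
    rho = _corr_matrix(ra, rb)
    pmat = _pvalue_matrix(np.nan_to_num(rho), n)

    ids_a, ids_b = matrix_a.feature_ids, matrix_b.feature_ids
    idx_a = {f: i for i, f in enumerate(ids_a)}
    idx_b = {f: i for i, f in enumerate(ids_b)}
    if whitelist is None:
        candidates = [(a, b) for a in ids_a for b in ids_b]
    else:
        candidates = sorted(set(whitelist))
        unknown = [(a, b) for a, b in candidates if a not in idx_a or b not in idx_b]
        candidates = [c for c in candidates if c not in set(unknown)]

    edges: list[CorrelationEdge] = []
    for a, b in candidates:
        r = rho[idx_a[a], idx_b[b]]
        if np.isnan(r):
            warnings.warn(f"skipping pair ({a}, {b}): constant expression vector")
            continue
        p = float(pmat[idx_a[a], idx_b[b]])
        edges.append(
            CorrelationEdge(a, b, layer_pair, "spearman", float(r), p,
                            passed=bool(r < rho_max and p < alpha))
        )
    return edges


def screen_positive_pairs(
    matrix_lnc: ExpressionMatrix,
    matrix_mrna: ExpressionMatrix,
    candidate_pairs: Iterable[tuple[str, str]],
    r_min: float = R_MIN,
) -> list[CorrelationEdge]:
    """Pearson screen for positively co-expressed lncRNA-mRNA pairs.

    ``passed`` requires ``r > r_min`` (strict); no p gate is applied on this
    layer. The p-value is still computed and stored for auditability.
    """
    _check_shared_samples(matrix_lnc, matrix_mrna)
    if not matrix_lnc.feature_ids or not matrix_mrna.feature_ids:
        return []
    n = len(matrix_lnc.sample_ids)
    a = matrix_lnc.values.to_numpy(dtype=float)
    b = matrix_mrna.values.to_numpy(dtype=float)
    rho = _corr_matrix(a, b)
    pmat = _pvalue_matrix(np.nan_to_num(rho), n)
    idx_a = {f: i for i, f in enumerate(matrix_lnc.feature_ids)}
    idx_b = {f: i for i, f in enumerate(matrix_mrna.feature_ids)}

    edges: list[CorrelationEdge] = []
    for lnc, mrna in sorted(set(candidate_pairs)):
        if lnc not in idx_a or mrna not in idx_b:
            continue
        r = rho[idx_a[lnc], idx_b[mrna]]
        if np.isnan(r):
            warnings.warn(f"skipping pair ({lnc}, {mrna}): constant expression vector")
            continue
        p = float(pmat[idx_a[lnc], idx_b[mrna]])
        edges.append(
            CorrelationEdge(lnc, mrna, "lnc_mrna", "pearson", float(r), p,
                            passed=bool(r > r_min))
        )
    return edges


def passed_edges(edges: Sequence[CorrelationEdge]) -> list[CorrelationEdge]:
    return [e for e in edges if e.passed]
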