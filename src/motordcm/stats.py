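"""Connection-wise group inference and covariate-adjusted correlations.

Each connection's posterior-mean coupling is tested for a between-group
difference with an ANCOVA: an ordinary-least-squares fit with group dummy
codes plus nuisance covariates (age and education continuous; gender and
site categorical), where the group effect is the extra-sum-of-squares
F test of the group dummies.  Family-wise control is Bonferroni over the
number of connections (30 intrinsic + 17 modulatory = 47 by default);
significant connections are followed up with three pairwise contrasts on
the pooled ANCOVA residual error, Bonferroni-corrected for the three
pairs.  Pearson partial correlation residualises both variables on the
covariates before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_COVARIATES = ("age", "gender", "site", "education")
N_CONNECTION_TESTS = 47  # 30 intrinsic + 17 modulatory
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    connection: str
    F: float
    df: tuple[int, int]
    p: float
    significant_bonferroni: bool


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    untestable: bool = False


def _dummy(values: pd.Series) -> np.ndarray:
    """Treatment-coded dummies (first level dropped), levels sorted."""
    levels = sorted(pd.unique(values.astype(str)))
    return np.column_stack(
        [(values.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(values), 0))


def build_design(
    table: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    group_col: str = "group",
    categorical=("gender", "site"),
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(group dummies, nuisance matrix incl. intercept, group levels)."""
    groups = sorted(pd.unique(table[group_col].astype(str)))
    G = np.column_stack(
        [(table[group_col].astype(str) == g).to_numpy(float) for g in groups[1:]]
    ) if len(groups) > 1 else np.empty((len(table), 0))
    cols = [np.ones((len(table), 1))]
    for cov in covariates:
        if cov in categorical:
            cols.append(_dummy(table[cov]))
        else:
            cols.append(table[cov].to_numpy(float)[:, None])
    X0 = np.column_stack(cols)
    return G, X0, groups


def _check_rank(X: np.ndarray, names_hint: str) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix ({names_hint})")


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def ancova_f(y: np.ndarray, G: np.ndarray, X0: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """Extra-sum-of-squares F test for the group dummies.

    Full model [X0 G] vs reduced [X0]; returns (F, (df1, df2), p).
    """
    n = len(y)
    X_full = np.column_stack([X0, G])
    _check_rank(X_full, "covariates + group dummies")
    df1 = G.shape[1]
    df2 = n - X_full.shape[1]
    if df1 == 0 or df2 <= 0:
        raise ValueError("degenerate design: no group contrast or no residual df")
    sse_full = _sse(y, X_full)
    sse_red = _sse(y, X0)
    num = (sse_red - sse_full) / df1
    den = sse_full / df2
    F = num / den if den > 0 else (0.0 if num <= 0 else np.inf)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def bonferroni_threshold(n_tests: int, alpha: float = ALPHA_DEFAULT) -> float:
    """Per-test level alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def ancova_per_connection(
    table: pd.DataFrame,
    connections: list[str] | None = None,
    *,
    group_col: str = "group",
    covariates=DEFAULT_COVARIATES,
    alpha: float = ALPHA_DEFAULT,
    n_tests: int | None = None,
) -> list[TestResult]:
    """Group ANCOVA for every connection column of a parameter table.

    ``connections`` defaults to all columns not named as group or
    covariates.  Significance is at ``alpha / n_tests`` with ``n_tests``
    defaulting to the number of connections tested.
    """
    if table[group_col].isna().any():
        raise ValueError("missing group labels")
    if connections is None:
        reserved = {group_col, *covariates}
        connections = [c for c in table.columns if c not in reserved]
    G, X0, groups = build_design(table, covariates, group_col)
    if len(groups) < 3:
        raise ValueError("at least 3 groups are required")
    n_tests = n_tests or len(connections)
    thresh = bonferroni_threshold(n_tests, alpha)
    out = []
    for conn in connections:
        y = table[conn].to_numpy(float)
        F, df, p = ancova_f(y, G, X0)
        out.append(TestResult(conn, F, df, p, bool(p < thresh)))
    return out


def pairwise_posthoc(
    table: pd.DataFrame,
    connection: str,
    *,
    group_col: str = "group",
    covariates=DEFAULT_COVARIATES,
    welch: bool = False,
) -> list[PairwiseResult]:
    """Three pairwise group contrasts, Bonferroni-corrected (p x 3, capped).

    Default: contrasts of adjusted group means on the pooled residual error
    of the full ANCOVA model.  ``welch=True`` switches to Welch two-sample
    t-tests on the raw values.
    """
    groups = sorted(pd.unique(table[group_col].astype(str)))
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    n_pairs = max(len(pairs), 1)
    results = []
    if welch:
        for a, b in pairs:
            ya = table.loc[table[group_col].astype(str) == a, connection].to_numpy(float)
            yb = table.loc[table[group_col].astype(str) == b, connection].to_numpy(float)
            if len(ya) < 2 or len(yb) < 2:
                results.append(PairwiseResult(a, b, np.nan, 0, np.nan, np.nan, True))
                continue
            t, p = sps.ttest_ind(ya, yb, equal_var=False)
            df = len(ya) + len(yb) - 2
            results.append(PairwiseResult(a, b, float(t), df, float(p),
                                          min(1.0, float(p) * n_pairs)))
        return results

    G, X0, _ = build_design(table, covariates, group_col)
    X = np.column_stack([X0, G])
    _check_rank(X, "covariates + group dummies")
    y = table[connection].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df2 = len(y) - X.shape[1]
    mse = float(resid @ resid) / df2
    XtX_inv = np.linalg.inv(X.T @ X)
    k0 = X0.shape[1]
    counts = table[group_col].astype(str).value_counts()
    for a, b in pairs:
        if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
            results.append(PairwiseResult(a, b, np.nan, 0, np.nan, np.nan, True))
            continue
        contrast = np.zeros(X.shape[1])
        ia, ib = groups.index(a), groups.index(b)
        if ia > 0:
            contrast[k0 + ia - 1] = 1.0
        if ib > 0:
            contrast[k0 + ib - 1] = -1.0
        est = float(contrast @ beta)
        se = float(np.sqrt(mse * contrast @ XtX_inv @ contrast))
        t = est / se if se > 0 else 0.0
        p = 2.0 * float(sps.t.sf(abs(t), df2))
        results.append(PairwiseResult(a, b, t, df2, p, min(1.0, p * n_pairs)))
    return results


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Pearson correlation of x and y after projecting out covariates.

    Both variables are residualised on [1, covariates] by least squares;
    p comes from the t transform with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        Z = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    bx, *_ = np.linalg.lstsq(Z, x, rcond=None)
    by, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx = x - Z @ bx
    ry = y - Z @ by
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = min(max(r, -0.999999999999), 0.999999999999)
    t = r_ * np.sqrt(df / (1.0 - r_**2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return r, p, n


def results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "connection": [r.connection for r in results],
            "F": [r.F for r in results],
            "df1": [r.df[0] for r in results],
            "df2": [r.df[1] for r in results],
            "p": [r.p for r in results],
            "significant_bonferroni": [r.significant_bonferroni for r in results],
        }
    )
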