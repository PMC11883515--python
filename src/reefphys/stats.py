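"""Regional comparison statistics.

The comparison layer used on the extracted traits: Shapiro-Wilk normality
gating, Tukey's ladder-of-powers transformation, factorial linear models
(temperature x region, with body mass as a covariate for thermal limits),
a permutation MANOVA (pseudo-F on a Euclidean distance matrix with a
permutation null), estimated-marginal-mean style pairwise contrasts, the
Benjamini-Hochberg FDR step-up, and two-sample tests.

The model-selection policy mirrors common practice for factorial ecology
designs: fit the linear model; if its residuals fail the Shapiro-Wilk gate,
transform the response with the Tukey ladder and refit; if the residuals
still fail, fall back to the PERMANOVA. :func:`auto_compare` implements this
cascade explicitly and records every step it took.

Standard tests (Shapiro-Wilk, Student's t, Mann-Whitney U) and the OLS /
ANOVA machinery are delegated to scipy and statsmodels; the permutation
MANOVA, FDR step-up, ladder search and contrast layer are implemented here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "normality_gate",
    "tukey_ladder",
    "linear_model_anova",
    "permanova",
    "pairwise_contrasts",
    "bh_fdr",
    "two_sample_test",
    "auto_compare",
]

#: Tukey ladder-of-powers grid; 0 denotes the log transform
LADDER_GRID = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)

#: identity preference: keep lambda = 1 unless another rung improves the
#: Shapiro-Wilk W by more than this margin (on already-normal data the W of
#: neighbouring rungs differs only by sampling noise, and an untransformed
#: response is always easier to interpret)
LADDER_W_MARGIN = 0.01


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    df: float | tuple | None
    p_raw: float
    p_adjusted: float | None = None
    n_perm: int | None = None
    method_notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normality gate and transformation


def normality_gate(sample, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; pass means "no evidence against normality".

    Returns (W, p, passed) with passed = p > alpha.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p > alpha)


def _ladder_transform(y: np.ndarray, lam: float) -> np.ndarray:
    if lam > 0:
        return y**lam
    if lam == 0:
        return np.log(y)
    return -(y**lam)  # negate so the transform stays order-preserving


def tukey_ladder(y) -> tuple[float, np.ndarray, dict]:
    """Pick the ladder-of-powers transform that best normalises ``y``.

    Scans lambda over ``LADDER_GRID`` (0 = log; negative powers are negated
    to preserve order) and keeps the lambda with the largest Shapiro-Wilk W
    of the transformed sample, breaking ties — including near-ties within
    ``LADDER_W_MARGIN`` — toward lambda = 1 (identity). Non-positive
    samples are shifted by ``1 - min(y)`` first; the shift is recorded in
    the returned notes.
    """
    y = np.asarray(y, dtype=float)
    notes: dict = {}
    if y.min() <= 0:
        shift = 1.0 - y.min()
        y = y + shift
        notes["shift"] = float(shift)
    best_lam, best_w = 1.0, -np.inf
    w_identity = -np.inf
    for lam in LADDER_GRID:
        z = _ladder_transform(y, lam)
        if not np.all(np.isfinite(z)) or np.ptp(z) == 0:
            continue
        try:
            w, _ = sps.shapiro(z)
        except ValueError:
            continue
        if lam == 1.0:
            w_identity = w
        if w > best_w:
            best_lam, best_w = lam, w
    if w_identity >= best_w - LADDER_W_MARGIN:
        best_lam = 1.0
    notes["lambda"] = float(best_lam)
    return best_lam, _ladder_transform(y, best_lam), notes


# ---------------------------------------------------------------------------
# linear models


def linear_model_anova(
    data: pd.DataFrame,
    response: str,
    temp_col: str = "acclimation_temp",
    region_col: str = "region",
    mass_col: str | None = None,
    ss_type: int = 2,
):
    """Factorial OLS: response ~ C(temperature) * C(region) [+ mass].

    Temperature is treated as a categorical factor (discrete acclimation
    groups). Returns (anova_table, coefficient_table, fitted_model) with
    the requested sums-of-squares type (Type II by default; Type I
    available). If some temperature x region cell is empty the interaction
    is inestimable; it is dropped with a warning and the additive model is
    fitted instead.
    """
    for col in (temp_col, region_col):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    cells = pd.crosstab(data[temp_col], data[region_col])
    interaction_ok = (cells.to_numpy() > 0).all()
    rhs = f"C({temp_col}) * C({region_col})" if interaction_ok else (
        f"C({temp_col}) + C({region_col})"
    )
    if not interaction_ok:
        logger.warning(
            "empty %s x %s cell(s): interaction dropped from the model",
            temp_col, region_col,
        )
    if mass_col is not None:
        rhs += f" + {mass_col}"
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    table = anova_lm(model, typ=ss_type)
    coefs = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "t": model.tvalues, "p": model.pvalues}
    )
    return table, coefs, model


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_centered(responses: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix of squared Euclidean distances."""
    x = responses - responses.mean(axis=0)
    # for Euclidean distances G equals the centred Gram matrix X X'
    return x @ x.T


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _design_matrices(factors: pd.DataFrame) -> tuple[list[np.ndarray], list[str], list[int]]:
    """Nested model matrices for sequential SS: intercept, then each main
    effect, then (for two factors) their interaction."""
    n = len(factors)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = []
    for col in factors.columns:
        d = pd.get_dummies(factors[col].astype("category"), drop_first=True)
        blocks.append(d.to_numpy(dtype=float))
        names.append(str(col))
    if factors.shape[1] == 2:
        a = pd.get_dummies(factors.iloc[:, 0].astype("category"), drop_first=True)
        b = pd.get_dummies(factors.iloc[:, 1].astype("category"), drop_first=True)
        inter = np.einsum("ij,ik->ijk", a.to_numpy(float), b.to_numpy(float))
        inter = inter.reshape(n, -1)
        if inter.shape[1] > 0:
            blocks.append(inter)
            names.append(":".join(map(str, factors.columns)))
    mats, dfs = [], []
    acc = np.empty((n, 0))
    prev_rank = 0
    for blk in blocks:
        acc = np.hstack([acc, blk])
        rank = np.linalg.matrix_rank(acc)
        mats.append(acc.copy())
        dfs.append(rank - prev_rank)
        prev_rank = rank
    return mats, names, dfs[1:]  # drop the intercept "term"


def permanova(
    responses,
    factors,
    n_perm: int = 9999,
    seed: int = 0,
    *,
    exact: bool = False,
):
    """Permutation MANOVA on Euclidean distances (pseudo-F partition).

    ``responses`` is (n,) or (n, p); ``factors`` a single label array, or a
    data frame / dict of one or two factors (two factors add their
    interaction, sequential SS). The pseudo-F for each term comes from the
    trace partition of the Gower-centred matrix under nested hat matrices —
    for Euclidean distances and a univariate response this is numerically
    identical to the classical ANOVA F. The permutation null permutes raw
    observations (rows); p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    ``exact=True`` (single two-level factor only) enumerates every distinct
    assignment of observations to groups instead of sampling permutations.
    Returns a single :class:`ComparisonResult` for a one-factor design,
    else a list with one result per term.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if isinstance(factors, (pd.Series, np.ndarray, list, tuple)):
        factors = pd.DataFrame({"factor": np.asarray(factors)})
    elif isinstance(factors, dict):
        factors = pd.DataFrame(factors)
    factors = factors.reset_index(drop=True)
    n = len(y)
    if len(factors) != n:
        raise ValueError("responses and factors must align")
    for col in factors.columns:
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has a single level")

    g = _gower_centered(y)
    ss_total = float(np.trace(g))
    if ss_total <= 0:
        raise ValueError("all observations identical: pseudo-F undefined")

    mats, names, term_dfs = _design_matrices(factors)
    hats = [_hat(m) for m in mats]
    h_full = hats[-1]
    df_res = n - int(np.linalg.matrix_rank(mats[-1]))
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    i_n = np.eye(n)

    def term_f(gmat: np.ndarray) -> np.ndarray:
        ss_res = float(np.sum((i_n - h_full) * gmat.T))
        fs = np.empty(len(names))
        for j in range(len(names)):
            ss_j = float(np.sum((hats[j + 1] - hats[j]) * gmat.T))
            fs[j] = (ss_j / term_dfs[j]) / (ss_res / df_res)
        return fs

    f_obs = term_f(g)
    tol = 1e-9 * (1.0 + np.abs(f_obs))

    if exact:
        if factors.shape[1] != 1 or factors.iloc[:, 0].nunique() != 2:
            raise ValueError("exact enumeration supports a single 2-level factor")
        labels = factors.iloc[:, 0].to_numpy()
        level = labels[0]
        n1 = int(np.sum(labels == level))
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            perm_labels = np.full(n, "", dtype=object)
            perm_labels[:] = [lab for lab in labels if lab != level][0]
            perm_labels[list(combo)] = level
            # permuting labels is equivalent to permuting rows of G
            fm = pd.DataFrame({factors.columns[0]: perm_labels})
            mats_p, _, dfs_p = _design_matrices(fm)
            h1 = _hat(mats_p[-1])
            ss_res = float(np.sum((i_n - h1) * g.T))
            ss_j = float(np.sum((h1 - hats[0]) * g.T))
            f = (ss_j / dfs_p[0]) / (ss_res / df_res)
            count += f >= f_obs[0] - tol[0]
            total += 1
        result = ComparisonResult(
            test_name=f"permanova[{names[0]}]",
            statistic=float(f_obs[0]),
            df=(term_dfs[0], df_res),
            p_raw=count / total,
            n_perm=total,
            method_notes={"scheme": "exact enumeration", "splits": total},
        )
        return result

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += term_f(g[np.ix_(perm, perm)]) >= f_obs - tol
    p = (1.0 + exceed) / (1.0 + n_perm)
    results = [
        ComparisonResult(
            test_name=f"permanova[{names[j]}]",
            statistic=float(f_obs[j]),
            df=(term_dfs[j], df_res),
            p_raw=float(p[j]),
            n_perm=n_perm,
            method_notes={"scheme": "unrestricted raw permutation", "seed": seed},
        )
        for j in range(len(names))
    ]
    return results[0] if len(results) == 1 else results


# ---------------------------------------------------------------------------
# contrasts, FDR, two-sample tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, original order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def pairwise_contrasts(
    values,
    groups,
    *,
    method: str = "lm",
    n_perm: int = 999,
    seed: int = 0,
    adjust: str = "fdr",
) -> list[ComparisonResult]:
    """All pairwise group contrasts with FDR adjustment.

    ``method="lm"``: estimated-marginal-mean style contrasts of cell means
    using the pooled residual variance of the one-way model (t statistics,
    residual df). ``method="permanova"``: a two-group permutation test per
    pair. Both report raw and BH-adjusted p values.
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("pairwise contrasts need at least 2 groups")
    pairs = list(itertools.combinations(levels, 2))
    results: list[ComparisonResult] = []
    if method == "lm":
        grand_df = len(y) - len(levels)
        if grand_df <= 0:
            raise ValueError("no residual degrees of freedom for contrasts")
        means = {g: y[labels == g].mean() for g in levels}
        ns = {g: int(np.sum(labels == g)) for g in levels}
        sse = sum(np.sum((y[labels == g] - means[g]) ** 2) for g in levels)
        mse = sse / grand_df
        for a, b in pairs:
            se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            tstat = (means[a] - means[b]) / se if se > 0 else float("inf")
            p = 2.0 * sps.t.sf(abs(tstat), grand_df)
            results.append(
                ComparisonResult(
                    test_name=f"contrast[{a} - {b}]",
                    statistic=float(tstat),
                    df=grand_df,
                    p_raw=float(p),
                    method_notes={"method": "cell-mean t, pooled residual variance"},
                )
            )
    elif method == "permanova":
        rng = np.random.default_rng(seed)
        for a, b in pairs:
            mask = (labels == a) | (labels == b)
            res = permanova(
                y[mask], labels[mask], n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            res.test_name = f"permanova[{a} - {b}]"
            results.append(res)
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    adj = bh_fdr([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.method_notes["adjust"] = adjust
    return results


def two_sample_test(x, y, flavor: str = "t", *, equal_var: bool = True) -> ComparisonResult:
    """Two-tailed two-sample comparison.

    ``flavor="t"``: Student's pooled-variance t by default (``equal_var=False``
    for Welch). ``flavor="mann_whitney"``: exact null distribution when the
    smaller sample has at most 8 observations, normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if flavor == "t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t test needs n >= 2 per group")
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero variance in both groups")
        stat, p = sps.ttest_ind(x, y, equal_var=equal_var)
        df = len(x) + len(y) - 2 if equal_var else None
        return ComparisonResult(
            test_name="t" if equal_var else "welch_t",
            statistic=float(stat),
            df=df,
            p_raw=float(p),
            method_notes={"two_tailed": True, "equal_var": equal_var},
        )
    if flavor == "mann_whitney":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("Mann-Whitney needs n >= 1 per group")
        method = "exact" if min(len(x), len(y)) <= 8 else "asymptotic"
        try:
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:
            # exact method refuses ties; fall back to the tie-corrected normal
            method = "asymptotic"
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return ComparisonResult(
            test_name="mann_whitney_u",
            statistic=float(stat),
            df=None,
            p_raw=float(p),
            method_notes={"two_tailed": True, "method": method},
        )
    raise ValueError(f"unknown test flavor {flavor!r}")


# ---------------------------------------------------------------------------
# model-selection cascade


@dataclass
class AutoComparison:
    """Outcome of the gate -> transform -> PERMANOVA cascade."""

    method: str  # "lm" | "lm_transformed" | "permanova"
    anova_table: pd.DataFrame | None
    permanova_results: list[ComparisonResult] | None
    shapiro: tuple[float, float, bool]
    notes: dict = field(default_factory=dict)


def auto_compare(
    data: pd.DataFrame,
    response: str,
    temp_col: str = "acclimation_temp",
    region_col: str = "region",
    mass_col: str | None = None,
    *,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
) -> AutoComparison:
    """The logged model-selection policy applied to one trait.

    Fit the factorial linear model; if the residuals fail the Shapiro-Wilk
    gate at ``alpha``, Tukey-ladder transform the response and refit; if
    they still fail, run the PERMANOVA on the untransformed response.
    """
    table, _coefs, model = linear_model_anova(
        data, response, temp_col, region_col, mass_col
    )
    gate = normality_gate(model.resid, alpha)
    if gate[2]:
        return AutoComparison("lm", table, None, gate, {"transform": None})
    lam, transformed, tnotes = tukey_ladder(data[response].to_numpy())
    d2 = data.copy()
    tcol = f"{response}_ladder"
    d2[tcol] = transformed
    table2, _c2, model2 = linear_model_anova(d2, tcol, temp_col, region_col, mass_col)
    gate2 = normality_gate(model2.resid, alpha)
    if gate2[2]:
        return AutoComparison(
            "lm_transformed", table2, None, gate2, {"transform": tnotes}
        )
    res = permanova(
        data[response].to_numpy(),
        data[[temp_col, region_col]],
        n_perm=n_perm,
        seed=seed,
    )
    if isinstance(res, ComparisonResult):
        res = [res]
    return AutoComparison(
        "permanova", None, res, gate2,
        {"transform": tnotes, "reason": "residuals non-normal after transform"},
    )
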