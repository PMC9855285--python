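"""Inferential layer: mixed repeated-measures ANOVA/ANCOVA, t-tests, JZS Bayes factors.

The split-plot (mixed) ANOVA is computed by the univariate contrast approach:
within-subject effects are evaluated on orthonormal contrast variables of the
repeated measures, between-subject effects on subject means, each with its
own error stratum.  Effects use Type III sums of squares with sum-to-zero
coding, matching the JASP/SPSS convention; degrees of freedom are
uncorrected (no sphericity adjustment) by default, with Greenhouse-Geisser
available for the one-within design.

The Bayes factor for t-tests uses the Jeffreys-Zellner-Siow default prior
(Cauchy with scale r on the standardized effect) and is evaluated by adaptive
quadrature of the marginal likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, linalg
from scipy import stats as sps

__all__ = [
    "StatResult",
    "rm_anova_mixed",
    "rm_anova_two_within",
    "ancova_mixed",
    "independent_t",
    "independent_t_from_stats",
    "paired_t",
    "pearson_r",
    "jzs_bf_ttest",
]


@dataclass
class StatResult:
    """One test's statistics, formatted the way ERP papers report them."""

    test: str                       # rm_anova | ancova | paired_t | independent_t | pearson_r
    effect: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float | None = None
    effect_size_type: str | None = None   # "partial_eta_sq" | "cohen_d" | None
    bf10: float | None = None
    notes: dict = field(default_factory=dict)

    def __str__(self) -> str:
        letter = {"rm_anova": "F", "ancova": "F", "paired_t": "t",
                  "independent_t": "t", "pearson_r": "r"}[self.test]
        df = ", ".join(f"{d:g}" for d in self.df)
        parts = [f"{self.effect}: {letter}({df}) = {self.statistic:.3f}, p = {self.p:.3f}"]
        if self.effect_size is not None:
            label = {"partial_eta_sq": "eta_p^2", "cohen_d": "d"}.get(
                self.effect_size_type or "", self.effect_size_type)
            parts.append(f"{label} = {self.effect_size:.3f}")
        if self.bf10 is not None:
            parts.append(f"BF10 = {self.bf10:.3f}")
        return ", ".join(parts)


# ---------------------------------------------------------------------------
# linear-model helpers

def _as_matrix(values) -> np.ndarray:
    Y = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if Y.ndim != 2:
        raise ValueError("values must be a 2-D participants x cells table")
    if np.isnan(Y).any():
        raise ValueError("missing cells in the repeated-measures table (no imputation)")
    return Y

def _sum_code(group) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(group).astype(str).to_numpy()
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    G = np.zeros((len(labels), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        G[labels == lev, j] = 1.0
    G[labels == levels[-1], :] = -1.0
    return G, levels

def _fit(X: np.ndarray, y: np.ndarray):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear predictors, e.g. covariate confounded with group)")
    XtXi = np.linalg.inv(X.T @ X)
    b = XtXi @ X.T @ y
    resid = y - X @ b
    return b, XtXi, float(resid @ resid)

def _hyp_ss(b: np.ndarray, XtXi: np.ndarray, cols: Sequence[int]) -> float:
    """Type III SS for H0: b[cols] = 0 in the full model."""
    L = np.eye(len(b))[list(cols)]
    Lb = L @ b
    return float(Lb @ np.linalg.solve(L @ XtXi @ L.T, Lb))

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix, orthonormal rows orthogonal to the unit vector."""
    return linalg.helmert(k, full=False)


def _f_result(test: str, effect: str, ss_eff: float, df_eff: float,
              ss_err: float, df_err: float, tiny: float = 0.0) -> StatResult:
    # SS below numerical round-off of the data scale are exact zeros
    ss_eff = 0.0 if ss_eff <= tiny else ss_eff
    ss_err = 0.0 if ss_err <= tiny else ss_err
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else 0.0
    p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return StatResult(test=test, effect=effect, statistic=float(F),
                      df=(float(df_eff), float(df_err)), p=p,
                      effect_size=float(eta), effect_size_type="partial_eta_sq",
                      notes={"ss_effect": ss_eff, "ss_error": ss_err})


def _mixed_anova_core(Y: np.ndarray, group, covariate=None, test_name: str = "rm_anova",
                      contrast_blocks: dict[str, np.ndarray] | None = None
                      ) -> dict[str, StatResult]:
    """Shared split-plot machinery.

    ``contrast_blocks`` maps within-effect name -> orthonormal contrast matrix
    (rows are unit-norm cell-weight vectors orthogonal to the constant).
    Each block gets its own error stratum.  Between part runs on subject
    means.  With a covariate, both parts gain a centred-covariate column
    (the within parts thereby test/partial the covariate x effect terms).
    """
    n, k = Y.shape
    G, levels = _sum_code(group)
    g = len(levels)
    if np.min(np.bincount(pd.factorize(pd.Series(group).astype(str))[0])) < 2:
        raise ValueError("need at least two participants per group")
    X = np.column_stack([np.ones(n), G])
    grp_cols = list(range(1, 1 + G.shape[1]))
    tiny = max(float(np.sum(Y * Y)), 1.0) * 1e-12
    n_cov = 0
    if covariate is not None:
        cov = np.asarray(covariate, float)
        if cov.shape != (n,):
            raise ValueError("covariate must be one value per participant")
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariate must be finite")
        if np.ptp(cov) == 0:
            raise ValueError("constant covariate carries no information")
        X = np.column_stack([X, cov - cov.mean()])
        n_cov = 1
    results: dict[str, StatResult] = {}

    # between-subject stratum: subject means, scaled back by k
    m = Y.mean(axis=1)
    b, XtXi, sse = _fit(X, m)
    df_bs_err = n - g - n_cov
    ss_group = k * _hyp_ss(b, XtXi, grp_cols)
    results["group"] = _f_result(test_name, "group", ss_group, g - 1,
                                 k * sse, df_bs_err, tiny)
    if n_cov:
        ss_cov = k * _hyp_ss(b, XtXi, [X.shape[1] - 1])
        results["covariate"] = _f_result(test_name, "covariate", ss_cov, 1,
                                         k * sse, df_bs_err, tiny)

    # within-subject strata: one per contrast block
    if contrast_blocks is None:
        contrast_blocks = {"condition": _orthonormal_contrasts(k)}
    for name, C in contrast_blocks.items():
        Z = Y @ C.T
        q = C.shape[0]
        ss_eff = ss_int = sse_w = 0.0
        for j in range(q):
            b, XtXi, sse_j = _fit(X, Z[:, j])
            ss_eff += _hyp_ss(b, XtXi, [0])
            ss_int += _hyp_ss(b, XtXi, grp_cols)
            sse_w += sse_j
        df_err = q * (n - g - n_cov)
        results[name] = _f_result(test_name, name, ss_eff, q, sse_w, df_err, tiny)
        results[f"{name}*group"] = _f_result(test_name, f"{name}*group",
                                             ss_int, q * (g - 1), sse_w, df_err, tiny)
    return results


def rm_anova_mixed(values, group, sphericity_correction: str = "none"
                   ) -> dict[str, StatResult]:
    """Mixed repeated-measures ANOVA: one within factor x one between factor.

    Parameters
    ----------
    values : DataFrame or ndarray, shape (n_participants, n_conditions)
        One row per participant, one column per within-factor level
        (complete; missing cells raise).
    group : sequence of length n_participants
        Between-subject group labels (two or more levels).
    sphericity_correction : {"none", "gg"}
        "gg" additionally reports Greenhouse-Geisser-corrected dfs and
        p-values in the ``notes`` of the within-effect results.

    Returns a dict with keys ``condition``, ``group``, ``condition*group``.
    """
    Y = _as_matrix(values)
    res = _mixed_anova_core(Y, group)
    if sphericity_correction == "gg":
        eps = _gg_epsilon(Y)
        for key in ("condition", "condition*group"):
            r = res[key]
            df1, df2 = r.df
            r.notes["gg_epsilon"] = eps
            r.notes["gg_df"] = (df1 * eps, df2 * eps)
            r.notes["gg_p"] = float(sps.f.sf(r.statistic, df1 * eps, df2 * eps))
    elif sphericity_correction != "none":
        raise ValueError(f"unknown sphericity correction {sphericity_correction!r}")
    return res


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled covariance of the measures."""
    k = Y.shape[1]
    S = np.cov(Y, rowvar=False)
    C = _orthonormal_contrasts(k)
    V = C @ S @ C.T
    tr = np.trace(V)
    return float(tr ** 2 / ((k - 1) * np.sum(V * V)))


def rm_anova_two_within(values, group,
                        factor_names: tuple[str, str] = ("condition", "cue_side"),
                        levels: tuple[int, int] = (3, 2)) -> dict[str, StatResult]:
    """Mixed ANOVA with two crossed within factors and one between factor.

    ``values`` columns hold the a x b cells with the first factor varying
    slowest.  Used for the rejection-rate analysis
    (condition x attended hemifield x group).
    """
    a, b = levels
    Y = _as_matrix(values)
    if Y.shape[1] != a * b:
        raise ValueError(f"expected {a * b} cell columns, got {Y.shape[1]}")
    Ca, Cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    ja, jb = np.full((1, a), 1 / np.sqrt(a)), np.full((1, b), 1 / np.sqrt(b))
    na, nb = factor_names
    blocks = {
        na: np.kron(Ca, jb),
        nb: np.kron(ja, Cb),
        f"{na}*{nb}": np.kron(Ca, Cb),
    }
    return _mixed_anova_core(Y, group, contrast_blocks=blocks)


def ancova_mixed(values, group, covariate) -> dict[str, StatResult]:
    """Mixed rm-ANCOVA with a participant-level covariate (e.g. VWM capacity).

    The covariate is centred and enters both strata, so the within-subject
    error loses one df per contrast: with 36 participants and 3 conditions
    the condition x group interaction is tested on (2, 66) df.
    """
    Y = _as_matrix(values)
    return _mixed_anova_core(Y, group, covariate=covariate, test_name="ancova")


# ---------------------------------------------------------------------------
# t-tests and correlation

def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)))


def independent_t_from_stats(mean1: float, sd1: float, n1: int,
                             mean2: float, sd2: float, n2: int,
                             compute_bf: bool = False) -> StatResult:
    """Pooled-variance Student t from group summaries, with Cohen's d.

    Accepting printed summaries (means, SDs, ns) allows reported group
    comparisons to be recomputed without raw data.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp = _pooled_sd(sd1, n1, sd2, n2)
    if sp == 0:
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    d = (mean1 - mean2) / sp
    res = StatResult(test="independent_t", effect="group", statistic=float(t),
                     df=(float(n1 + n2 - 2),), p=float(p),
                     effect_size=float(d), effect_size_type="cohen_d")
    if compute_bf:
        res.bf10 = jzs_bf_ttest(float(t), n1, n2)
    return res


def independent_t(x, y, compute_bf: bool = False) -> StatResult:
    """Pooled-variance independent-samples t-test on raw group values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return independent_t_from_stats(x.mean(), x.std(ddof=1), len(x),
                                    y.mean(), y.std(ddof=1), len(y),
                                    compute_bf=compute_bf)


def paired_t(x, y, d_convention: str = "dz", compute_bf: bool = False) -> StatResult:
    """Paired t-test; Cohen's d reported under a configurable convention.

    ``dz`` = mean difference / SD of differences; ``dav`` = mean difference /
    average of the two condition SDs; ``pooled`` = mean difference / pooled
    condition SD.  All three are stored in ``notes``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = x - y
    sd_d = diff.std(ddof=1)
    if sd_d == 0:
        raise ValueError("zero difference variance; t is undefined")
    t, p = sps.ttest_rel(x, y)
    ds = {
        "dz": diff.mean() / sd_d,
        "dav": diff.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2),
        "pooled": diff.mean() / _pooled_sd(x.std(ddof=1), n, y.std(ddof=1), n),
    }
    if d_convention not in ds:
        raise ValueError(f"unknown d convention {d_convention!r}")
    res = StatResult(test="paired_t", effect="condition pair", statistic=float(t),
                     df=(float(n - 1),), p=float(p),
                     effect_size=float(ds[d_convention]), effect_size_type="cohen_d",
                     notes={f"d_{k}": float(v) for k, v in ds.items()})
    if compute_bf:
        res.bf10 = jzs_bf_ttest(float(t), n)
    return res


def pearson_r(x, y) -> StatResult:
    """Pearson product-moment correlation with the t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    r, p = sps.pearsonr(x, y)
    return StatResult(test="pearson_r", effect="correlation", statistic=float(r),
                      df=(float(len(x) - 2),), p=float(p))


# ---------------------------------------------------------------------------
# JZS Bayes factor

def jzs_bf_ttest(t: float, n1: int, n2: int | None = None,
                 rscale: float = np.sqrt(2) / 2) -> float:
    """Default-prior (JZS) Bayes factor BF10 for a t statistic.

    The alternative places a Cauchy(0, ``rscale``) prior on the standardized
    effect size; marginalizing uses the inverse-gamma mixture representation
    and adaptive quadrature.  ``n2`` is given for independent-samples tests
    and omitted for one-sample/paired tests.  Values below 1 favour the null.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("need group sizes of at least 2")
    if n2 is None:
        N, nu = float(n1), n1 - 1
    else:
        N, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2
    r = rscale

    def integrand(g: float) -> float:
        return ((1 + N * g) ** -0.5
                * (1 + t * t / ((1 + N * g) * nu)) ** (-(nu + 1) / 2)
                * r / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-r * r / (2 * g)))

    num, err = integrate.quad(integrand, 0, np.inf, limit=400, epsrel=1e-8)
    if not np.isfinite(num) or num <= 0 or err > 1e-4 * max(num, 1e-300):
        raise ValueError(
            f"JZS marginal likelihood integration did not converge (value={num}, abs err={err})")
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return float(num / den)
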