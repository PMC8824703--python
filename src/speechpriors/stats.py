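"""Statistical battery for the discrimination and naive-listening analyses.

Covers the analyses the experiments report: paired change tests (t or
Wilcoxon, gated on a Shapiro–Wilk normality check), bivariate and partial
correlations with an optional one-sided Bayes factor (Jeffreys-style
stretched-beta prior of width 1 on the population correlation, truncated to
positive values and integrated numerically), a 2x2 mixed ANOVA, a two-way
repeated-measures ANOVA with Greenhouse–Geisser-corrected degrees of freedom
and a linear trend contrast over blocks, logistic regression of recognition
group, and the memory-specificity correlation set.

No multiple-testing correction is applied anywhere, matching how these
analyses are conventionally reported for this design; results carry the
number of tests run instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import gammaln, hyp2f1

import pingouin as pg
import statsmodels.api as sm

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ChangeTestResult:
    statistic: float
    p: float
    effect: float        # Cohen's d for t; r = Z/sqrt(N) for Wilcoxon
    test: str            # "paired_t" | "wilcoxon"
    n: int


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p: float
    method: str
    n: int
    covariates: tuple[str, ...] = ()
    bf10_onesided: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float


@dataclass(frozen=True)
class LogisticResult:
    predictors: tuple[str, ...]
    coef: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    odds_ratio: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n: int


# ---------------------------------------------------------------------------
# paired change tests


def paired_change_test(pre, post, method: str = "auto") -> ChangeTestResult:
    """Pre/post comparison by paired t-test or Wilcoxon signed-rank.

    ``method='auto'`` uses Wilcoxon when Shapiro–Wilk rejects normality of
    the difference scores at alpha=0.05.  All-zero differences under an
    explicit Wilcoxon request return p=1 (no evidence of change); any other
    zero-variance difference vector is an error.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 3:
        raise ValueError("pre and post must be equal-length 1-D arrays, n >= 3")
    diff = post - pre
    if np.ptp(diff) == 0:
        if method == "wilcoxon" and np.all(diff == 0):
            return ChangeTestResult(statistic=0.0, p=1.0, effect=0.0,
                                    test="wilcoxon", n=len(diff))
        raise ValueError("zero-variance difference scores")
    if method == "auto":
        method = "wilcoxon" if stats.shapiro(diff).pvalue < SHAPIRO_ALPHA else "t"
    if method == "t":
        res = stats.ttest_rel(post, pre)
        d = float(np.mean(diff) / np.std(diff, ddof=1))
        return ChangeTestResult(statistic=float(res.statistic),
                                p=float(res.pvalue), effect=d,
                                test="paired_t", n=len(diff))
    if method == "wilcoxon":
        res = stats.wilcoxon(post, pre, method="approx")
        z = float(res.zstatistic)
        return ChangeTestResult(statistic=z, p=float(res.pvalue),
                                effect=z / np.sqrt(len(diff)),
                                test="wilcoxon", n=len(diff))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# correlation, partial correlation, one-sided Bayes factor


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def _log_r_density(r: float, rho: float, n: int) -> float:
    """Log sampling density of the Pearson correlation r given rho."""
    return (np.log(n - 2) + gammaln(n - 1) - 0.5 * np.log(2 * np.pi)
            - gammaln(n - 0.5)
            + 0.5 * (n - 1) * np.log1p(-rho**2)
            + 0.5 * (n - 4) * np.log1p(-r**2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))


def correlation_bf10_onesided(r: float, n: int) -> float:
    """Bayes factor for a positive correlation against the point null.

    Prior on rho: stretched beta of width 1 (i.e. uniform on (-1, 1))
    truncated to rho > 0, the default one-sided prior of standard Bayesian
    correlation tests; the marginal likelihood is integrated numerically.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the correlation Bayes factor")
    log_f0 = _log_r_density(r, 0.0, n)

    def ratio(rho: float) -> float:
        return np.exp(_log_r_density(r, rho, n) - log_f0)

    bf, _ = integrate.quad(ratio, 0.0, 1.0, epsabs=1e-8, limit=200)
    return float(bf)


def association(x, y, method: str = "pearson", covariates: pd.DataFrame | np.ndarray | None = None,
                onesided_bayes: bool = False) -> AssociationResult:
    """Bivariate or partial correlation between ``x`` and ``y``.

    Partial correlations residualize both variables against the covariates
    (after rank-transforming everything for the Spearman variant: ranks
    first, then residualization).  The one-sided Bayes factor tests a
    positive association.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] == n and cov.ndim == 2:
                pass
            else:
                cov = cov.T
            cov_names = tuple(f"c{i}" for i in range(cov.shape[1]))
        if method == "spearman":
            x = stats.rankdata(x)
            y = stats.rankdata(y)
            cov = np.apply_along_axis(stats.rankdata, 0, cov)
        rx = _residualize(x, cov)
        ry = _residualize(y, cov)
        r = float(np.corrcoef(rx, ry)[0, 1])
        k = cov.shape[1]
        df = n - 2 - k
        t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
        p = 2 * stats.t.sf(abs(t), df)
        label = f"partial_{method}"
        n_eff = n - k
    else:
        if method == "pearson":
            res = stats.pearsonr(x, y)
        else:
            res = stats.spearmanr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        label = method
        n_eff = n

    bf = correlation_bf10_onesided(r, n_eff) if onesided_bayes else None
    return AssociationResult(r=r, p=float(p), method=label, n=n,
                             covariates=cov_names, bf10_onesided=bf)


# ---------------------------------------------------------------------------
# ANOVA


def mixed_anova_2x2(data: pd.DataFrame, dv: str = "d_prime", within: str = "phase",
                    between: str = "group", subject: str = "participant") -> list[AnovaResult]:
    """2x2 mixed ANOVA (between group x within phase) on a long-format table."""
    counts = data.groupby([between, within], observed=True)[dv].count()
    if (counts < 2).any() or counts.size < 4:
        raise ValueError("every group x phase cell needs at least 2 observations")
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject)
    aov.columns = [c.replace("-", "_") for c in aov.columns]
    df1_col = "DF1" if "DF1" in aov.columns else "ddof1"
    df2_col = "DF2" if "DF2" in aov.columns else "ddof2"
    out = []
    for _, row in aov.iterrows():
        if row["Source"] == "Interaction":
            label = f"{between} x {within}"
        else:
            label = str(row["Source"])
        f, p, np2 = float(row["F"]), float(row["p_unc"]), float(row["np2"])
        ss_eff = float(row.get("SS", np.nan))
        ss_scale = max(float(aov["SS"].abs().max()), np.var(data[dv]) * len(data))
        if not np.isfinite(f) and ss_eff <= 1e-12 * max(ss_scale, 1e-300):
            # vanishing effect sum-of-squares with a zero error term: no effect
            f, p, np2 = 0.0, 1.0, 0.0
        out.append(AnovaResult(effect=label, F=f,
                               df1=float(row[df1_col]), df2=float(row[df2_col]),
                               p=p, eta_p2=np2))
    return out


def _gg_epsilon(cell_scores: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon for one within effect.

    ``cell_scores``: subjects x cells matrix; ``contrast``: (df x cells)
    orthonormal contrast matrix spanning the effect.
    """
    sigma = np.cov(cell_scores, rowvar=False)
    m = contrast @ sigma @ contrast.T
    df = contrast.shape[0]
    return float(np.trace(m) ** 2 / (df * np.trace(m @ m)))


def _orthonormal_contrast(p: int) -> np.ndarray:
    """(p-1) x p orthonormal contrasts orthogonal to the unit vector."""
    basis = np.eye(p) - np.full((p, p), 1.0 / p)
    q, _ = np.linalg.qr(basis[:, : p - 1])
    return q.T  # rows orthonormal, each orthogonal to 1 (up to fp error)


def rm_anova(y: np.ndarray, correction: str = "greenhouse_geisser") -> list[AnovaResult]:
    """Two-way fully-within repeated-measures ANOVA on ``y`` with shape
    (subjects, levels_A, levels_B); factor A is exposure (pre/post), B is
    block.  Degrees of freedom for within effects are sphericity-corrected
    (Greenhouse–Geisser by default; ``correction='huynh_feldt'`` or 'none').

    Also reports the linear trend of the block factor within the first level
    of A (pre-exposure), as effect "A1_linear_trend".
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must be (subjects, A levels, B levels)")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed in the within design")
    n, p, q = y.shape
    m = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * q * np.sum((m_a - m) ** 2)
    ss_b = n * p * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = q * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = p * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - m)
    ss_abs = np.sum(resid**2)

    ca = _orthonormal_contrast(p)
    cb = _orthonormal_contrast(q)
    cab = np.kron(ca, cb)
    cells = y.reshape(n, p * q)

    def hf_adjust(eps: float, df: int) -> float:
        # Huynh–Feldt correction from the GG epsilon
        return min(1.0, (n * df * eps - 2) / (df * (n - 1 - df * eps)))

    effects = []
    for label, ss_eff, ss_err, df1, df2, scores, c in (
        ("exposure", ss_a, ss_as, p - 1, (p - 1) * (n - 1), y.mean(axis=2), ca),
        ("block", ss_b, ss_bs, q - 1, (q - 1) * (n - 1), y.mean(axis=1), cb),
        ("exposure x block", ss_ab, ss_abs, (p - 1) * (q - 1),
         (p - 1) * (q - 1) * (n - 1), cells, cab),
    ):
        f = (ss_eff / df1) / (ss_err / df2)
        eps = 1.0
        if correction != "none" and df1 > 1:
            eps = min(1.0, _gg_epsilon(scores, c))
            if correction == "huynh_feldt":
                eps = hf_adjust(eps, df1)
        pval = stats.f.sf(f, eps * df1, eps * df2)
        effects.append(AnovaResult(effect=label, F=float(f), df1=eps * df1,
                                   df2=eps * df2, p=float(pval),
                                   eta_p2=float(ss_eff / (ss_eff + ss_err))))

    # linear trend over blocks within the pre-exposure level
    w = np.arange(q) - (q - 1) / 2.0
    w = w / np.linalg.norm(w)
    trend_scores = y[:, 0, :] @ w
    t = trend_scores.mean() / (trend_scores.std(ddof=1) / np.sqrt(n))
    effects.append(AnovaResult(
        effect="A1_linear_trend", F=float(t**2), df1=1.0, df2=float(n - 1),
        p=float(stats.f.sf(t**2, 1, n - 1)),
        eta_p2=float(t**2 / (t**2 + n - 1))))
    return effects


# ---------------------------------------------------------------------------
# logistic regression of recognition group


def _check_separation(y: np.ndarray, predictors: pd.DataFrame) -> None:
    for name in predictors.columns:
        v = predictors[name].to_numpy(dtype=float)
        if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
            raise ValueError(f"perfect separation on predictor {name!r}")


def logistic_recognition(recognized, predictors: pd.DataFrame) -> LogisticResult:
    """ML logistic regression of recognition group on the given predictors.

    Reports Wald z and p, odds ratios and 95% Wald CIs per predictor.
    """
    y = np.asarray(recognized, dtype=float)
    if len(y) < 20:
        raise ValueError("need n >= 20")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame({"x": np.asarray(predictors, dtype=float)})
    _check_separation(y, predictors)
    x = sm.add_constant(predictors.astype(float), prepend=True)
    try:
        fit = sm.Logit(y, x).fit(disp=0)
    except Exception as exc:  # statsmodels' own separation error, etc.
        raise ValueError(f"logistic fit failed: {exc}") from exc
    ci = fit.conf_int()
    return LogisticResult(
        predictors=tuple(predictors.columns),
        coef={k: float(v) for k, v in fit.params.items()},
        z={k: float(v) for k, v in fit.tvalues.items()},
        p={k: float(v) for k, v in fit.pvalues.items()},
        odds_ratio={k: float(np.exp(v)) for k, v in fit.params.items()},
        ci95={k: (float(np.exp(ci.loc[k, 0])), float(np.exp(ci.loc[k, 1])))
              for k in fit.params.index},
        n=len(y),
    )


# ---------------------------------------------------------------------------
# memory-specificity analysis


def memory_analysis(cohort: pd.DataFrame, memory_scores: pd.DataFrame
                    ) -> dict[str, AssociationResult]:
    """Specificity set: hallucination-proneness vs (i) Remember counts for
    hidden words, (ii) lure endorsement, (iii) reading-test-word memory, and
    (i) again partialling out the reading-test score."""
    needed = {"r_hidden", "lure_endorsed", "r_nart"}
    if not needed <= set(memory_scores.columns):
        raise ValueError(f"memory scores missing {sorted(needed - set(memory_scores.columns))}")
    df = cohort.merge(memory_scores, on="participant", validate="one_to_one")
    lshs = df["lshs_a"].to_numpy(dtype=float)
    return {
        "hidden": association(lshs, df["r_hidden"], method="spearman"),
        "lures": association(lshs, df["lure_endorsed"], method="spearman"),
        "nart_words": association(lshs, df["r_nart"], method="spearman"),
        "hidden_partial_nart": association(
            lshs, df["r_hidden"], method="spearman",
            covariates=df[["nart"]]),
    }


# ---------------------------------------------------------------------------
# end-to-end qualitative pattern


def qualitative_pattern(params=None, seed: int = 0, n_trials_per_kind: int = 45,
                        alpha: float = 0.05) -> dict:
    """Run the full simulated study once and assess the four-way pattern:

    (a) significant pre-to-post discrimination gain,
    (b) no significant trait–(d' change) correlation (modulation null),
    (c) spontaneous recognition positively predicted by the hallucination
        scale (odds ratio > 1, significant),
    (d) memory specificity: the hidden-word correlation is significant and
        positive while the lure and reading-test-word correlations are
        smaller in magnitude.

    Returns per-component booleans, their conjunction under ``pattern``, and
    the underlying statistics.
    """
    from .observers import (scenario_params, sample_cohort,
                            simulate_cohort_counts, run_naive_cohort, _streams)

    if params is None:
        params = scenario_params("naive", n=134)
    params = type(params)(**{**vars(params), "seed": seed})
    cohort = sample_cohort(params)
    rng = _streams(params)["discrimination"]
    counts = simulate_cohort_counts(cohort, n_trials_per_kind, n_trials_per_kind, rng)

    gain = paired_change_test(counts["d_prime_pre"], counts["d_prime_post"], method="t")
    delta = counts["d_prime_post"] - counts["d_prime_pre"]
    mod = association(counts["lshs_a"], delta, method="pearson")

    cohort_df, mem_scores = run_naive_cohort(params)
    logit = logistic_recognition(cohort_df["recognized"].astype(int),
                                 cohort_df[["lshs_a"]])
    mem = memory_analysis(cohort_df, mem_scores)

    ok_gain = gain.p < alpha and gain.statistic > 0
    ok_mod_null = mod.p >= alpha
    ok_recognition = (logit.odds_ratio["lshs_a"] > 1.0
                      and logit.p["lshs_a"] < alpha)
    ok_memory = (mem["hidden"].p < alpha and mem["hidden"].r > 0
                 and abs(mem["lures"].r) < mem["hidden"].r
                 and abs(mem["nart_words"].r) < mem["hidden"].r)
    return {
        "exposure_gain": ok_gain,
        "modulation_null": ok_mod_null,
        "recognition_effect": ok_recognition,
        "memory_dissociation": ok_memory,
        "pattern": ok_gain and ok_mod_null and ok_recognition and ok_memory,
        "stats": {"gain": gain, "modulation": mod, "logistic": logit,
                  "memory": mem},
    }
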