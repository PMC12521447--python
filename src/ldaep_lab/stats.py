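"""Group-level inference for LDAEP cohort tables.

Implements the inferential layer of a two-group LDAEP study: normality
screening (Lilliefors-corrected Kolmogorov–Smirnov), one-way ANOVA with
partial η² and noncentral-F confidence intervals, Type-II ANCOVA adjusting
for age and BDI-II subscales (with estimated marginal means and VIFs),
Wilcoxon rank-sum / χ² / Fisher exact tests, pooled-variance t-tests with
Cohen's d, and exact noncentral-t a-priori power for a two-sample design.

Conventions follow common reporting practice for this literature: partial
η² = F·df1/(F·df1 + df2); the η² interval is the one-sided 95% construction
(lower bound from noncentral-F inversion, upper bound 1.00); pooled-variance
t is the default (so F = t² for two groups); no multiple-testing correction
is applied and all tests are two-tailed at α = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols as _sm_ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "AnovaResult",
    "AncovaResult",
    "PowerSpec",
    "ks_normality",
    "one_way_anova",
    "ancova_type2",
    "rank_and_exact_tests",
    "two_sample_t_and_d",
    "power_two_sample_t",
    "power_at_n",
    "run_group_analysis",
]


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    eta_ci: tuple[float, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    mean_diff: float | None = None  # first minus second group (2 groups only)
    mean_diff_ci: tuple[float, float] | None = None


@dataclass
class AncovaResult:
    table: pd.DataFrame  # per-term: sum_sq, df, F, p, partial_eta_sq
    emmeans: dict[str, tuple[float, float]]  # group -> (EMM, SE)
    r2: float
    r2_adj: float
    vif: dict[str, float]
    n: int


@dataclass(frozen=True)
class PowerSpec:
    d: float = 0.77
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2
    allocation_ratio: float = 1.0  # n2/n1
    n_cap: int = 100000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("target power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def partial_eta_sq_from_f(F: float, df1: float, df2: float) -> float:
    """Identity η²_p = F·df1 / (F·df1 + df2)."""
    return F * df1 / (F * df1 + df2)


def _eta_ci_lower(F: float, df1: int, df2: int, level: float = 0.95) -> float:
    """Lower confidence bound on partial η² by noncentral-F inversion.

    One-sided construction: the lower bound is the noncentrality λ at which
    the observed F sits at the upper (1 − level) tail, mapped through
    η² = λ/(λ + df1 + df2 + 1); the matching upper bound is 1.00.
    """
    alpha = 1.0 - level
    if sps.f.sf(F, df1, df2) >= alpha:  # central F already explains the tail
        return 0.0

    def g(lam: float) -> float:
        return sps.ncf.sf(F, df1, df2, lam) - alpha

    hi = 1.0
    while g(hi) < 0 and hi < 1e7:
        hi *= 2
    from scipy.optimize import brentq

    lam = brentq(g, 0.0, hi, xtol=1e-10)
    return lam / (lam + df1 + df2 + 1)


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality screen with estimated parameters
    (Lilliefors correction).  Returns (statistic, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4 for the normality screen")
    if np.ptp(x) == 0:
        warnings.warn("constant input: normality test degenerate")
        return np.nan, np.nan
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Classical between/within one-way ANOVA with partial η² and, for two
    groups, the pooled-variance mean difference with its 95% t interval."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")

    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df1 = len(labels) - 1
    df2 = values.size - len(labels)
    msw = ssw / df2
    F = (ssb / df1) / msw
    p = float(sps.f.sf(F, df1, df2))
    eta = partial_eta_sq_from_f(F, df1, df2)
    ci = (_eta_ci_lower(F, df1, df2), 1.0)

    mean_diff = mean_diff_ci = None
    if len(labels) == 2:
        a, b = samples
        mean_diff = float(a.mean() - b.mean())
        sp = np.sqrt(msw)  # pooled SD
        se = sp * np.sqrt(1 / len(a) + 1 / len(b))
        tcrit = sps.t.ppf(0.975, df2)
        mean_diff_ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)

    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=p, partial_eta_sq=float(eta), eta_ci=ci,
        group_means={str(g): float(s.mean()) for g, s in zip(labels, samples)},
        group_sds={str(g): float(s.std(ddof=1)) for g, s in zip(labels, samples)},
        group_ns={str(g): int(len(s)) for g, s in zip(labels, samples)},
        mean_diff=mean_diff, mean_diff_ci=mean_diff_ci,
    )


def ancova_type2(data: pd.DataFrame, outcome: str, group: str = "group2",
                 covariates: tuple[str, ...] = ("age", "bdi_cognitive",
                                                "bdi_somatic_affective")) -> AncovaResult:
    """ANCOVA with Type-II sums of squares.

    Per term, SS = SSE(model without the term, all others retained) −
    SSE(full model), tested against the full-model residual mean square.
    Partial η² = SS_term/(SS_term + SS_resid).  Estimated marginal means are
    the fitted group values at the covariate sample means, with SEs from the
    coefficient covariance.  VIFs come from auxiliary regressions on the
    full design matrix.
    """
    cols = [outcome, group, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = data[cols].dropna().copy()
    n = len(df)
    if n <= len(covariates) + 2:
        raise ValueError("not enough observations for the ANCOVA design")

    rhs = f"C({group})" + "".join(f" + {c}" for c in covariates)
    model = _sm_ols(f"{outcome} ~ {rhs}", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design in columns {cols[1:]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a2 = anova_lm(model, typ=2)
    ss_resid = float(a2.loc["Residual", "sum_sq"])
    table = a2.drop(index="Residual").copy()
    table["partial_eta_sq"] = table["sum_sq"] / (table["sum_sq"] + ss_resid)
    table = table.rename(columns={"PR(>F)": "p"})

    # estimated marginal means at covariate sample means
    cov_means = {c: float(df[c].mean()) for c in covariates}
    emmeans = {}
    for g in pd.unique(df[group]):
        pred = pd.DataFrame([{group: g, **cov_means}])
        design = model.model.data.design_info
        from patsy import dmatrix

        x = np.asarray(dmatrix(design, pred))[0]
        mu = float(x @ model.params.values)
        se = float(np.sqrt(x @ model.cov_params().values @ x))
        emmeans[str(g)] = (mu, se)

    exog = model.model.exog
    names = model.model.exog_names
    vif = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        vif[name] = float(variance_inflation_factor(exog, j))

    return AncovaResult(
        table=table,
        emmeans=emmeans,
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        vif=vif,
        n=n,
    )


def rank_and_exact_tests(kind: str, *, x: np.ndarray | None = None,
                         y: np.ndarray | None = None,
                         counts: np.ndarray | None = None
                         ) -> tuple[float, float]:
    """Wilcoxon rank-sum, Pearson χ², or Fisher's exact test.

    ``wilcoxon``: two samples; returns the Mann–Whitney U of the first
    sample (the W that R's ``wilcox.test`` reports) with an exact p for
    small untied samples and the tie-corrected normal approximation
    otherwise.  ``chi_square``: r×c counts, no continuity correction.
    ``fisher``: 2×2 counts, two-sided exact p.
    """
    if kind == "wilcoxon":
        if x is None or y is None:
            raise ValueError("wilcoxon needs two samples")
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    if kind == "chi_square":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("negative counts")
        res = sps.chi2_contingency(counts, correction=False)
        return float(res.statistic), float(res.pvalue)
    if kind == "fisher":
        counts = np.asarray(counts)
        if counts.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 table")
        if np.any(counts < 0):
            raise ValueError("negative counts")
        stat, p = sps.fisher_exact(counts, alternative="two-sided")
        return float(stat), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def two_sample_t_and_d(x: np.ndarray, y: np.ndarray, pooled: bool = True
                       ) -> dict[str, float | tuple[float, float]]:
    """Independent-samples t-test with Cohen's d (pooled SD) and 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = float(x.mean() - y.mean())
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    d = diff / np.sqrt(sp2)
    if pooled:
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        dof = n1 + n2 - 2
    else:  # Welch
        se = np.sqrt(v1 / n1 + v2 / n2)
        dof = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = diff / se
    p = 2 * sps.t.sf(abs(t), dof)
    tcrit = sps.t.ppf(0.975, dof)
    return dict(t=float(t), df=float(dof), p=float(p), d=float(d),
                mean_diff=diff, ci=(diff - tcrit * se, diff + tcrit * se))


def power_at_n(n1: int, n2: int, d: float, alpha: float = 0.05, tails: int = 2
               ) -> float:
    """Exact noncentral-t power of the two-sample pooled t-test."""
    df = n1 + n2 - 2
    ncp = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def power_two_sample_t(spec: PowerSpec) -> tuple[int, float]:
    """Smallest total n (allocation per ``allocation_ratio``) reaching the
    target power; returns (total n, achieved power)."""
    if spec.d == 0:
        raise ValueError("effect size d must be nonzero")
    r = spec.allocation_ratio
    n1 = 2
    while True:
        n2 = max(int(round(n1 * r)), 2)
        if n1 + n2 > spec.n_cap:
            raise ValueError(f"target power unreachable below n = {spec.n_cap}")
        pw = power_at_n(n1, n2, spec.d, spec.alpha, spec.tails)
        if pw >= spec.power:
            return n1 + n2, pw
        n1 += 1


# ---------------------------------------------------------------------------
# full analysis plan

SLOPES = ("n1_slope", "p2_slope", "n1p2_slope")


def merge_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Merge past + never users into a single non-user group (``group2``)."""
    out = cohort.copy()
    out["group2"] = np.where(out["group"] == "current_user", "current_user", "non_user")
    return out


def run_group_analysis(cohort: pd.DataFrame, slopes: tuple[str, ...] = SLOPES,
                       bdi_threshold: int = 13) -> dict[str, pd.DataFrame]:
    """Execute the full analysis plan on a cohort table.

    In order: group merge, per-slope ANOVA (current users vs. non-users),
    per-slope Type-II ANCOVA (age + BDI subscales), BDI Wilcoxon contrasts,
    BDI-threshold-stratified t-tests, menstrual-phase ANOVAs within each
    group, HC-type t-tests within users, and adverse-mood contrasts
    (slope t-tests, BDI Wilcoxon, Fisher on the threshold flag).

    Returns one tidy table per analysis; analyses whose design is degenerate
    in the given cohort are reported with a notice row instead of a result.
    """
    required = ["group", *slopes, "age", "bdi_cognitive", "bdi_somatic_affective"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    df = merge_groups(cohort)
    if "bdi_total" not in df.columns:
        df["bdi_total"] = df["bdi_cognitive"] + df["bdi_somatic_affective"]
    df["above_bdi_threshold"] = df["bdi_total"] >= bdi_threshold
    users = df[df["group2"] == "current_user"]
    nonusers = df[df["group2"] == "non_user"]
    out: dict[str, pd.DataFrame] = {}
    notices: list[str] = []

    two_groups = len(users) >= 2 and len(nonusers) >= 2

    # normality screen
    rows = []
    for s in slopes:
        for gname, gdf in (("current_user", users), ("non_user", nonusers)):
            if len(gdf) >= 4:
                stat, p = ks_normality(gdf[s].to_numpy())
                rows.append(dict(variable=s, group=gname, test="ks_lilliefors",
                                 statistic=stat, p=p))
    out["normality"] = pd.DataFrame(rows)

    # primary ANOVA and ANCOVA
    rows_anova, rows_ancova = [], []
    if two_groups:
        for s in slopes:
            a = one_way_anova(df[s].to_numpy(), df["group2"].to_numpy())
            rows_anova.append(dict(
                outcome=s, test="one_way_anova", F=a.F, df1=a.df1, df2=a.df2, p=a.p,
                partial_eta_sq=a.partial_eta_sq, eta_ci_low=a.eta_ci[0],
                eta_ci_high=a.eta_ci[1], mean_diff=a.mean_diff,
                mean_diff_ci_low=a.mean_diff_ci[0], mean_diff_ci_high=a.mean_diff_ci[1],
            ))
            try:
                c = ancova_type2(df, s)
                grow = c.table.loc["C(group2)"]
                emm_u, emm_n = c.emmeans["current_user"], c.emmeans["non_user"]
                rows_ancova.append(dict(
                    outcome=s, test="ancova_type2", F=float(grow["F"]),
                    df1=int(grow["df"]), df2=int(c.n - len(c.table) - 1),
                    p=float(grow["p"]), partial_eta_sq=float(grow["partial_eta_sq"]),
                    emm_user=emm_u[0], emm_user_se=emm_u[1],
                    emm_nonuser=emm_n[0], emm_nonuser_se=emm_n[1],
                    r2=c.r2, r2_adj=c.r2_adj, max_vif=max(c.vif.values()),
                ))
            except ValueError as exc:
                notices.append(f"ancova {s}: {exc}")
    else:
        notices.append("between-group analyses skipped: need both groups with n >= 2")
    out["anova"] = pd.DataFrame(rows_anova)
    out["ancova"] = pd.DataFrame(rows_ancova)

    # BDI contrasts (Wilcoxon)
    rows = []
    if two_groups:
        for var in ("bdi_total", "bdi_cognitive", "bdi_somatic_affective"):
            w, p = rank_and_exact_tests("wilcoxon", x=users[var].to_numpy(),
                                        y=nonusers[var].to_numpy())
            rows.append(dict(variable=var, test="wilcoxon_rank_sum", W=w, p=p))
    out["bdi_group_contrasts"] = pd.DataFrame(rows)

    # BDI-threshold stratified slope t-tests
    rows = []
    lo = df[~df["above_bdi_threshold"]]
    hi = df[df["above_bdi_threshold"]]
    for s in slopes:
        if len(lo) >= 2 and len(hi) >= 2:
            r = two_sample_t_and_d(lo[s].to_numpy(), hi[s].to_numpy())
            rows.append(dict(outcome=s, contrast="below_vs_above_bdi_threshold",
                             t=r["t"], df=r["df"], p=r["p"], d=r["d"]))
        else:
            notices.append(f"bdi-threshold t-test for {s} skipped: a stratum has n < 2")
    out["bdi_threshold_ttests"] = pd.DataFrame(rows)

    # menstrual-phase ANOVAs within each group
    rows = []
    for gname, gdf in (("current_user", users), ("non_user", nonusers)):
        cyc = gdf[gdf["menstrual_phase"].isin(["follicular", "ovulatory", "luteal"])]
        counts = cyc["menstrual_phase"].value_counts()
        if (counts >= 2).sum() >= 2:
            keep = cyc[cyc["menstrual_phase"].isin(counts[counts >= 2].index)]
            for s in slopes:
                a = one_way_anova(keep[s].to_numpy(), keep["menstrual_phase"].to_numpy())
                rows.append(dict(group=gname, outcome=s, F=a.F, df1=a.df1,
                                 df2=a.df2, p=a.p, partial_eta_sq=a.partial_eta_sq))
        else:
            notices.append(f"phase ANOVA in {gname} skipped: too few phase groups")
    out["phase_anova"] = pd.DataFrame(rows)

    # HC-type t-tests within current users
    rows = []
    comb = users[users["hc_type"] == "combined"]
    prog = users[users["hc_type"] == "progestin_only"]
    if len(comb) >= 2 and len(prog) >= 2:
        for s in slopes:
            r = two_sample_t_and_d(comb[s].to_numpy(), prog[s].to_numpy())
            rows.append(dict(outcome=s, contrast="combined_vs_progestin_only",
                             t=r["t"], df=r["df"], p=r["p"], d=r["d"]))
    else:
        notices.append("hc-type t-tests skipped: a formulation subgroup has n < 2")
    out["hc_type_ttests"] = pd.DataFrame(rows)

    # adverse-mood contrasts within current users
    rows = []
    adv = users[users["adverse_mood"].astype(bool)]
    no_adv = users[~users["adverse_mood"].astype(bool)]
    if len(adv) >= 2 and len(no_adv) >= 2:
        for s in slopes:
            r = two_sample_t_and_d(adv[s].to_numpy(), no_adv[s].to_numpy())
            rows.append(dict(variable=s, test="t_test", statistic=r["t"], p=r["p"]))
        for var in ("bdi_total", "bdi_cognitive", "bdi_somatic_affective"):
            w, p = rank_and_exact_tests("wilcoxon", x=adv[var].to_numpy(),
                                        y=no_adv[var].to_numpy())
            rows.append(dict(variable=var, test="wilcoxon_rank_sum", statistic=w, p=p))
        tab = np.array([
            [int(adv["above_bdi_threshold"].sum()), int((~adv["above_bdi_threshold"]).sum())],
            [int(no_adv["above_bdi_threshold"].sum()), int((~no_adv["above_bdi_threshold"]).sum())],
        ])
        if tab.sum() > 0:
            _, p = rank_and_exact_tests("fisher", counts=tab)
            rows.append(dict(variable="above_bdi_threshold", test="fisher_exact",
                             statistic=np.nan, p=p))
    else:
        notices.append("adverse-mood contrasts skipped: a subgroup has n < 2")
    out["adverse_mood"] = pd.DataFrame(rows)

    out["notices"] = pd.DataFrame({"notice": notices})
    return out


def render_report(tables: dict[str, pd.DataFrame]) -> str:
    """Human-readable multi-section report."""
    parts = []
    for name, tab in tables.items():
        parts.append(f"== {name} ==")
        parts.append(tab.to_string(index=False) if len(tab) else "(empty)")
        parts.append("")
    return "\n".join(parts)
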