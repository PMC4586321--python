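"""Inferential battery: mixed repeated-measures ANOVA with Greenhouse–Geisser
correction, effect sizes and observed power; a two-sample randomization test;
and Pearson correlations.

The mixed ANOVA handles one between-subject factor (age group) and one
within-subject factor (electrode or predictability) via the classical
sums-of-squares decomposition. Sphericity is corrected with the
Greenhouse–Geisser (Box) epsilon estimated from the pooled within-group
covariance of the within-subject levels; within-subject effects report the
epsilon-adjusted p. Partial eta squared follows its F-statistic identity
eta_p^2 = F * df_num / (F * df_num + df_den). Observed power (alpha = 0.05)
is 1 − CDF_F'(F_crit; df1*eps, df2*eps, lambda = F * df1 * eps), i.e. the
noncentral-F tail at the epsilon-adjusted degrees of freedom with the sample
F taken as the noncentrality per numerator df.

The randomization test uses the statistic T = (sum A)^2 + (sum B)^2, which at
fixed group sizes is a monotone transform of the between-group sum of squares;
the p-value is the add-one-smoothed upper tail (1 + #{T_perm >= T_obs}) /
(n + 1) over random re-assignments preserving group sizes, replaced by exact
enumeration whenever the number of distinct splits is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: Exact enumeration replaces sampling when the number of splits is below this.
EXACT_ENUMERATION_CAP = 20_000


@dataclass
class AnovaEffect:
    """One row of an ANOVA table."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p: float                        # uncorrected
    epsilon: float                  # GG epsilon (1.0 for between effects)
    p_gg: float                     # GG-corrected p (== p when epsilon is 1)
    eta_p2: float
    power: float


@dataclass
class RandomizationResult:
    observed_stat: float
    n_randomizations: int
    p_value: float
    exact: bool
    seed: int | None


@dataclass
class CorrelationResult:
    r: float
    b: float                        # least-squares slope of y on x
    p: float                        # two-sided
    n: int


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA

def _gg_epsilon(cells: np.ndarray, groups: np.ndarray) -> float:
    """Box/Greenhouse–Geisser epsilon from the pooled within-group covariance.

    ``cells`` is subjects x k within-levels. Epsilon is computed on the
    double-centered pooled covariance matrix; bounded to [1/(k-1), 1].
    """
    k = cells.shape[1]
    if k < 3:
        return 1.0
    pooled = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        sub = cells[groups == g]
        if len(sub) > 1:
            pooled += (len(sub) - 1) * np.cov(sub, rowvar=False)
            dof += len(sub) - 1
    S = pooled / dof
    # double-center
    S = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(S) ** 2
    den = (k - 1) * np.sum(S * S)
    eps = num / den
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _observed_power(F: float, df1: float, df2: float, eps: float = 1.0,
                    alpha: float = ALPHA) -> float:
    d1, d2 = df1 * eps, df2 * eps
    lam = F * d1
    fcrit = sps.f.isf(alpha, d1, d2)
    return float(1.0 - sps.ncf.cdf(fcrit, d1, d2, lam))


def rm_anova(data: pd.DataFrame, subject: str = "subject",
             between: str | None = "group",
             within: str | None = "within",
             value: str = "value") -> pd.DataFrame:
    """Mixed-design ANOVA from a long-format table.

    ``data`` holds one row per subject x within-level with columns for the
    subject id, the between-group label, the within-factor level and the
    value. Either factor may be omitted (``None``) to get a one-way design.
    The within design must be balanced (every subject measured at every
    level) and every group must contain at least two subjects.

    Returns a DataFrame with one row per effect (between, within,
    interaction) carrying F, dfs, uncorrected p, GG epsilon, GG-corrected p,
    partial eta squared and observed power at alpha = 0.05.
    """
    if within is None:
        return _between_anova(data, subject, between, value)

    wide = data.pivot_table(index=[subject] +
                            ([between] if between else []),
                            columns=within, values=value, observed=True)
    if wide.isna().any().any():
        raise ValueError("unbalanced within-design: missing subject x level cells")
    cells = wide.to_numpy()                       # subjects x k
    n, k = cells.shape
    if between is not None:
        groups = np.asarray([ix[1] for ix in wide.index])
    else:
        groups = np.zeros(n, dtype=int)
    labels, counts = np.unique(groups, return_counts=True)
    if between is not None and (counts < 2).any():
        raise ValueError("every group needs at least two subjects")
    a = len(labels)

    grand = cells.mean()
    subj_means = cells.mean(axis=1)
    level_means = cells.mean(axis=0)
    group_means = np.array([cells[groups == g].mean() for g in labels])
    ss_total = ((cells - grand) ** 2).sum()
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_A = k * (counts * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_A
    ss_B = n * ((level_means - grand) ** 2).sum()
    # cell means per group x level
    ss_cells = 0.0
    for g, ng in zip(labels, counts):
        cm = cells[groups == g].mean(axis=0)
        ss_cells += ng * ((cm - grand) ** 2).sum()
    ss_AB = ss_cells - ss_A - ss_B
    ss_err = ss_total - ss_between_subj - ss_B - ss_AB

    df_A, df_sw = a - 1, n - a
    df_B = k - 1
    df_AB = (a - 1) * (k - 1)
    df_err = (n - a) * (k - 1)
    eps = _gg_epsilon(cells, groups)

    rows = []
    if between is not None:
        F_A = (ss_A / df_A) / (ss_subj_within / df_sw)
        p_A = sps.f.sf(F_A, df_A, df_sw)
        rows.append(AnovaEffect(
            between, F_A, df_A, df_sw, p_A, 1.0, p_A,
            F_A * df_A / (F_A * df_A + df_sw),
            _observed_power(F_A, df_A, df_sw)))
    ms_err = ss_err / df_err
    F_B = (ss_B / df_B) / ms_err
    p_B = sps.f.sf(F_B, df_B, df_err)
    p_B_gg = sps.f.sf(F_B, df_B * eps, df_err * eps)
    rows.append(AnovaEffect(
        within, F_B, df_B, df_err, p_B, eps, p_B_gg,
        F_B * df_B / (F_B * df_B + df_err),
        _observed_power(F_B, df_B, df_err, eps)))
    if between is not None:
        F_AB = (ss_AB / df_AB) / ms_err
        p_AB = sps.f.sf(F_AB, df_AB, df_err)
        p_AB_gg = sps.f.sf(F_AB, df_AB * eps, df_err * eps)
        rows.append(AnovaEffect(
            f"{within} * {between}", F_AB, df_AB, df_err, p_AB, eps, p_AB_gg,
            F_AB * df_AB / (F_AB * df_AB + df_err),
            _observed_power(F_AB, df_AB, df_err, eps)))
    return pd.DataFrame([r.__dict__ for r in rows])


def _between_anova(data: pd.DataFrame, subject: str, between: str,
                   value: str) -> pd.DataFrame:
    """One-way between-subjects ANOVA (no within factor)."""
    if between is None:
        raise ValueError("need at least one factor")
    groups = [g[value].to_numpy() for _, g in data.groupby(between, observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two subjects")
    vals = np.concatenate(groups)
    grand = vals.mean()
    ss_A = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_err = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_A = len(groups) - 1
    df_err = len(vals) - len(groups)
    F = (ss_A / df_A) / (ss_err / df_err)
    p = sps.f.sf(F, df_A, df_err)
    eff = AnovaEffect(between, F, df_A, df_err, p, 1.0, p,
                      F * df_A / (F * df_A + df_err),
                      _observed_power(F, df_A, df_err))
    return pd.DataFrame([eff.__dict__])


# ---------------------------------------------------------------------------
# randomization test

def _sum_sq_stat(sum_a: np.ndarray | float, total: float) -> np.ndarray | float:
    return sum_a ** 2 + (total - sum_a) ** 2


def randomization_test(group_a, group_b, n: int = 10_000,
                       seed: int | None = None,
                       exact_cap: int = EXACT_ENUMERATION_CAP,
                       ) -> RandomizationResult:
    """Two-sample randomization test on T = (sum A)^2 + (sum B)^2.

    Re-assigns the pooled values to the two groups (sizes preserved) and
    compares the observed T with its randomization distribution;
    p = (1 + #{T_perm >= T_obs}) / (n + 1). When the total number of distinct
    splits is at most ``exact_cap``, every split is enumerated instead and
    p is the exact tail proportion (the observed split is one of them, so
    p >= 1/n_splits and never 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([a, b])
    total = pooled.sum()
    t_obs = _sum_sq_stat(a.sum(), total)

    n_splits = comb(len(pooled), len(a))
    if n_splits <= exact_cap:
        sums = np.fromiter(
            (pooled[list(ix)].sum()
             for ix in combinations(range(len(pooled)), len(a))),
            dtype=float, count=n_splits)
        t_perm = _sum_sq_stat(sums, total)
        p = float((t_perm >= t_obs - 1e-12 * abs(t_obs)).sum() / n_splits)
        return RandomizationResult(float(t_obs), n_splits, p, True, seed)

    rng = np.random.default_rng(seed)
    # vectorized: each row is a random permutation; first len(a) columns = group A
    u = rng.random((n, len(pooled)))
    order = np.argsort(u, axis=1)[:, :len(a)]
    sums = pooled[order].sum(axis=1)
    t_perm = _sum_sq_stat(sums, total)
    count = int((t_perm >= t_obs - 1e-12 * abs(t_obs)).sum())
    p = (1 + count) / (n + 1)
    return RandomizationResult(float(t_obs), n, float(p), False, seed)


# ---------------------------------------------------------------------------
# correlation

def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r, least-squares slope of y on x, and two-sided p (t, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; correlation undefined")
    res = sps.linregress(x, y)
    return CorrelationResult(r=float(res.rvalue), b=float(res.slope),
                             p=float(res.pvalue), n=len(x))


# ---------------------------------------------------------------------------
# the full battery

def analysis_battery(measures: pd.DataFrame, behavior: pd.DataFrame,
                     n_randomizations: int = 10_000,
                     seed: int | None = 0,
                     alpha: float = ALPHA) -> dict[str, pd.DataFrame]:
    """Run the study's full inferential battery.

    Parameters
    ----------
    measures
        Long table with columns ``subject``, ``group``, ``age``,
        ``analysis`` (one of the measure families below), ``condition``,
        ``electrode``, ``measure``, ``value``.
    behavior
        One row per subject: ``subject``, ``group``, ``age``,
        ``pct_hits_randT``, ``pct_hits_predT``, ``pct_fa``, ``dprime``,
        ``mean_rt_randT``, ``mean_rt_predT``, ``rt_benefit``.

    Returns
    -------
    dict with DataFrames ``behavior_anovas``, ``scalp_anovas`` (electrode x
    age, raw and normalized CNV/P3 to standards and randTs), ``posthoc``
    (per-electrode follow-ups + pairwise randomization tests where the scalp
    interaction is significant), ``predictability_anovas`` (predictability x
    age on CNV at Cz, standard P3 at CPz, target P3 peak amplitude and
    latency at CPz) and ``correlations`` (ERP measures vs age and d', and
    predictability deltas vs the RT benefit).
    """
    rng = np.random.default_rng(seed)
    results: dict[str, pd.DataFrame] = {}

    # (a) behavioral ANOVAs ------------------------------------------------
    rows = []
    for col in ("pct_hits_randT", "pct_fa", "dprime", "mean_rt_randT"):
        tab = _between_anova(behavior.rename(columns={col: "value"}),
                             "subject", "group", "value")
        tab.insert(0, "measure", col)
        tab.insert(1, "factors", "age group")
        rows.append(tab)
    for name, (ca, cb) in (("pct_hits", ("pct_hits_randT", "pct_hits_predT")),
                           ("mean_rt", ("mean_rt_randT", "mean_rt_predT"))):
        long = behavior.melt(id_vars=["subject", "group"], value_vars=[ca, cb],
                             var_name="within", value_name="value")
        long["within"] = long["within"].map({ca: "random", cb: "predicted"})
        tab = rm_anova(long, within="within")
        tab.insert(0, "measure", name)
        tab.insert(1, "factors", "predictability x age group")
        rows.append(tab)
    results["behavior_anovas"] = pd.concat(rows, ignore_index=True)

    # (b) electrode x age scalp ANOVAs ------------------------------------
    scalp_rows, posthoc_rows = [], []
    scalp = measures[measures["analysis"] == "scalp"]
    for (cond, meas, normalized), sub in scalp.groupby(
            ["condition", "measure", "normalized"], observed=True):
        long = sub.rename(columns={"electrode": "within"})
        tab = rm_anova(long, within="within")
        tab.insert(0, "condition", cond)
        tab.insert(1, "measure", meas)
        tab.insert(2, "normalized", normalized)
        scalp_rows.append(tab)
        inter = tab[tab["effect"].str.contains(r"\*")].iloc[0]
        if inter["p_gg"] < alpha:
            posthoc_rows.extend(_per_electrode_followup(
                sub, cond, meas, normalized, n_randomizations, rng, alpha))
    results["scalp_anovas"] = pd.concat(scalp_rows, ignore_index=True)
    results["posthoc"] = pd.DataFrame(
        posthoc_rows, columns=["condition", "measure", "normalized",
                               "electrode", "kind", "groups", "F", "p",
                               "stat", "p_randomization"])

    # (d) predictability x age ANOVAs -------------------------------------
    pred_rows = []
    pred = measures[measures["analysis"] == "predictability"]
    for (meas, electrode), sub in pred.groupby(["measure", "electrode"],
                                               observed=True):
        for pair_tag, pair_conds in (("S2", ("randS2", "predS2")),
                                     ("S3", ("randS3", "predS3")),
                                     ("T", ("randT", "predT"))):
            part = sub[sub["condition"].isin(pair_conds)]
            if part.empty:
                continue
            long = part.copy()
            long["within"] = np.where(
                long["condition"].str.startswith("pred"), "predicted", "random")
            tab = rm_anova(long, within="within")
            tab.insert(0, "measure", meas)
            tab.insert(1, "electrode", electrode)
            tab.insert(2, "pair", pair_tag)
            pred_rows.append(tab)
    results["predictability_anovas"] = pd.concat(pred_rows, ignore_index=True)

    # (e) correlations ------------------------------------------------------
    corr_rows = []
    beh = behavior.set_index("subject")
    norm_scalp = scalp[scalp["normalized"]]
    for (cond, meas, electrode), sub in norm_scalp.groupby(
            ["condition", "measure", "electrode"], observed=True):
        if electrode not in ("Fz", "Pz"):
            continue
        sub = sub.set_index("subject")
        vals = sub["value"]
        predictors = {"age": sub["age"], "dprime": beh.loc[vals.index, "dprime"]}
        for target, series in predictors.items():
            c = pearson_correlation(series.to_numpy(), vals.to_numpy())
            corr_rows.append(dict(x=target,
                                  y=f"normalized {meas} {cond} {electrode}",
                                  r=c.r, b=c.b, p=c.p, n=c.n))
    corr_rows.extend(_prediction_delta_correlations(pred, beh))
    results["correlations"] = pd.DataFrame(corr_rows)
    return results


def _per_electrode_followup(sub: pd.DataFrame, cond, meas, normalized,
                            n_randomizations, rng, alpha):
    """Age-group ANOVA per electrode; pairwise randomization tests if significant."""
    rows = []
    for el, es in sub.groupby("electrode", observed=True):
        tab = _between_anova(es, "subject", "group", "value")
        F, p = tab.loc[0, "F"], tab.loc[0, "p"]
        rows.append((cond, meas, normalized, el, "anova", "all",
                     F, p, np.nan, np.nan))
        if p < alpha:
            by_group = {g: gs["value"].to_numpy()
                        for g, gs in es.groupby("group", observed=True)}
            for ga, gb in combinations(sorted(by_group), 2):
                res = randomization_test(
                    by_group[ga], by_group[gb], n=n_randomizations,
                    seed=int(rng.integers(2 ** 31)))
                rows.append((cond, meas, normalized, el, "randomization",
                             f"{ga} vs {gb}", np.nan, np.nan,
                             res.observed_stat, res.p_value))
    return rows


def _prediction_delta_correlations(pred: pd.DataFrame, beh: pd.DataFrame):
    """Correlate predictability deltas (CNV amp, target-P3 latency) with RT benefit."""
    rows = []
    for meas, electrode, conds, label in (
            ("cnv_amp", "Cz", ("randT", "predT"),
             "CNV amplitude delta (randT - predT) at Cz"),
            ("p3_peak_lat", "CPz", ("randT", "predT"),
             "P3 latency delta (randT - predT) at CPz")):
        sub = pred[(pred["measure"] == meas) & (pred["electrode"] == electrode)
                   & pred["condition"].isin(conds)]
        if sub.empty:
            continue
        wide = sub.pivot_table(index="subject", columns="condition",
                               values="value", observed=True)
        delta = wide[conds[0]] - wide[conds[1]]
        rt_benefit = beh.loc[delta.index, "rt_benefit"]
        c = pearson_correlation(rt_benefit.to_numpy(), delta.to_numpy())
        rows.append(dict(x="rt_benefit", y=label, r=c.r, b=c.b, p=c.p, n=c.n))
    return rows
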