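"""Statistical battery for stiffness tables.

Covers the analyses run on structural-stiffness measurements from two devices
(OCT air-jet indentation in N/mm and a reference impulse-response device in
N/m) over subjects x {upper, lower} limb x {normal, wound, after} status:

* one-way ANOVA with Fisher's LSD post hoc (uncorrected, by definition),
* pooled-variance Student's t-tests,
* two-way mixed-effects ICC, consistency form (ICC(3,1) and ICC(3,k)) with
  F-distribution 95% confidence bounds,
* Cohen's d with a normal-approximation 95% CI plus the pooled-t CI of the
  mean difference,
* Pearson correlation between the two devices.

All estimators are written out from their closed-form sums so they can be
verified against independent references; only the t and F distribution
functions come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IccResult", "EffectSize", "oneway_anova", "lsd_posthoc", "students_t",
    "icc_two_way_mixed", "cohens_d", "pearson", "analysis_report",
    "synthetic_stiffness_table", "significance_pattern",
    "STATUSES", "LOCATIONS",
]

STATUSES = ("normal", "wound", "after")
LOCATIONS = ("upper", "lower")


@dataclass(frozen=True)
class IccResult:
    icc_single: float
    icc_average: float
    ci_single: tuple
    ci_average: tuple
    model: str = "two-way mixed, consistency"


@dataclass(frozen=True)
class EffectSize:
    mean_difference: float
    cohens_d: float
    ci95: tuple          # 95% CI of the mean difference (pooled t)
    d_ci95: tuple        # 95% CI of d (normal approximation)
    n1: int
    n2: int


def _as_groups(groups):
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite values in input")
    return gs


def oneway_anova(groups):
    """Classical one-way ANOVA.

    Returns ``(F, p, ms_error, df_error)`` from the between/within sum-of-
    squares decomposition; identical groups give F = 0, p = 1.
    """
    gs = _as_groups(groups)
    n_tot = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = n_tot - len(gs)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if msb == 0 else np.inf
    else:
        f = msb / msw
    p = 1.0 if f == 0 else float(sps.f.sf(f, df_b, df_w))
    return float(f), p, float(msw), int(df_w)


def lsd_posthoc(groups, ms_error: float, df_error: int, labels=None) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons using the ANOVA error term.

    For each pair: t = (m_i - m_j) / sqrt(MSW * (1/n_i + 1/n_j)) with
    df_error degrees of freedom, two-sided p, no multiplicity correction
    (that is what LSD means).
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels must match the number of groups")
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        diff = gs[i].mean() - gs[j].mean()
        se = np.sqrt(ms_error * (1.0 / gs[i].size + 1.0 / gs[j].size))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        p = 1.0 if t == 0 else float(2 * sps.t.sf(abs(t), df_error))
        rows.append({"a": labels[i], "b": labels[j], "mean_diff": float(diff),
                     "t": float(t), "p": p})
    return pd.DataFrame(rows)


def students_t(x, y):
    """Pooled-variance two-sample t-test; returns ``(t, p, mean_diff)``."""
    x, y = _as_groups([x, y])
    n1, n2 = x.size, y.size
    diff = x.mean() - y.mean()
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = 1.0 if t == 0 else float(2 * sps.t.sf(abs(t), n1 + n2 - 2))
    return float(t), p, float(diff)


def icc_two_way_mixed(matrix, alpha: float = 0.05,
                      form: str = "consistency") -> IccResult:
    """Two-way mixed-effects ICC of a complete subjects x conditions matrix.

    Consistency form (default): ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    and ICC(3,k) = (MS_R - MS_E) / MS_R, with CIs from F-distribution bounds.
    ``form="agreement"`` gives the absolute-agreement ICC(2,1)/(2,k) point
    estimates (CIs only for the consistency form).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    n, k = m.shape
    grand = m.mean()
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "agreement":
        denom1 = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
        icc1 = (ms_r - ms_e) / denom1 if denom1 else 0.0
        denomk = ms_r + (ms_c - ms_e) / n
        icck = (ms_r - ms_e) / denomk if denomk else 0.0
        return IccResult(float(icc1), float(icck), (np.nan, np.nan),
                         (np.nan, np.nan), model="two-way random, agreement")
    if form != "consistency":
        raise ValueError("form must be 'consistency' or 'agreement'")
    icc1 = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    icck = (ms_r - ms_e) / ms_r if ms_r else 0.0
    if ms_e == 0:  # perfect consistency: degenerate CI at the estimate
        return IccResult(float(icc1), float(icck),
                         (float(icc1), float(icc1)), (float(icck), float(icck)))
    fstat = ms_r / ms_e
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = fstat / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = fstat * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_single = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    ci_avg = (1 - 1 / fl, 1 - 1 / fu)
    return IccResult(float(icc1), float(icck),
                     tuple(map(float, ci_single)), tuple(map(float, ci_avg)))


def cohens_d(x, y) -> EffectSize:
    """Pooled-SD Cohen's d between independent samples, with 95% CIs.

    d = (mean_x - mean_y) / s_pooled. The CI of d uses the normal
    approximation SE = sqrt((n1+n2)/(n1*n2) + d^2/(2*(n1+n2))); the CI of the
    mean difference uses the pooled-variance t interval.
    """
    x, y = _as_groups([x, y])
    n1, n2 = x.size, y.size
    diff = x.mean() - y.mean()
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    sp = np.sqrt(sp2)
    if sp == 0:
        if diff != 0:
            raise ValueError("Cohen's d undefined: zero pooled variance with "
                             "unequal means")
        d = 0.0
    else:
        d = diff / sp
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d ** 2 / (2 * (n1 + n2)))
    d_ci = (d - 1.96 * se_d, d + 1.96 * se_d)
    se_diff = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    tcrit = sps.t.ppf(0.975, n1 + n2 - 2)
    diff_ci = (diff - tcrit * se_diff, diff + tcrit * se_diff)
    return EffectSize(mean_difference=float(diff), cohens_d=float(d),
                      ci95=tuple(map(float, diff_ci)),
                      d_ci95=tuple(map(float, d_ci)), n1=n1, n2=n2)


def pearson(x, y):
    """Product-moment correlation; two-sided p via t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("Pearson r undefined for a zero-variance vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return r, float(2 * sps.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# Table-level report
# ---------------------------------------------------------------------------

_COLUMNS = ("subject_id", "location", "status", "device", "k_value")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"stiffness table missing columns {sorted(missing)}")
    t = table.copy()
    dup = t.duplicated(subset=["subject_id", "location", "status", "device"])
    if dup.any():
        raise ValueError(
            f"duplicate (subject, location, status, device) rows: "
            f"{t[dup].head().to_dict('records')}")
    if not np.all(np.isfinite(t["k_value"])) or (t["k_value"] <= 0).any():
        raise ValueError("k_value must be finite and positive")
    return t


def _cell(t, device, location, status):
    sel = t[(t.device == device) & (t.location == location) & (t.status == status)]
    return sel.sort_values("subject_id")["k_value"].to_numpy()


def analysis_report(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full battery over a long-format stiffness table.

    Returns a dict of DataFrames: ``location_ttests`` (upper vs lower per
    device/status), ``status_anova`` (ANOVA + LSD over statuses per
    device/location), ``icc`` (per device, subjects x 6 conditions),
    ``effect_by_status`` and ``effect_by_location`` (Cohen's d tables) and
    ``device_correlation`` (OCT vs reference per location/status), plus a
    ``warnings`` list of skipped contrasts. p-values are flagged at
    alpha and alpha/5 (the conventional 0.05 / 0.01 pair).
    """
    t = _validate_table(table)
    devices = sorted(t.device.unique())
    warnings: list[str] = []

    def flag(p):
        return "**" if p < 0.01 else ("*" if p < alpha else "")

    loc_rows, anova_rows, eff_status_rows, eff_loc_rows, corr_rows = [], [], [], [], []
    icc_rows = []
    statuses = [s for s in STATUSES if s in set(t.status)]
    if len(statuses) < len(STATUSES):
        warnings.append(f"statuses present: {statuses}; ANOVA sections need all "
                        f"three of {STATUSES}")
    for dev in devices:
        # upper vs lower t-test per status
        for status in statuses:
            up, lo = _cell(t, dev, "upper", status), _cell(t, dev, "lower", status)
            if len(up) < 2 or len(lo) < 2:
                warnings.append(f"{dev}/{status}: too few values for t-test")
                continue
            tt, p, diff = students_t(up, lo)
            loc_rows.append({"device": dev, "status": status,
                             "mean_upper": up.mean(), "mean_lower": lo.mean(),
                             "t": tt, "p": p, "sig": flag(p)})
        # status ANOVA + LSD per location
        for loc in LOCATIONS:
            groups = [_cell(t, dev, loc, s) for s in statuses]
            if len(statuses) < 2 or any(len(g) < 2 for g in groups):
                warnings.append(f"{dev}/{loc}: ANOVA skipped (insufficient groups)")
                continue
            f, p, msw, dfw = oneway_anova(groups)
            row = {"device": dev, "location": loc, "F": f, "p": p, "sig": flag(p)}
            for rec in lsd_posthoc(groups, msw, dfw, labels=statuses).to_dict("records"):
                row[f"lsd_{rec['a']}_vs_{rec['b']}_p"] = rec["p"]
                row[f"lsd_{rec['a']}_vs_{rec['b']}_sig"] = flag(rec["p"])
            anova_rows.append(row)
            # pairwise effect sizes across statuses
            for (i, a), (j, b) in combinations(enumerate(statuses), 2):
                es = cohens_d(groups[i], groups[j])
                eff_status_rows.append({
                    "device": dev, "location": loc, "contrast": f"{a}_vs_{b}",
                    "mean_difference": es.mean_difference, "cohens_d": es.cohens_d,
                    "ci95_lo": es.ci95[0], "ci95_hi": es.ci95[1]})
        # upper vs lower effect size per status
        for status in statuses:
            up, lo = _cell(t, dev, "upper", status), _cell(t, dev, "lower", status)
            if len(up) < 2 or len(lo) < 2:
                continue
            es = cohens_d(up, lo)
            eff_loc_rows.append({"device": dev, "status": status,
                                 "mean_difference": es.mean_difference,
                                 "cohens_d": es.cohens_d,
                                 "ci95_lo": es.ci95[0], "ci95_hi": es.ci95[1]})
        # ICC across the six (status x location) conditions
        pivot = t[t.device == dev].pivot_table(
            index="subject_id", columns=["location", "status"], values="k_value")
        if pivot.isna().any().any() or pivot.shape[1] < 2:
            warnings.append(f"{dev}: ICC skipped (incomplete condition matrix)")
        else:
            icc = icc_two_way_mixed(pivot.to_numpy())
            icc_rows.append({"device": dev, "icc_single": icc.icc_single,
                             "icc_average": icc.icc_average,
                             "ci_single_lo": icc.ci_single[0],
                             "ci_single_hi": icc.ci_single[1],
                             "ci_average_lo": icc.ci_average[0],
                             "ci_average_hi": icc.ci_average[1]})
    # cross-device correlation
    if len(devices) == 2:
        d0, d1 = devices
        for loc in LOCATIONS:
            for status in statuses:
                a, b = _cell(t, d0, loc, status), _cell(t, d1, loc, status)
                if len(a) != len(b) or len(a) < 3:
                    warnings.append(f"{loc}/{status}: correlation skipped")
                    continue
                r, p = pearson(a, b)
                corr_rows.append({"location": loc, "status": status, "r": r,
                                  "p": p, "sig": flag(p)})
    else:
        warnings.append("device correlation needs exactly two devices")
    return {
        "location_ttests": pd.DataFrame(loc_rows),
        "status_anova": pd.DataFrame(anova_rows),
        "icc": pd.DataFrame(icc_rows),
        "effect_by_status": pd.DataFrame(eff_status_rows),
        "effect_by_location": pd.DataFrame(eff_loc_rows),
        "device_correlation": pd.DataFrame(corr_rows),
        "warnings": warnings,
    }


# ---------------------------------------------------------------------------
# Synthetic table generator
# ---------------------------------------------------------------------------

#: Default condition means (N/mm, OCT device) for the synthetic cohort:
#: wound skin stiffer than normal and post-treatment skin, with the location
#: contrast confined to wound status (lower-limb wounds stiffer).
DEFAULT_MEANS = {
    ("upper", "normal"): 0.90, ("upper", "wound"): 1.45, ("upper", "after"): 0.95,
    ("lower", "normal"): 0.95, ("lower", "wound"): 2.05, ("lower", "after"): 0.95,
}


def synthetic_stiffness_table(n_subjects: int = 14, seed: int = 0,
                              means: dict | None = None,
                              sigma_subject: float = 0.25,
                              sigma_noise: float = 0.25,
                              reference_scale: float = 450.0,
                              reference_noise: float = 25.0) -> pd.DataFrame:
    """Simulate a repeated-measures stiffness cohort for both devices.

    Each subject carries a random intercept (SD ``sigma_subject``) shared
    across all six (location x status) conditions, plus condition noise
    (SD ``sigma_noise``) — the same subjects are measured in every condition,
    as in a within-subject protocol. The reference device reads the same
    latent stiffness on its own scale (x ``reference_scale``, N/m) with
    instrument noise, so the two devices correlate strongly by construction.
    """
    rng = np.random.default_rng(seed)
    means = DEFAULT_MEANS if means is None else means
    subj_eff = rng.normal(0.0, sigma_subject, n_subjects)
    rows = []
    for s in range(n_subjects):
        for loc in LOCATIONS:
            for status in STATUSES:
                k_oct = means[(loc, status)] + subj_eff[s] + \
                    rng.normal(0.0, sigma_noise)
                k_oct = max(k_oct, 0.05)
                k_ref = max(reference_scale * k_oct +
                            rng.normal(0.0, reference_noise), 1.0)
                rows.append((f"S{s:02d}", loc, status, "oct", k_oct))
                rows.append((f"S{s:02d}", loc, status, "reference", k_ref))
    return pd.DataFrame(rows, columns=_COLUMNS)


def significance_pattern(report: dict, device: str = "oct",
                         alpha: float = 0.05) -> bool:
    """True iff the report shows the expected wound-stiffening signature.

    For the given device: wound vs normal and wound vs after significant at
    both locations; normal vs after not significant; and the upper-vs-lower
    difference significant only for wound status.
    """
    anova = report["status_anova"]
    loc = report["location_ttests"]
    for location in LOCATIONS:
        row = anova[(anova.device == device) & (anova.location == location)]
        if row.empty:
            return False
        row = row.iloc[0]
        if not (row["lsd_normal_vs_wound_p"] < alpha and
                row["lsd_wound_vs_after_p"] < alpha and
                row["lsd_normal_vs_after_p"] >= alpha):
            return False
    for status in STATUSES:
        row = loc[(loc.device == device) & (loc.status == status)]
        if row.empty:
            return False
        sig = row.iloc[0]["p"] < alpha
        if sig != (status == "wound"):
            return False
    return True
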