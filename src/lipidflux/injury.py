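"""Myocardial-injury association statistics.

The injury magnitude per subject is the delta troponin (delta cTnT): peak
minus baseline (pre-PCI) cardiac troponin T.  Lipid associations are
screened with ordinary least squares of delta cTnT on the log concentration
of one species at one timepoint, adjusted for age, sex, BMI, current
smoking, diabetes history and ischemic time.  Severity stratification
compares the top delta-troponin tertile against the combined middle+bottom
tertiles, and MACE vs no-event subjects, with unpaired t-tests on log values
and raw-scale log2 fold changes.  Late-phase trajectories over five
timepoints reuse the repeated-measures ANOVA with pairwise-vs-baseline
Bonferroni contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .temporal import log_transform, rm_anova_gg, species_matrix

__all__ = [
    "DEFAULT_COVARIATES", "RegressionResult", "delta_troponin",
    "adjusted_regression", "tertile_split", "group_fold_change",
    "late_phase_trajectories", "control_comparison", "run_injury_stats",
]

DEFAULT_COVARIATES = ("age", "sex_male", "bmi", "smoker", "diabetes",
                      "ischemic_time_min")


class BaselineError(ValueError):
    """Missing pre-PCI troponin draw."""


def delta_troponin(series: Iterable[Tuple[float, float]], *,
                   baseline_time: float = 0.0,
                   window_hours: Optional[float] = None) -> float:
    """Peak minus baseline troponin (ng/L); never negative.

    ``series`` is (hours, value) pairs; the draw at ``baseline_time`` is the
    pre-PCI baseline, the peak is the maximum over all draws (optionally only
    those within ``window_hours``), baseline included.
    """
    pts = [(float(t), float(v)) for t, v in series]
    if len(pts) < 2:
        raise ValueError("need at least two troponin measurements")
    base = [v for t, v in pts if t == baseline_time]
    if not base:
        raise BaselineError("no_baseline")
    if window_hours is not None:
        pts = [(t, v) for t, v in pts if t <= window_hours]
    peak = max(v for _, v in pts + [(baseline_time, base[0])])
    return peak - base[0]


@dataclass(frozen=True)
class RegressionResult:
    """Covariate-adjusted OLS association of one species with delta cTnT."""

    species: str
    timepoint: str
    b: float                 # unstandardized coefficient, ng/L per log-unit
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates_adjusted: Tuple[str, ...]
    flag: str = ""

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p) and self.p < 0.05


def adjusted_regression(delta: pd.Series, log_lipid: pd.Series,
                        covariates: pd.DataFrame, *,
                        species: str = "", timepoint: str = ""
                        ) -> RegressionResult:
    """OLS of delta cTnT on log lipid concentration plus clinical covariates.

    All three inputs are indexed by subject; rows with any missing value are
    dropped.  Requires >= 10 more subjects than fitted parameters.  A design
    matrix with condition number > 1e8 flags the result as collinear.
    """
    df = pd.concat({"delta": delta, "lipid": log_lipid}, axis=1) \
        .join(covariates, how="inner").dropna()
    covs = tuple(covariates.columns)
    n_params = 2 + len(covs)
    if len(df) < n_params + 10:
        return RegressionResult(species, timepoint, np.nan, np.nan, np.nan,
                                np.nan, len(df), covs, flag="insufficient_n")
    x = sm.add_constant(df[["lipid", *covs]])
    fit = sm.OLS(df["delta"], x).fit()
    flag = ""
    if np.linalg.cond(x.to_numpy()) > 1e8:
        flag = "collinear"
    ci = fit.conf_int().loc["lipid"]
    return RegressionResult(
        species, timepoint, float(fit.params["lipid"]),
        float(ci[0]), float(ci[1]), float(fit.pvalues["lipid"]),
        int(fit.nobs), covs, flag=flag)


def tertile_split(deltas: pd.Series) -> pd.DataFrame:
    """Label each subject 'top' or 'lower' by delta-troponin tertile.

    The top group holds the ceil(n/3) largest values; ties at the boundary go
    to the lower group.  With n = 80 distinct values this gives 27 vs 53.
    An all-equal input yields an empty top group flagged degenerate.
    """
    d = deltas.dropna()
    n = len(d)
    if n < 3:
        raise ValueError("need >= 3 subjects for a tertile split")
    k = int(np.ceil(n / 3))
    cutoff = np.sort(d.to_numpy())[n - k - 1] if n - k - 1 >= 0 else -np.inf
    labels = np.where(d.to_numpy() > cutoff, "top", "lower")
    out = pd.DataFrame({"delta_ctnt": d, "tertile_group": labels}, index=d.index)
    out.attrs["cutoff"] = float(cutoff)
    out.attrs["degenerate"] = bool((labels == "top").sum() == 0)
    # lower-third boundary, reported for reference
    out.attrs["bottom_cutoff"] = float(np.sort(d.to_numpy())[k - 1])
    return out


def group_fold_change(values: pd.Series, labels: pd.Series, *,
                      group_a: str, group_b: str,
                      species: str = "", grouping: str = "") -> Dict[str, object]:
    """log2(mean_A / mean_B) on the raw scale; two-sided unpaired t on logs.

    Both groups need n >= 3; smaller groups yield a flagged NaN result.
    """
    df = pd.concat({"v": values, "g": labels}, axis=1).dropna()
    a = df.loc[df["g"] == group_a, "v"].to_numpy(float)
    b = df.loc[df["g"] == group_b, "v"].to_numpy(float)
    out = {"species": species, "grouping": grouping,
           "n_a": len(a), "n_b": len(b),
           "log2_fc": np.nan, "p": np.nan, "flag": ""}
    if len(a) < 3 or len(b) < 3:
        out["flag"] = "insufficient_n"
        return out
    if a.mean() <= 0 or b.mean() <= 0:
        out["flag"] = "nonpositive_mean"
        return out
    out["log2_fc"] = float(np.log2(a.mean() / b.mean()))
    la, lb = np.log(a[a > 0]), np.log(b[b > 0])
    _, p = stats.ttest_ind(la, lb, equal_var=True)
    out["p"] = float(p)
    return out


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cut, sym in _STAR_LEVELS:
        if p < cut:
            return sym
    return ""


def late_phase_trajectories(conc: pd.DataFrame, meta: pd.DataFrame,
                            species: Sequence[str],
                            timepoints: Sequence[str] = ("t0", "t1", "t2",
                                                         "t3", "t4"),
                            alpha: float = 0.05) -> pd.DataFrame:
    """Early-to-late trajectories for selected species (complete-case subset).

    RM-ANOVA over the five timepoints; pairwise-vs-baseline paired t-tests
    Bonferroni-corrected with m = k-1; star categories at 0.05/0.01/0.001.
    """
    rows = []
    for sp in species:
        mat = species_matrix(conc, meta, sp, timepoints)
        if len(mat) < 3:
            rows.append({"species": sp, "n": len(mat), "p_gg": np.nan,
                         "flag": "insufficient_n"})
            continue
        logm = log_transform(mat).to_numpy()
        res = rm_anova_gg(logm)
        row = {"species": sp, "n": res.n_subjects, "p_gg": res.p_gg,
               "flag": res.flag}
        m = len(timepoints) - 1  # comparisons to baseline only
        base = logm[:, 0]
        for j, tp in enumerate(timepoints[1:], start=1):
            t, p = stats.ttest_rel(logm[:, j], base)
            p_corr = min(1.0, float(p) * m)
            row[f"p_{tp}_vs_t0"] = p_corr
            row[f"stars_{tp}"] = _stars(p_corr)
            row[f"direction_{tp}"] = float(np.sign(logm[:, j].mean()
                                                   - base.mean()))
        rows.append(row)
    return pd.DataFrame(rows)


def control_comparison(conc: pd.DataFrame, meta: pd.DataFrame,
                       species: Sequence[str]) -> pd.DataFrame:
    """STEMI (pre-PCI) vs control comparison for species and their class totals.

    Unpaired two-sided t-tests on log values; raw-scale log2 fold changes.
    """
    m = meta.drop_duplicates("sample_id").set_index("sample_id")
    sub = conc.copy()
    sub["timepoint"] = sub["sample_id"].map(m["timepoint"])
    sub = sub[sub["timepoint"].isin(["t0", "ctrl"])]
    labels = sub.drop_duplicates("sample_id").set_index("sample_id")["timepoint"]

    rows = []
    for sp in species:
        v = sub[sub["species"] == sp].set_index("sample_id")["concentration"]
        rows.append(group_fold_change(v, labels, group_a="t0", group_b="ctrl",
                                      species=sp, grouping="stemi_vs_control"))
        cls = sub.loc[sub["species"] == sp, "lipid_class"]
        if len(cls):
            cls = cls.iloc[0]
            tot = sub[sub["lipid_class"] == cls] \
                .groupby("sample_id")["concentration"].sum()
            rows.append(group_fold_change(
                tot, labels, group_a="t0", group_b="ctrl",
                species=f"total {cls}", grouping="stemi_vs_control"))
    out = pd.DataFrame(rows).drop_duplicates(subset=["species"])
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# study-level driver
# ---------------------------------------------------------------------------

def subject_deltas(troponin: pd.DataFrame, *,
                   window_hours: Optional[float] = None) -> pd.Series:
    """Delta cTnT per subject from a long serial-troponin table."""
    out = {}
    for sid, g in troponin.groupby("subject_id"):
        out[sid] = delta_troponin(zip(g["hours"], g["tnt_ng_l"]),
                                  window_hours=window_hours)
    return pd.Series(out, name="delta_ctnt")


def run_injury_stats(conc: pd.DataFrame, meta: pd.DataFrame,
                     clinical: pd.DataFrame, troponin: pd.DataFrame, *,
                     timepoints: Sequence[str] = ("t0", "t1", "t2"),
                     covariates: Sequence[str] = DEFAULT_COVARIATES,
                     late_species: Optional[Sequence[str]] = None,
                     extra_covariates: Sequence[str] = ()
                     ) -> Dict[str, pd.DataFrame]:
    """Regression screen + tertile/MACE stratification + control comparison."""
    clin = clinical.set_index("subject_id")
    deltas = subject_deltas(troponin)
    covs = clin.loc[deltas.index, list(covariates) + list(extra_covariates)]

    m = meta.drop_duplicates("sample_id").set_index("sample_id")
    sub = conc.copy()
    sub["subject_id"] = sub["sample_id"].map(m["subject_id"])
    sub["timepoint"] = sub["sample_id"].map(m["timepoint"])

    species = sorted(sub["species"].unique())
    reg_rows = []
    for tp in timepoints:
        at_tp = sub[sub["timepoint"] == tp]
        wide = at_tp.pivot_table(index="subject_id", columns="species",
                                 values="concentration", aggfunc="first")
        logw = log_transform(wide)
        for sp in species:
            if sp not in logw.columns:
                continue
            res = adjusted_regression(deltas, logw[sp], covs,
                                      species=sp, timepoint=tp)
            reg_rows.append({
                "species": sp, "timepoint": tp, "b": res.b,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                "n": res.n, "significant": res.significant, "flag": res.flag})
    regression = pd.DataFrame(reg_rows)

    tert = tertile_split(deltas)
    mace = clin.loc[deltas.index, "mace"].map({1: "mace", 0: "none",
                                               True: "mace", False: "none"})
    sig_species = sorted(
        regression.loc[regression["significant"], "species"].unique())

    grp_rows = []
    for tp in timepoints:
        at_tp = sub[sub["timepoint"] == tp]
        wide = at_tp.pivot_table(index="subject_id", columns="species",
                                 values="concentration", aggfunc="first")
        for sp in (sig_species or species):
            if sp not in wide.columns:
                continue
            r = group_fold_change(wide[sp], tert["tertile_group"],
                                  group_a="top", group_b="lower",
                                  species=sp, grouping="tertile_top_vs_rest")
            r["timepoint"] = tp
            grp_rows.append(r)
            r = group_fold_change(wide[sp], mace, group_a="mace",
                                  group_b="none", species=sp,
                                  grouping="mace_vs_none")
            r["timepoint"] = tp
            grp_rows.append(r)
    comparisons = pd.DataFrame(grp_rows)

    late = None
    if late_species:
        late = late_phase_trajectories(sub, meta, late_species)

    controls = control_comparison(conc, meta, sig_species) \
        if sig_species else pd.DataFrame()

    return {"deltas": deltas.to_frame(), "tertiles": tert,
            "regression": regression, "comparisons": comparisons,
            "late_phase": late, "controls": controls}
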