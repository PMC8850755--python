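"""Repeated-measures statistics of the lipidome time course.

Each subject is sampled at every timepoint, so species are tested with a
within-subject (repeated-measures) ANOVA.  Sphericity violations are handled
with the Greenhouse–Geisser correction: the usual F statistic is kept but
both degrees of freedom are multiplied by the epsilon estimated from the
sample covariance of the timepoint measures.  Pairwise timepoint contrasts
use paired t-tests with Bonferroni correction (family = the pairwise
comparisons within a species by default).  Tests run on natural-log
concentrations (half-minimum imputation for zeros); effect sizes are
reported as percent differences of raw-scale means with bootstrap SEMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "ANOVAResult", "rm_anova_gg", "pairwise_bonferroni", "percent_difference",
    "log_transform", "class_totals", "within_class_log_ratio",
    "cluster_heatmap_data", "species_matrix", "run_temporal_stats",
]


# ---------------------------------------------------------------------------
# core tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ANOVAResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction."""

    f_stat: float
    gg_epsilon: float
    p_gg: float
    df_num: float
    df_den: float
    n_subjects: int
    n_timepoints: int
    flag: str = ""


def rm_anova_gg(values: np.ndarray) -> ANOVAResult:
    """Repeated-measures ANOVA on a complete subjects x timepoints matrix.

    F comes from the standard within-subject decomposition; epsilon from the
    Greenhouse–Geisser formula on the double-centered sample covariance of
    the timepoint measures; the p-value from F(eps*(k-1), eps*(k-1)*(n-1)).
    With no within-subject variance at all, F = 0 and p = 1 by convention.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with k >= 2 timepoints")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        return ANOVAResult(np.nan, np.nan, np.nan, np.nan, np.nan, n, k,
                           flag="insufficient_n")

    grand = x.mean()
    subj = x.mean(axis=1, keepdims=True)
    time = x.mean(axis=0, keepdims=True)
    ss_time = n * ((time - grand) ** 2).sum()
    resid = x - subj - time + grand
    ss_err = (resid ** 2).sum()
    df_t, df_e = k - 1, (k - 1) * (n - 1)

    if ss_err <= 0:
        if ss_time <= 0:
            return ANOVAResult(0.0, 1.0, 1.0, df_t, df_e, n, k)
        return ANOVAResult(np.inf, 1.0, 0.0, df_t, df_e, n, k)
    f = (ss_time / df_t) / (ss_err / df_e)

    s = np.cov(x, rowvar=False, ddof=1)
    c = np.eye(k) - np.ones((k, k)) / k
    a = c @ s @ c
    denom = (k - 1) * (a * a).sum()
    eps = (np.trace(a) ** 2) / denom if denom > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    p = float(stats.f.sf(f, eps * df_t, eps * df_e))
    return ANOVAResult(float(f), eps, p, eps * df_t, eps * df_e, n, k)


def pairwise_bonferroni(values: np.ndarray,
                        labels: Sequence[str],
                        alpha: float = 0.05,
                        m: Optional[int] = None) -> pd.DataFrame:
    """Paired t-tests for every timepoint pair with Bonferroni correction.

    ``m`` is the family size (defaults to the number of pairs, k*(k-1)/2);
    p_corrected = min(1, p * m), significance = p_corrected < alpha.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    k = x.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if m is None:
        m = len(pairs)
    rows = []
    for i, j in pairs:
        d = x[:, j] - x[:, i]
        if len(d) < 2 or np.allclose(d.std(ddof=1), 0):
            p = 1.0 if np.allclose(d, 0) or len(d) < 2 else 0.0
            t = 0.0 if p == 1.0 else np.inf * np.sign(d.mean())
        else:
            t, p = stats.ttest_rel(x[:, j], x[:, i])
        p_corr = min(1.0, float(p) * m)
        rows.append({"a": labels[i], "b": labels[j], "t": float(t),
                     "p": float(p), "p_corrected": p_corr,
                     "significant": p_corr < alpha, "n": len(d)})
    return pd.DataFrame(rows)


def percent_difference(a: np.ndarray, b: np.ndarray, *,
                       n_boot: int = 2000, seed: int = 0
                       ) -> Tuple[float, float]:
    """Percent difference of raw-scale means, 100*(mean_b - mean_a)/mean_a,
    with a nonparametric bootstrap SEM over subjects (paired resampling)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) == 0 or a.mean() == 0:
        return np.nan, np.nan
    pct = 100.0 * (b.mean() - a.mean()) / a.mean()
    if len(a) < 2 or n_boot <= 0:
        return float(pct), np.nan
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))
    am = a[idx].mean(axis=1)
    bm = b[idx].mean(axis=1)
    boots = 100.0 * (bm - am) / am
    return float(pct), float(np.std(boots, ddof=1))


# ---------------------------------------------------------------------------
# transforms and aggregations
# ---------------------------------------------------------------------------

def log_transform(wide: pd.DataFrame) -> pd.DataFrame:
    """Natural log with half-minimum imputation for zeros (per species);
    missing values stay missing."""
    x = wide.copy()
    for col in x.columns:
        pos = x[col][x[col] > 0]
        if len(pos):
            x.loc[x[col] == 0, col] = pos.min() / 2.0
    return np.log(x.where(x > 0))


def class_totals(conc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample class totals: sum of retained species within each class.

    Missing species are excluded from the sum; ``coverage`` is the fraction
    of the class's species that contributed.
    """
    if "lipid_class" not in conc.columns:
        raise ValueError("long table needs a lipid_class column")
    g = conc.groupby(["sample_id", "lipid_class"])["concentration"]
    out = g.agg(total="sum", n_present="count").reset_index()
    sizes = conc.groupby("lipid_class")["species"].nunique()
    out["coverage"] = out.apply(
        lambda r: r["n_present"] / sizes[r["lipid_class"]], axis=1)
    return out


def species_matrix(conc: pd.DataFrame, meta: pd.DataFrame, species: str,
                   timepoints: Sequence[str]) -> pd.DataFrame:
    """Complete-case subjects x timepoints matrix for one species (raw scale)."""
    m = meta.drop_duplicates("sample_id").set_index("sample_id")
    sub = conc[conc["species"] == species].copy()
    sub["subject_id"] = sub["sample_id"].map(m["subject_id"])
    sub["timepoint"] = sub["sample_id"].map(m["timepoint"])
    sub = sub[sub["timepoint"].isin(timepoints)]
    mat = sub.pivot_table(index="subject_id", columns="timepoint",
                          values="concentration", aggfunc="first")
    mat = mat.reindex(columns=list(timepoints)).dropna()
    return mat


def within_class_log_ratio(conc: pd.DataFrame, meta: pd.DataFrame,
                           lipid_class: str, reference: str = "t0",
                           log_base: float = 2.0) -> pd.DataFrame:
    """Per-species log ratio of within-class relative concentration vs t0.

    Per sample, each species' share is its concentration divided by the class
    total; the table reports log_base of (mean share at t) / (mean share at
    reference) per species and timepoint — abundance-scale shifts that move
    every species of the class equally cancel out.
    """
    m = meta.drop_duplicates("sample_id").set_index("sample_id")
    sub = conc[conc["lipid_class"] == lipid_class].copy()
    if sub.empty:
        raise ValueError(f"no species of class {lipid_class!r}")
    sub["timepoint"] = sub["sample_id"].map(m["timepoint"])
    totals = sub.groupby("sample_id")["concentration"].transform("sum")
    sub["share"] = sub["concentration"] / totals
    mean_share = sub.groupby(["species", "timepoint"])["share"].mean().unstack()
    if reference not in mean_share.columns:
        raise ValueError(f"reference timepoint {reference!r} absent")
    ratio = mean_share.div(mean_share[reference], axis=0)
    out = np.log(ratio) / np.log(log_base)
    return out.drop(columns=[reference])


def cluster_heatmap_data(matrix: pd.DataFrame, *, log: bool = True
                         ) -> Dict[str, object]:
    """Hierarchical clustering of species rows (Euclidean, complete linkage).

    Returns the linkage matrix, the leaf ordering, and the (log) matrix ready
    for heatmap plotting.
    """
    x = matrix.copy()
    if log:
        x = log_transform(x.T).T
    x = x.dropna()
    if len(x) < 2:
        raise ValueError("need >= 2 complete rows to cluster")
    z = linkage(x.to_numpy(), method="complete", metric="euclidean")
    order = leaves_list(z)
    return {"linkage": z,
            "row_order": [x.index[i] for i in order],
            "matrix": x}


# ---------------------------------------------------------------------------
# study-level driver
# ---------------------------------------------------------------------------

def run_temporal_stats(conc: pd.DataFrame, meta: pd.DataFrame, *,
                       timepoints: Sequence[str] = ("t0", "t1", "t2"),
                       alpha: float = 0.05,
                       bonferroni_family: str = "per_species",
                       n_boot: int = 2000, seed: int = 0
                       ) -> Dict[str, pd.DataFrame]:
    """Per-species RM-ANOVA + pairwise contrasts and class-total summaries.

    ``bonferroni_family``: 'per_species' corrects within each species'
    pairwise comparisons (m = k(k-1)/2); 'study_wide' additionally multiplies
    by the number of species tested.
    """
    species = sorted(conc["species"].unique())
    k = len(timepoints)
    n_pairs = k * (k - 1) // 2
    if bonferroni_family == "per_species":
        m_family = n_pairs
    elif bonferroni_family == "study_wide":
        m_family = n_pairs * len(species)
    else:
        raise ValueError(f"unknown bonferroni_family {bonferroni_family!r}")

    anova_rows, pair_rows = [], []
    for i, sp in enumerate(species):
        mat = species_matrix(conc, meta, sp, timepoints)
        if mat.empty or len(mat) < 3:
            anova_rows.append({"species": sp, "n": len(mat), "f_stat": np.nan,
                               "gg_epsilon": np.nan, "p_gg": np.nan,
                               "flag": "insufficient_n"})
            continue
        logm = log_transform(mat)
        res = rm_anova_gg(logm.to_numpy())
        anova_rows.append({"species": sp, "n": res.n_subjects,
                           "f_stat": res.f_stat, "gg_epsilon": res.gg_epsilon,
                           "p_gg": res.p_gg, "flag": res.flag})
        pw = pairwise_bonferroni(logm.to_numpy(), list(timepoints),
                                 alpha=alpha, m=m_family)
        raw = mat.to_numpy()
        cols = list(mat.columns)
        for j, row in pw.iterrows():
            ia, ib = cols.index(row["a"]), cols.index(row["b"])
            pct, sem = percent_difference(raw[:, ia], raw[:, ib],
                                          n_boot=n_boot, seed=seed + i)
            pair_rows.append({"species": sp, **row.to_dict(),
                              "pct_diff": pct, "pct_sem": sem})

    anova_df = pd.DataFrame(anova_rows)
    pairwise_df = pd.DataFrame(pair_rows)

    # class totals: same machinery on per-subject class sums
    totals = class_totals(conc)
    totals = totals.rename(columns={"lipid_class": "species",
                                    "total": "concentration"})
    totals["lipid_class"] = totals["species"]
    cls_rows, cls_pairs = [], []
    for cls in sorted(totals["species"].unique()):
        mat = species_matrix(totals, meta, cls, timepoints)
        if len(mat) < 3:
            continue
        logm = log_transform(mat)
        res = rm_anova_gg(logm.to_numpy())
        pw = pairwise_bonferroni(logm.to_numpy(), list(timepoints),
                                 alpha=alpha, m=n_pairs)
        raw = mat.to_numpy()
        cols = list(mat.columns)
        means = {f"mean_{tp}": raw[:, cols.index(tp)].mean() for tp in cols}
        sems = {f"sem_{tp}": raw[:, cols.index(tp)].std(ddof=1) / np.sqrt(len(raw))
                for tp in cols}
        cls_rows.append({"lipid_class": cls, "n": res.n_subjects,
                         "p_gg": res.p_gg, **means, **sems})
        for _, row in pw.iterrows():
            ia, ib = cols.index(row["a"]), cols.index(row["b"])
            pct, sem = percent_difference(raw[:, ia], raw[:, ib],
                                          n_boot=n_boot, seed=seed)
            cls_pairs.append({"lipid_class": cls, **row.to_dict(),
                              "pct_diff": pct, "pct_sem": sem})

    return {"anova": anova_df, "pairwise": pairwise_df,
            "class_summary": pd.DataFrame(cls_rows),
            "class_pairwise": pd.DataFrame(cls_pairs)}
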