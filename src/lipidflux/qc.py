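"""Pooled-QC drift normalization and reproducibility filtering.

The pooled plasma QC (PQC) — equal aliquots of every study sample, injected
throughout each batch — has constant composition, so any structure in its
measured intensities is systematic error.  Two removal methods share one
contract (the PQC median of every species is preserved):

* **SERRF-style** random-forest normalization: per species, a forest is fit
  on the PQCs with injection order, batch, and the k most PQC-correlated
  other species as predictors, then predicts the systematic component for
  every injection; normalized = raw * median(PQC raw) / predicted.
* **loess** fallback: per species and batch, a local regression of PQC
  intensity on injection order, interpolated to every injection.

After correction, species are retained only when their coefficient of
variation (CoV = sd/mean*100) across PQCs is below the threshold (20% by
default) and their highest sample-type mean is not in the blank extracts.
"""

from __future__ import annotations

import logging
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["SerrfNormalizer", "serrf_normalize", "loess_normalize",
           "qc_filter", "pca_qc", "QCError"]

log = logging.getLogger(__name__)


class QCError(ValueError):
    pass


def _to_wide(conc: pd.DataFrame) -> pd.DataFrame:
    return conc.pivot_table(index="sample_id", columns="species",
                            values="concentration", aggfunc="first")


def _to_long(wide: pd.DataFrame, template: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack(future_stack=True).rename("concentration").reset_index()
    long.columns = ["sample_id", "species", "concentration"]
    keep = [c for c in template.columns
            if c not in ("concentration",)]
    meta_cols = template[keep].drop_duplicates(["sample_id", "species"])
    out = meta_cols.merge(long, on=["sample_id", "species"], how="right")
    return out[template.columns]


def _meta_indexed(meta: pd.DataFrame, index) -> pd.DataFrame:
    m = meta.drop_duplicates("sample_id").set_index("sample_id")
    missing = [i for i in index if i not in m.index]
    if missing:
        raise QCError(f"metadata missing for samples: {missing[:5]} ...")
    return m.loc[index]


class SerrfNormalizer:
    """Systematic-error removal using random forests, anchored on PQCs.

    sklearn-style transformer over a wide (samples x species) table; the
    functional wrapper :func:`serrf_normalize` handles long tables.

    Parameters
    ----------
    k_correlated : number of most PQC-correlated companion species used as
        predictors alongside injection order and batch.
    trees : forest size per species.
    seed : RNG seed for the forests.
    min_pqc_per_batch : below this the method falls back to loess.
    """

    def __init__(self, k_correlated: int = 10, trees: int = 500,
                 seed: int = 0, min_pqc_per_batch: int = 5):
        self.k_correlated = k_correlated
        self.trees = trees
        self.seed = seed
        self.min_pqc_per_batch = min_pqc_per_batch

    def get_params(self, deep: bool = True) -> Dict[str, object]:
        return {"k_correlated": self.k_correlated, "trees": self.trees,
                "seed": self.seed, "min_pqc_per_batch": self.min_pqc_per_batch}

    def set_params(self, **params) -> "SerrfNormalizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit_transform(self, wide: pd.DataFrame, meta: pd.DataFrame
                      ) -> pd.DataFrame:
        m = _meta_indexed(meta, wide.index)
        is_pqc = (m["sample_type"] == "pqc").to_numpy()
        if is_pqc.sum() == 0:
            raise QCError("no PQC samples; cannot normalize")
        pqc_per_batch = m.loc[is_pqc].groupby("batch").size()
        if (pqc_per_batch < self.min_pqc_per_batch).any() or \
                set(m["batch"].unique()) - set(pqc_per_batch.index):
            log.warning("fewer than %d PQCs in some batch: falling back to "
                        "loess normalization", self.min_pqc_per_batch)
            return _loess_wide(wide, m)

        order = m["injection_order"].to_numpy(float)
        batch = pd.factorize(m["batch"])[0].astype(float)
        logx = np.log(wide.where(wide > 0))

        # companion-species correlations measured on PQCs only
        pqc_log = logx.loc[is_pqc]
        corr = pqc_log.corr()

        # Companion features are standardized group-wise: PQC rows by PQC
        # statistics, all other rows by their own statistics.  Training rows
        # and prediction rows then live on the same scale, and bulk
        # biological differences between study samples and the pool do not
        # masquerade as systematic error (the original SERRF scaling).
        sd_floor = 1e-12
        mu_p = pqc_log.mean()
        sd_p = pqc_log.std(ddof=1).clip(lower=sd_floor)
        other_log = logx.loc[~is_pqc]
        mu_o = other_log.mean()
        sd_o = other_log.std(ddof=1).clip(lower=sd_floor)
        z = logx.copy()
        z.loc[is_pqc] = (pqc_log - mu_p) / sd_p
        z.loc[~is_pqc] = (other_log - mu_o) / sd_o

        out = wide.copy()
        rng = np.random.default_rng(self.seed)
        for j, sp in enumerate(wide.columns):
            y = logx[sp].to_numpy()
            ok_pqc = is_pqc & np.isfinite(y)
            if ok_pqc.sum() < self.min_pqc_per_batch:
                continue
            comp = corr[sp].drop(index=sp).abs().dropna()
            companions = comp.sort_values(ascending=False) \
                             .head(self.k_correlated).index.tolist()
            feats = [order, batch] + [z[c].to_numpy() for c in companions]
            X = np.column_stack(feats)
            X = np.where(np.isfinite(X), X, 0.0)

            rf = RandomForestRegressor(
                n_estimators=self.trees, min_samples_leaf=2,
                random_state=int(rng.integers(2**31)), n_jobs=1)
            rf.fit(X[ok_pqc], y[ok_pqc])
            pred = rf.predict(X)
            norm = wide[sp].to_numpy() * np.exp(np.median(y[ok_pqc]) - pred)
            # enforce the median-preservation contract exactly
            med_raw = np.nanmedian(wide[sp].to_numpy()[is_pqc])
            med_new = np.nanmedian(norm[is_pqc])
            if np.isfinite(med_new) and med_new > 0:
                norm *= med_raw / med_new
            out[sp] = norm
        return out


def _loess_wide(wide: pd.DataFrame, m: pd.DataFrame, span: float = 0.75
                ) -> pd.DataFrame:
    is_pqc = (m["sample_type"] == "pqc").to_numpy()
    if is_pqc.sum() == 0:
        raise QCError("no PQC samples; cannot normalize")
    order = m["injection_order"].to_numpy(float)
    batches = m["batch"].to_numpy()
    out = wide.copy()
    for sp in wide.columns:
        raw = wide[sp].to_numpy(float)
        y = np.log(np.where(raw > 0, raw, np.nan))
        trend = np.zeros_like(y)
        usable = True
        for b in np.unique(batches):
            mb = batches == b
            mp = mb & is_pqc & np.isfinite(y)
            if mp.sum() < 2:
                usable = False
                break
            fit = lowess(y[mp], order[mp], frac=span, return_sorted=True)
            trend[mb] = np.interp(order[mb], fit[:, 0], fit[:, 1])
        if not usable:
            continue
        pqc_med = np.nanmedian(y[is_pqc & np.isfinite(y)])
        norm = raw * np.exp(pqc_med - trend)
        med_raw = np.nanmedian(raw[is_pqc])
        med_new = np.nanmedian(norm[is_pqc])
        if np.isfinite(med_new) and med_new > 0:
            norm *= med_raw / med_new
        out[sp] = norm
    return out


def serrf_normalize(conc: pd.DataFrame, meta: pd.DataFrame, *,
                    k_correlated: int = 10, trees: int = 500,
                    seed: int = 0) -> pd.DataFrame:
    """SERRF-style normalization of a long concentration table."""
    wide = _to_wide(conc)
    norm = SerrfNormalizer(k_correlated=k_correlated, trees=trees,
                           seed=seed).fit_transform(wide, meta)
    return _to_long(norm, conc)


def loess_normalize(conc: pd.DataFrame, meta: pd.DataFrame,
                    span: float = 0.75) -> pd.DataFrame:
    """Deterministic local-regression drift normalization (PQC-anchored)."""
    wide = _to_wide(conc)
    m = _meta_indexed(meta, wide.index)
    return _to_long(_loess_wide(wide, m, span=span), conc)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def qc_filter(conc: pd.DataFrame, meta: pd.DataFrame,
              threshold_pct: float = 20.0
              ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop species failing PQC reproducibility or the blank rule.

    Returns (filtered long table, per-species metrics) where metrics has
    columns species, cov_pqc, blank_max_flag, retained, reason.
    """
    wide = _to_wide(conc)
    m = _meta_indexed(meta, wide.index)
    if not (m["sample_type"] == "pqc").any():
        raise QCError("no PQC samples; cannot compute CoV")

    grp_mean = wide.groupby(m["sample_type"].to_numpy()).mean()
    pqc = wide.loc[(m["sample_type"] == "pqc").to_numpy()]
    cov = pqc.std(ddof=1) / pqc.mean() * 100.0

    has_blanks = "blank" in grp_mean.index
    if has_blanks:
        blank_max = grp_mean.idxmax() == "blank"
    else:
        blank_max = pd.Series(False, index=wide.columns)

    rows = []
    for sp in wide.columns:
        c = cov.get(sp, np.nan)
        bm = bool(blank_max.get(sp, False))
        if not np.isfinite(c):
            retained, reason = False, "no_pqc_data"
        elif c >= threshold_pct:
            retained, reason = False, "cov"
        elif bm:
            retained, reason = False, "blank_max"
        else:
            retained, reason = True, ""
        rows.append((sp, c, bm, retained, reason))
    metrics = pd.DataFrame(rows, columns=["species", "cov_pqc",
                                          "blank_max_flag", "retained", "reason"])
    kept = set(metrics.loc[metrics["retained"], "species"])
    return conc[conc["species"].isin(kept)].copy(), metrics


# ---------------------------------------------------------------------------
# PCA consistency report
# ---------------------------------------------------------------------------

def pca_qc(conc: pd.DataFrame, meta: pd.DataFrame) -> Dict[str, object]:
    """2-component PCA of log concentrations with QC-replicate dispersion.

    Reports, for each replicated sample type (PQC, SRM), the mean distance of
    its scores to the type centroid divided by the overall score dispersion;
    tight QC clustering (ratio << 1) indicates consistent data.
    """
    wide = _to_wide(conc)
    if len(wide) < 3:
        raise QCError(">=3 samples required for the PCA consistency check")
    m = _meta_indexed(meta, wide.index)

    X = np.log(wide.where(wide > 0))
    # half-minimum imputation for zeros/missing, per species
    fill = np.log(wide[wide > 0].min() / 2.0)
    X = X.fillna(fill).dropna(axis=1)
    if X.shape[1] < 2:
        raise QCError("not enough usable species for PCA")
    scores = PCA(n_components=2).fit_transform(X.to_numpy())

    overall = float(np.mean(np.linalg.norm(
        scores - scores.mean(axis=0), axis=1)))
    report: Dict[str, object] = {"scores": pd.DataFrame(
        scores, index=wide.index, columns=["pc1", "pc2"]),
        "overall_dispersion": overall, "types": {}}
    for typ in ("pqc", "srm"):
        sel = (m["sample_type"] == typ).to_numpy()
        if sel.sum() >= 2:
            s = scores[sel]
            within = float(np.mean(np.linalg.norm(s - s.mean(axis=0), axis=1)))
            report["types"][typ] = {
                "n": int(sel.sum()), "within_dispersion": within,
                "relative_dispersion": within / overall if overall > 0 else 0.0}
    return report
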