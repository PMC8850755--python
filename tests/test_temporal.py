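import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidflux.temporal import (class_totals, cluster_heatmap_data,
                                log_transform, pairwise_bonferroni,
                                percent_difference, rm_anova_gg,
                                within_class_log_ratio)


# ---------------------------------------------------------------------------
# RM-ANOVA with Greenhouse-Geisser
# ---------------------------------------------------------------------------

def test_constant_data_gives_f_zero_p_one():
    x = np.tile(np.array([[3.0, 3.0, 3.0]]), (10, 1)) \
        + np.arange(10)[:, None] * 0.0
    res = rm_anova_gg(x)
    assert res.f_stat == 0.0 and res.p_gg == 1.0


def test_subject_offsets_only_gives_f_zero():
    x = np.tile(np.arange(10.0)[:, None], (1, 3))  # between-subject variance only
    res = rm_anova_gg(x)
    assert res.f_stat == 0.0 and res.p_gg == 1.0


def test_k2_equals_paired_t():
    rng = np.random.default_rng(12)
    for _ in range(20):
        x = rng.normal(size=(14, 2)) + rng.normal(size=(14, 1))
        res = rm_anova_gg(x)
        t, p = stats.ttest_rel(x[:, 1], x[:, 0])
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)
        assert res.p_gg == pytest.approx(p, rel=1e-10)
        assert res.gg_epsilon == 1.0


def test_epsilon_tends_to_one_under_compound_symmetry():
    rng = np.random.default_rng(3)
    eps = []
    for _ in range(40):
        x = rng.normal(size=(200, 3)) + rng.normal(size=(200, 1))
        eps.append(rm_anova_gg(x).gg_epsilon)
    assert np.mean(eps) > 0.9


def test_matches_pingouin_oracle():
    """Independent cross-check of F, epsilon and corrected p on random data."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    x = rng.normal(size=(25, 4)) + rng.normal(size=(25, 1)) \
        + rng.normal(size=(1, 4))
    df = pd.DataFrame(x, columns=list("abcd")).reset_index().melt(
        id_vars="index", var_name="time", value_name="y")
    ref = pingouin.rm_anova(data=df, dv="y", within="time", subject="index",
                            correction=True)
    res = rm_anova_gg(x)
    assert res.f_stat == pytest.approx(float(ref["F"][0]), rel=1e-6)
    assert res.gg_epsilon == pytest.approx(float(ref["eps"][0]), rel=1e-6)
    assert res.p_gg == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)


def test_insufficient_subjects_flagged():
    res = rm_anova_gg(np.array([[1.0, 2.0], [2.0, 1.0]]))
    assert res.flag == "insufficient_n"


def test_null_pvalues_uniform():
    rng = np.random.default_rng(42)
    ps = [rm_anova_gg(rng.normal(size=(20, 3))).p_gg for _ in range(400)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# pairwise comparisons
# ---------------------------------------------------------------------------

def test_identical_groups_corrected_p_is_one():
    x = np.tile(np.array([[1.0, 1.0, 1.0]]), (8, 1))
    pw = pairwise_bonferroni(x, ["t0", "t1", "t2"])
    assert (pw["p_corrected"] == 1.0).all()
    assert not pw["significant"].any()


def test_bonferroni_arithmetic():
    """p=0.02 with m=3 corrects to 0.06: not significant."""
    rng = np.random.default_rng(0)
    x = rng.normal(size=(30, 3))
    pw = pairwise_bonferroni(x, ["t0", "t1", "t2"])
    for _, r in pw.iterrows():
        assert r["p_corrected"] == pytest.approx(min(1.0, r["p"] * 3))
    assert min(1.0, 0.02 * 3) == pytest.approx(0.06)


def test_family_size_override():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(30, 3))
    pw3 = pairwise_bonferroni(x, ["t0", "t1", "t2"], m=3)
    pw9 = pairwise_bonferroni(x, ["t0", "t1", "t2"], m=9)
    assert (pw9["p_corrected"] >= pw3["p_corrected"]).all()


# ---------------------------------------------------------------------------
# percent difference
# ---------------------------------------------------------------------------

def test_percent_difference_examples():
    a = np.full(10, 10.0)
    pct, _ = percent_difference(a, a, n_boot=100, seed=0)
    assert pct == 0.0
    pct, sem = percent_difference(np.full(10, 10.0), np.full(10, 7.0),
                                  n_boot=100, seed=0)
    assert pct == pytest.approx(-30.0)
    assert sem == pytest.approx(0.0, abs=1e-12)


def test_percent_difference_reciprocal_relation():
    rng = np.random.default_rng(9)
    a = rng.lognormal(2, 0.3, 60)
    b = rng.lognormal(2.2, 0.3, 60)
    d_ab, _ = percent_difference(a, b, n_boot=0)
    d_ba, _ = percent_difference(b, a, n_boot=0)
    assert (1 + d_ab / 100) * (1 + d_ba / 100) == pytest.approx(1.0)


def test_bootstrap_sem_reasonable():
    rng = np.random.default_rng(4)
    a = rng.lognormal(0, 0.3, 50)
    b = a * 0.8 * rng.lognormal(0, 0.2, 50)
    pct, sem = percent_difference(a, b, n_boot=2000, seed=1)
    assert sem > 0
    # SEM should be in the ballpark of the delta-method scale
    assert sem < 50


# ---------------------------------------------------------------------------
# class totals and within-class ratios
# ---------------------------------------------------------------------------

def _long(values: dict, cls="PC"):
    rows = []
    for sid, species_vals in values.items():
        for sp, v in species_vals.items():
            rows.append({"sample_id": sid, "species": sp, "lipid_class": cls,
                         "concentration": v, "flags": ""})
    return pd.DataFrame(rows)


def test_class_total_single_species():
    conc = _long({"s1": {"PC 34:1": 12.5}})
    out = class_totals(conc)
    assert out.iloc[0]["total"] == 12.5 and out.iloc[0]["coverage"] == 1.0


def test_class_total_order_invariance():
    conc = _long({"s1": {"PC 34:1": 1.0, "PC 36:2": 2.0, "PC 38:4": 4.0}})
    shuffled = conc.sample(frac=1.0, random_state=0)
    t1 = class_totals(conc).iloc[0]["total"]
    t2 = class_totals(shuffled).iloc[0]["total"]
    assert t1 == t2 == 7.0


def _meta_for(samples_tp):
    return pd.DataFrame([{"sample_id": sid, "sample_type": "study",
                          "batch": 1, "injection_order": i + 1,
                          "subject_id": f"sub{i}", "timepoint": tp}
                         for i, (sid, tp) in enumerate(samples_tp.items())])


def test_log_ratio_single_species_class_is_zero():
    conc = _long({"a": {"PC 34:1": 5.0}, "b": {"PC 34:1": 50.0}})
    meta = _meta_for({"a": "t0", "b": "t1"})
    out = within_class_log_ratio(conc, meta, "PC")
    assert out.loc["PC 34:1", "t1"] == pytest.approx(0.0)


def test_log_ratio_invariant_to_uniform_class_scaling():
    base = {"PC 34:1": 2.0, "PC 36:2": 6.0}
    conc = _long({"a": base, "b": {k: 3.0 * v for k, v in base.items()}})
    meta = _meta_for({"a": "t0", "b": "t1"})
    out = within_class_log_ratio(conc, meta, "PC")
    assert np.allclose(out["t1"], 0.0)


def test_log_ratio_detects_single_species_shift():
    base = {"PC 34:1": 2.0, "PC 36:2": 6.0, "PC 36:6": 4.0}
    shifted = dict(base, **{"PC 36:6": 6.0})   # x1.5 on one species only
    conc = _long({"a": base, "b": shifted})
    meta = _meta_for({"a": "t0", "b": "t1"})
    out = within_class_log_ratio(conc, meta, "PC")
    assert out.loc["PC 36:6", "t1"] > 0
    assert out.loc["PC 34:1", "t1"] < 0
    assert out.loc["PC 36:2", "t1"] < 0


# ---------------------------------------------------------------------------
# clustered heatmap
# ---------------------------------------------------------------------------

def test_identical_rows_merge_at_height_zero():
    mat = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
                       index=["a", "b", "c"])
    out = cluster_heatmap_data(mat, log=False)
    assert out["linkage"][0, 2] == pytest.approx(0.0)
    order = out["row_order"]
    assert abs(order.index("a") - order.index("b")) == 1


def test_linkage_matches_bruteforce_agglomeration():
    """Complete-linkage merges on a 4-row matrix equal exhaustive agglomeration."""
    rng = np.random.default_rng(6)
    x = rng.normal(size=(4, 3))
    mat = pd.DataFrame(x, index=list("abcd"))
    z = cluster_heatmap_data(mat, log=False)["linkage"]

    # brute-force complete-linkage agglomeration
    clusters = {i: [i] for i in range(4)}
    heights = []
    next_id = 4
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i < j:
                    d = max(np.linalg.norm(x[a] - x[b])
                            for a in clusters[i] for b in clusters[j])
                    if best is None or d < best[0]:
                        best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    assert np.allclose(sorted(z[:, 2]), sorted(heights))


def test_three_abundance_tiers_recovered():
    rng = np.random.default_rng(2)
    tiers = {"hi": 1000.0, "mid": 30.0, "lo": 1.0}
    rows, labels = [], []
    for tier, level in tiers.items():
        for i in range(4):
            rows.append(level * np.exp(rng.normal(0, 0.1, 5)))
            labels.append(tier)
    mat = pd.DataFrame(rows, index=[f"{t}{i}" for i, t in enumerate(labels)])
    out = cluster_heatmap_data(mat)
    from scipy.cluster.hierarchy import fcluster
    cut = fcluster(out["linkage"], t=3, criterion="maxclust")
    groups = {}
    for lab, c in zip(labels, cut):
        groups.setdefault(lab, set()).add(c)
    assert all(len(v) == 1 for v in groups.values())
    assert len(set.union(*groups.values())) == 3


def test_log_transform_half_minimum_imputation():
    wide = pd.DataFrame({"PC 34:1": [0.0, 4.0, 8.0]})
    out = log_transform(wide)
    assert out.iloc[0, 0] == pytest.approx(np.log(2.0))
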