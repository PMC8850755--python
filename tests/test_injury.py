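import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidflux.injury import (BaselineError, adjusted_regression,
                              control_comparison, delta_troponin,
                              group_fold_change, late_phase_trajectories,
                              subject_deltas, tertile_split)


# ---------------------------------------------------------------------------
# delta troponin
# ---------------------------------------------------------------------------

def test_delta_troponin_peak_minus_baseline():
    series = [(0, 120.0), (6, 900.0), (12, 5943.5), (24, 3000.0)]
    assert delta_troponin(series) == pytest.approx(5823.5)


def test_delta_troponin_flat_series_zero():
    assert delta_troponin([(0, 200.0), (12, 200.0), (24, 200.0)]) == 0.0


def test_delta_troponin_never_negative():
    assert delta_troponin([(0, 500.0), (12, 100.0)]) == 0.0


def test_delta_troponin_missing_baseline():
    with pytest.raises(BaselineError, match="no_baseline"):
        delta_troponin([(6, 900.0), (12, 1200.0)])


def test_delta_troponin_window():
    series = [(0, 100.0), (24, 500.0), (96, 9000.0)]
    assert delta_troponin(series, window_hours=72) == 400.0


# ---------------------------------------------------------------------------
# adjusted regression
# ---------------------------------------------------------------------------

def _sim_regression(seed, n=80, b=800.0, conf=False):
    rng = np.random.default_rng(seed)
    idx = [f"S{i}" for i in range(n)]
    cov = pd.DataFrame({
        "age": rng.normal(64, 12, n),
        "sex_male": rng.integers(0, 2, n),
        "bmi": rng.normal(28, 4, n),
        "smoker": rng.integers(0, 2, n),
        "diabetes": rng.integers(0, 2, n),
        "ischemic_time_min": rng.normal(150, 60, n)}, index=idx)
    lipid = pd.Series(rng.normal(0, 0.3, n), index=idx)
    if conf:
        lipid = lipid + 0.02 * (cov["age"] - 64)
    delta = pd.Series(2500 + b * lipid.to_numpy()
                      + (40.0 * (cov["age"] - 64) if conf else 0.0)
                      + rng.normal(0, 600, n), index=idx)
    if conf:
        # no direct lipid effect in the confounded scenario
        delta = pd.Series(2500 + 40.0 * (cov["age"] - 64)
                          + rng.normal(0, 600, n), index=idx)
    return delta, lipid, cov


def test_adjusted_equals_simple_regression_without_covariate_effects():
    """With covariates orthogonal to everything, the lipid coefficient equals
    the two-variable normal-equations solution."""
    delta, lipid, cov = _sim_regression(0)
    res = adjusted_regression(delta, lipid, cov[[]])  # no covariates at all
    x = np.column_stack([np.ones(len(lipid)), lipid.to_numpy()])
    beta = np.linalg.solve(x.T @ x, x.T @ delta.to_numpy())
    assert res.b == pytest.approx(beta[1], abs=1e-8)


def test_null_rejection_rate_is_nominal():
    """Type-I error of the adjusted regression ~5% (2000 reps)."""
    hits = 0
    n_rep = 2000
    for seed in range(n_rep):
        delta, lipid, cov = _sim_regression(seed, b=0.0)
        res = adjusted_regression(delta, lipid, cov)
        hits += res.p < 0.05
    assert hits / n_rep == pytest.approx(0.05, abs=0.015)


def test_planted_coefficient_sign_and_ci_coverage():
    signs = covered = 0
    n_rep = 300
    for seed in range(n_rep):
        delta, lipid, cov = _sim_regression(seed, b=800.0)
        res = adjusted_regression(delta, lipid, cov)
        signs += res.b > 0
        covered += res.ci_low <= 800.0 <= res.ci_high
    assert signs / n_rep > 0.99
    assert covered / n_rep >= 0.93


def test_confounding_removed_by_adjustment():
    sig_unadj = sig_adj = 0
    for seed in range(100):
        delta, lipid, cov = _sim_regression(seed, conf=True)
        unadj = adjusted_regression(delta, lipid, cov[[]])
        adj = adjusted_regression(delta, lipid, cov)
        sig_unadj += unadj.p < 0.05
        sig_adj += adj.p < 0.05
    assert sig_unadj / 100 > 0.5       # age-confounded association
    assert sig_adj / 100 < 0.15        # vanishes after adjustment


def test_insufficient_subjects_flagged():
    delta, lipid, cov = _sim_regression(1, n=12)
    res = adjusted_regression(delta, lipid, cov)
    assert res.flag == "insufficient_n"


def test_collinear_covariates_flagged():
    delta, lipid, cov = _sim_regression(2)
    cov = cov.copy()
    cov["age_copy"] = cov["age"] * 1.0000000001
    res = adjusted_regression(delta, lipid, cov)
    assert res.flag == "collinear"


# ---------------------------------------------------------------------------
# tertile split
# ---------------------------------------------------------------------------

def test_tertile_split_80_subjects_27_vs_53():
    rng = np.random.default_rng(0)
    d = pd.Series(rng.permutation(np.arange(80) * 100.0 + 50),
                  index=[f"S{i}" for i in range(80)])
    out = tertile_split(d)
    counts = out["tertile_group"].value_counts()
    assert counts["top"] == 27 and counts["lower"] == 53


def test_tertile_split_exact_thirds():
    d = pd.Series(np.arange(1.0, 10.0), index=list("abcdefghi"))
    out = tertile_split(d)
    top = set(out.index[out["tertile_group"] == "top"])
    assert top == {"g", "h", "i"}


def test_tertile_split_degenerate_all_equal():
    d = pd.Series(np.full(9, 5.0))
    out = tertile_split(d)
    assert out.attrs["degenerate"]
    assert (out["tertile_group"] == "lower").all()


@settings(max_examples=50, deadline=None)
@given(n=st.integers(6, 120), seed=st.integers(0, 10_000))
def test_tertile_sizes_near_third_for_distinct_values(n, seed):
    rng = np.random.default_rng(seed)
    d = pd.Series(rng.permutation(np.arange(n, dtype=float)))
    out = tertile_split(d)
    top = (out["tertile_group"] == "top").sum()
    assert abs(top - int(np.ceil(n / 3))) <= 1


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_fold_change_identical_means():
    v = pd.Series(np.r_[np.full(5, 10.0), np.full(5, 10.0)])
    g = pd.Series(["a"] * 5 + ["b"] * 5)
    out = group_fold_change(v, g, group_a="a", group_b="b")
    assert out["log2_fc"] == pytest.approx(0.0)


def test_fold_change_two_to_one():
    rng = np.random.default_rng(0)
    v = pd.Series(np.r_[200 * np.exp(rng.normal(0, 1e-8, 10)),
                        100 * np.exp(rng.normal(0, 1e-8, 10))])
    g = pd.Series(["a"] * 10 + ["b"] * 10)
    out = group_fold_change(v, g, group_a="a", group_b="b")
    assert out["log2_fc"] == pytest.approx(1.0, abs=1e-6)


def test_fold_change_requires_three_per_group():
    v = pd.Series([1.0, 2.0, 3.0, 4.0])
    g = pd.Series(["a", "a", "b", "b"])
    assert group_fold_change(v, g, group_a="a", group_b="b")["flag"] == \
        "insufficient_n"


# ---------------------------------------------------------------------------
# late phase and controls
# ---------------------------------------------------------------------------

def _late_phase_tables(traj, n=12, sigma=0.05, seed=0):
    rng = np.random.default_rng(seed)
    tps = ["t0", "t1", "t2", "t3", "t4"]
    rows, meta = [], []
    for i in range(n):
        for j, tp in enumerate(tps):
            sid = f"S{i}_{tp}"
            meta.append({"sample_id": sid, "sample_type": "study", "batch": 1,
                         "injection_order": len(meta) + 1,
                         "subject_id": f"S{i}", "timepoint": tp})
            rows.append({"sample_id": sid, "species": "acylcarnitine 18:2",
                         "lipid_class": "acylcarnitine",
                         "concentration": traj[j] * np.exp(
                             rng.normal(0, sigma)), "flags": ""})
    return pd.DataFrame(rows), pd.DataFrame(meta)


def test_late_phase_constant_trajectory_no_stars():
    conc, meta = _late_phase_tables([5, 5, 5, 5, 5], sigma=0.0)
    out = late_phase_trajectories(conc, meta, ["acylcarnitine 18:2"])
    assert all(out.iloc[0][f"stars_{tp}"] == "" for tp in
               ("t1", "t2", "t3", "t4"))


def test_late_phase_v_shape_detected():
    conc, meta = _late_phase_tables([5.0, 4.0, 3.5, 2.5, 4.5])
    out = late_phase_trajectories(conc, meta, ["acylcarnitine 18:2"]).iloc[0]
    assert out["p_t3_vs_t0"] < 0.05
    assert out["direction_t3"] < 0
    assert out["stars_t3"] != ""


def test_late_phase_insufficient_subjects():
    conc, meta = _late_phase_tables([5, 4, 3, 2, 4], n=2)
    out = late_phase_trajectories(conc, meta, ["acylcarnitine 18:2"])
    assert out.iloc[0]["flag"] == "insufficient_n"


def test_control_comparison_empty_species_list():
    conc, meta = _late_phase_tables([5, 5, 5, 5, 5])
    out = control_comparison(conc, meta, [])
    assert out.empty


def test_control_comparison_detects_planted_elevation():
    rng = np.random.default_rng(8)
    rows, meta = [], []
    for i in range(80):
        sid = f"S{i}_t0"
        meta.append({"sample_id": sid, "sample_type": "study", "batch": 1,
                     "injection_order": i + 1, "subject_id": f"S{i}",
                     "timepoint": "t0"})
        rows.append({"sample_id": sid, "species": "LPC 17:1",
                     "lipid_class": "LPC",
                     "concentration": 15.0 * np.exp(rng.normal(0, 0.3)),
                     "flags": ""})
    for i in range(50):
        sid = f"C{i}_ctrl"
        meta.append({"sample_id": sid, "sample_type": "study", "batch": 1,
                     "injection_order": 100 + i, "subject_id": f"C{i}",
                     "timepoint": "ctrl"})
        rows.append({"sample_id": sid, "species": "LPC 17:1",
                     "lipid_class": "LPC",
                     "concentration": 10.0 * np.exp(rng.normal(0, 0.3)),
                     "flags": ""})
    out = control_comparison(pd.DataFrame(rows), pd.DataFrame(meta),
                             ["LPC 17:1"])
    row = out[out["species"] == "LPC 17:1"].iloc[0]
    assert row["log2_fc"] > 0 and row["p"] < 0.05


def test_marker_signs_recovered_end_to_end(seed_sweep):
    """The planted marker species (acylcarnitine 18:2 positive; TG 51:0,
    LPC 17:1, PI 34:1 negative) keep their signs in both the adjusted
    regression and the tertile fold change in >= 90% of 20 seeds."""
    hits = total = 0
    for run in seed_sweep["runs"]:
        for sp, rec in run["markers"].items():
            hits += int(np.sign(rec["b"]) == rec["planted_sign"])
            hits += int(np.sign(rec["fc"]) == rec["planted_sign"])
            total += 2
    assert total > 0
    assert hits / total >= 0.90


def test_acylcarnitine_tertile_elevation_significant(seed_sweep):
    """Planted top-tertile elevation of acylcarnitine 18:2 at 2 h: positive
    log2 fold change with p < 0.05 in >= 90% of seeds."""
    ok = n = 0
    for run in seed_sweep["runs"]:
        rec = run["markers"]["acylcarnitine 18:2"]
        ok += (rec["fc"] > 0) and (rec["fc_p"] < 0.05)
        n += 1
    assert ok / n >= 0.90


def test_subject_deltas_from_long_table():
    tn = pd.DataFrame({"subject_id": ["a", "a", "b", "b"],
                       "hours": [0, 12, 0, 12],
                       "tnt_ng_l": [100.0, 900.0, 200.0, 150.0]})
    d = subject_deltas(tn)
    assert d["a"] == 800.0 and d["b"] == 0.0
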