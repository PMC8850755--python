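import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidflux.nomenclature import parse_lipid_name
from lipidflux.panel import molecular_carbons
from lipidflux.quantitation import (C13_ABUNDANCE, NonPositiveResponseError,
                                    QuantitationError, ce_response_factor,
                                    correction_factor, deisotope,
                                    fa_qualifier_check, isotope_m2_fraction,
                                    quantify)
from lipidflux.synthetic import GroundTruth, StudyDesign, generate_study

from conftest import make_panel


# ---------------------------------------------------------------------------
# correction factors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,cf", [
    ("DG 15:0_18:1", 0.5),
    ("DG 16:0_16:0", 1.0),
    ("TG 16:0_18:1_18:2", 0.33),
    ("TG 16:0_16:0_18:1", 0.66),
    ("TG 17:0_17:0_17:0", 1.0),
    ("PC 34:2", 1.0),
    ("CE 18:1", 1.0),
])
def test_correction_factor_rules(name, cf):
    assert correction_factor(parse_lipid_name(name)) == cf


def test_correction_factor_requires_chains():
    with pytest.raises(QuantitationError, match="chain-resolved"):
        correction_factor(parse_lipid_name("TG 51:0"))


_chain = st.tuples(st.integers(10, 22), st.integers(0, 6))


@settings(max_examples=200, deadline=None)
@given(chains=st.one_of(st.tuples(_chain, _chain),
                        st.tuples(_chain, _chain, _chain)))
def test_correction_factor_exhaustive_outcomes(chains):
    """The CF is a pure function of chain multiplicity with 5 outcomes."""
    cls = "DG" if len(chains) == 2 else "TG"
    name = f"{cls} " + "_".join(f"{c}:{d}" for c, d in chains)
    cf = correction_factor(parse_lipid_name(name))
    n_distinct = len(set(chains))
    expected = {("DG", 1): 1.0, ("DG", 2): 0.5, ("TG", 1): 1.0,
                ("TG", 2): 0.66, ("TG", 3): 0.33}[(cls, n_distinct)]
    assert cf == expected


# ---------------------------------------------------------------------------
# CE response factors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("carbons,db,expected", [
    (20, 0, 0.13 * 20 - 0.71),    # saturated: 1.89
    (16, 1, 1.13 * 16 - 0.23),    # monounsaturated
    (20, 2, -0.07 * 20 + 1.54),   # polyunsaturated: 0.14
    (18, 4, -0.07 * 18 + 1.54),
])
def test_ce_response_lines(carbons, db, expected):
    assert ce_response_factor(carbons, db) == pytest.approx(expected, abs=1e-12)


def test_ce_response_nonpositive_raises():
    with pytest.raises(NonPositiveResponseError):
        ce_response_factor(22, 5)   # -0.07*22 + 1.54 = 0


# ---------------------------------------------------------------------------
# deisotoping
# ---------------------------------------------------------------------------

def _peak_table(panel, areas):
    rows = []
    for name, area in areas.items():
        rows.append({"sample_id": "A", "sample_type": "study", "batch": 1,
                     "injection_order": 1,
                     "transition_id": f"{name}|quantifier", "area": area})
    return pd.DataFrame(rows)


def test_deisotope_no_partner_unchanged():
    p = make_panel(["PC 34:1", "PC 36:4"])
    t = _peak_table(p, {"PC 34:1": 500.0, "PC 36:4": 800.0,
                        "PC 13:0_13:0": 1000.0})
    out = deisotope(t, p)
    got = out.set_index("transition_id")["area"]
    assert got["PC 34:1|quantifier"] == 500.0
    assert got["PC 36:4|quantifier"] == 800.0


def test_deisotope_printed_example():
    """PC 34:2 (1000) into PC 34:1 (100): corrected = 100 - p2(42)*1000."""
    p = make_panel(["PC 34:1", "PC 34:2"])
    t = _peak_table(p, {"PC 34:1": 100.0, "PC 34:2": 1000.0,
                        "PC 13:0_13:0": 1000.0})
    out = deisotope(t, p).set_index("transition_id")["area"]
    p2 = isotope_m2_fraction(42)  # 34 acyl + 8 backbone carbons
    assert out["PC 34:1|quantifier"] == pytest.approx(100.0 - p2 * 1000.0)
    assert out["PC 34:2|quantifier"] == 1000.0


def test_deisotope_clips_and_flags():
    p = make_panel(["PC 34:1", "PC 34:2"])
    t = _peak_table(p, {"PC 34:1": 50.0, "PC 34:2": 1000.0,
                        "PC 13:0_13:0": 1000.0})
    out = deisotope(t, p)
    row = out[out["transition_id"] == "PC 34:1|quantifier"].iloc[0]
    assert row["area"] == 0.0
    assert row["flags"] == "clipped"


def test_deisotope_matches_linear_solve_oracle():
    """Sequential recursion equals solving the full interference system."""
    names = [f"PC 34:{d}" for d in range(6)]
    p = make_panel(names)
    rng = np.random.default_rng(3)
    true = {n: float(a) for n, a in zip(names, rng.uniform(100, 5000, len(names)))}

    # independent forward model: M @ true = observed
    n = len(names)
    M = np.eye(n)
    p2 = isotope_m2_fraction(molecular_carbons(parse_lipid_name("PC 34:0")))
    for i in range(n - 1):
        M[i, i + 1] = p2     # species with d+1 leaks into species with d
    observed = M @ np.array([true[n_] for n_ in names])

    t = _peak_table(p, {**{n_: o for n_, o in zip(names, observed)},
                        "PC 13:0_13:0": 1000.0})
    got = deisotope(t, p).set_index("transition_id")["area"]
    solved = np.linalg.solve(M, observed)
    for n_, s in zip(names, solved):
        assert got[f"{n_}|quantifier"] == pytest.approx(s, abs=1e-6)
        assert got[f"{n_}|quantifier"] == pytest.approx(true[n_], rel=1e-9)


def test_m2_fraction_close_to_exact_binomial():
    """The linearized p2 approximates the exact binomial M+2/M+0 ratio.

    Exact ratio from the polynomial convolution ((1-a) + a z)^C is
    C(C,2) (a/(1-a))^2 — about 2% above the linearized form at natural 13C
    abundance; the model is documented as the linearized version.
    """
    a = C13_ABUNDANCE
    for C in (20, 42, 60):
        poly = np.polynomial.polynomial.polypow([1 - a, a], C)
        exact = poly[2] / poly[0]
        assert isotope_m2_fraction(C) == pytest.approx(exact, rel=0.03)


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

def test_quantify_ratio_arithmetic():
    p = make_panel(["PC 34:1"])
    t = _peak_table(p, {"PC 34:1": 2000.0, "PC 13:0_13:0": 1000.0})
    conc = quantify(t, p)
    assert conc.iloc[0]["concentration"] == pytest.approx(20.0)


def test_quantify_tg_divides_by_cf():
    p = make_panel(["TG 16:0_18:1_18:2"], istd=("TG 17:0_17:0_17:0", 10.0))
    t = _peak_table(p, {"TG 16:0_18:1_18:2": 2000.0,
                        "TG 17:0_17:0_17:0": 1000.0})
    conc = quantify(t, p)
    assert conc.iloc[0]["concentration"] == pytest.approx(20.0 / 0.33)
    conc_m = quantify(t, p, cf_convention="multiply")
    assert conc_m.iloc[0]["concentration"] == pytest.approx(20.0 * 0.33)


def test_quantify_missing_istd_flagged_not_dropped():
    p = make_panel(["PC 34:1"])
    t = _peak_table(p, {"PC 34:1": 2000.0, "PC 13:0_13:0": 0.0})
    conc = quantify(t, p)
    assert len(conc) == 1
    assert np.isnan(conc.iloc[0]["concentration"])
    assert conc.iloc[0]["flags"] == "istd_missing"


def test_quantify_scale_equivariance():
    """Multiplying every area in a sample by k leaves concentrations unchanged."""
    p = make_panel(["PC 34:1", "PC 36:2"])
    areas = {"PC 34:1": 1500.0, "PC 36:2": 300.0, "PC 13:0_13:0": 900.0}
    t1 = _peak_table(p, areas)
    t2 = _peak_table(p, {k: v * 7.3 for k, v in areas.items()})
    c1 = quantify(t1, p).set_index("species")["concentration"]
    c2 = quantify(t2, p).set_index("species")["concentration"]
    pd.testing.assert_series_equal(c1, c2)


def test_noise_free_pipeline_recovers_ground_truth(panel):
    """Drift-free, noise-free acquisition quantifies to exact ground truth."""
    truth = GroundTruth(drift_amplitude=0.0, batch_sigma=0.0,
                        measurement_sigma=0.0, high_noise_species=())
    study = generate_study(StudyDesign(n_stemi=5, n_control=3,
                                       n_late_subset=2, seed=9), truth, panel)
    conc = quantify(deisotope(study.peak_areas, panel), panel)
    truth_tab = study.true_concentrations.set_index(["sample_id", "species"])
    got = conc[conc["flags"] == ""].set_index(["sample_id", "species"])
    joined = got.join(truth_tab, rsuffix="_true", how="inner")
    rel = np.abs(joined["concentration"] - joined["concentration_true"]) \
        / joined["concentration_true"]
    assert len(joined) > 3000
    assert rel.max() < 1e-9


# ---------------------------------------------------------------------------
# FA qualifier check
# ---------------------------------------------------------------------------

def test_fa_qualifier_check_rules():
    assert fa_qualifier_check(1000.0, 400.0, reference_ratio=0.4)
    assert not fa_qualifier_check(1000.0, 0.0, reference_ratio=0.4)
    # interferent inflating only the quantifier 3x halves the ratio -> flag
    assert not fa_qualifier_check(3000.0, 400.0, reference_ratio=0.4)
    # within +/-50 percent of reference passes
    assert fa_qualifier_check(1000.0, 580.0, reference_ratio=0.4)
    assert not fa_qualifier_check(1000.0, 620.0, reference_ratio=0.4)
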