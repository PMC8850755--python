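import numpy as np
import pandas as pd
import pytest

from lipidflux.panel import IstdAssignment, MRMTransition, Panel, default_panel
from lipidflux.nomenclature import parse_lipid_name
from lipidflux.synthetic import GroundTruth, StudyDesign, generate_study


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def subset_panel(panel: Panel, classes) -> Panel:
    """A small panel restricted to the given classes (ISTDs kept)."""
    istd_names = {a.species.canonical_name for c, a in panel.istd_map.items()
                  if c in classes}
    keep = [t for t in panel.transitions
            if t.species.lipid_class in classes
            or t.species.canonical_name in istd_names]
    istd_map = {c: a for c, a in panel.istd_map.items()
                if c in classes or a.species.lipid_class in classes}
    return Panel(transitions=keep, istd_map=istd_map)


def make_panel(names, istd=("PC 13:0_13:0", 10.0)):
    """Tiny single-ISTD panel over arbitrary species names (same class)."""
    trans, classes = [], set()
    for n in list(names) + [istd[0]]:
        sp = parse_lipid_name(n)
        classes.add(sp.lipid_class)
        trans.append(MRMTransition(sp, 700.0, 184.0, "positive", "quantifier"))
    istd_sp = parse_lipid_name(istd[0])
    imap = {c: IstdAssignment(istd_sp, istd[1], "uM") for c in classes}
    return Panel(transitions=trans, istd_map=imap)


@pytest.fixture(scope="session")
def small_study(panel):
    """A compact but complete synthetic study used by several modules."""
    design = StudyDesign(n_stemi=12, n_control=8, n_late_subset=5, seed=11)
    return generate_study(design, GroundTruth(), panel), design


MARKERS = {  # planted delta-troponin associations, sign of the coefficient
    "acylcarnitine 18:2": +1,
    "TG 16:0_17:0_18:0": -1,
    "LPC 17:1": -1,
    "PI 34:1": -1,
}


@pytest.fixture(scope="session")
def seed_sweep(panel):
    """Twenty full pipeline runs (quantify + loess drift correction) at the
    default study design, one per seed, summarized for recovery checks.

    The deterministic loess normalizer is used here so that each of the 20
    replicates stays cheap; the SERRF path is exercised by ``default_run``.
    """
    from lipidflux.injury import (adjusted_regression, group_fold_change,
                                  subject_deltas, tertile_split,
                                  DEFAULT_COVARIATES)
    from lipidflux.qc import loess_normalize, qc_filter
    from lipidflux.quantitation import deisotope, quantify
    from lipidflux.temporal import log_transform

    truth = GroundTruth()
    results = []
    for seed in range(20):
        study = generate_study(StudyDesign(seed=seed), truth, panel)
        conc = quantify(deisotope(study.peak_areas, panel), panel)
        norm = loess_normalize(conc, study.samples)
        kept, _ = qc_filter(norm, study.samples)
        m = study.samples.drop_duplicates("sample_id").set_index("sample_id")
        kept = kept.assign(
            timepoint=kept["sample_id"].map(m["timepoint"]),
            subject_id=kept["sample_id"].map(m["subject_id"]))
        study_rows = kept[kept["timepoint"].isin(["t0", "t1", "t2"])]
        class_means = study_rows.groupby(["lipid_class", "timepoint"])[
            "concentration"].mean().unstack()

        deltas = subject_deltas(study.troponin)
        covs = study.clinical.set_index("subject_id").loc[
            deltas.index, list(DEFAULT_COVARIATES)]
        tert = tertile_split(deltas)

        markers = {}
        for sp, sign in MARKERS.items():
            at_t1 = study_rows[(study_rows["species"] == sp)
                               & (study_rows["timepoint"] == "t1")]
            wide = at_t1.set_index("subject_id")["concentration"]
            if wide.empty:
                continue
            logv = np.log(wide.where(wide > 0)).rename(sp)
            reg = adjusted_regression(deltas, logv, covs, species=sp,
                                      timepoint="t1")
            fc = group_fold_change(wide, tert["tertile_group"],
                                   group_a="top", group_b="lower", species=sp,
                                   grouping="tertile_top_vs_rest")
            markers[sp] = {"b": reg.b, "p": reg.p, "planted_sign": sign,
                           "fc": fc["log2_fc"], "fc_p": fc["p"]}
        results.append({"seed": seed, "class_means": class_means,
                        "markers": markers})
    return {"runs": results, "truth": truth}


@pytest.fixture(scope="session")
def default_run(panel, tmp_path_factory):
    """One full-pipeline run at the default study design, shared per session.

    SERRF forest size is reduced (100 trees; library default 500) to keep the
    session tractable; the drift model it must learn has low complexity.
    """
    from lipidflux.workflow import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(seed=2024, outdir=str(out), serrf_trees=100,
                         n_boot=500)
    manifest = run_pipeline(cfg)
    tables = {}
    for name in ("samples", "clinical", "troponin", "qc_metrics",
                 "concentrations_filtered", "anova_results",
                 "pairwise_results", "class_pairwise", "class_summary",
                 "regression_results", "group_comparisons",
                 "ground_truth_concentrations"):
        tables[name] = pd.read_csv(out / f"{name}.csv")
    return {"manifest": manifest, "outdir": out, "config": cfg, **tables}
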