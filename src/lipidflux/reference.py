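"""Accession-gated regression checks against the deposited study.

The headline numbers of the original cohort (species retained after QC,
fraction altered within 24 h, class-level percent differences) are
properties of the deposited raw dataset (MetaboLights accession MTBLS3839),
not of this package, and cannot be reproduced without downloading it.  This
module encodes them as optional regression targets: point
:func:`check_deposited_reproduction` at a local copy of the accession
(pre-mapped to the pipeline's CSV schemas) and it reruns the pipeline and
compares.  Without the download it refuses with a clear error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

from .workflow import PipelineConfig, load_accession, run_pipeline

#: Reference values reported for the deposited cohort (MTBLS3839).
DEPOSITED_REFERENCE: Dict[str, float] = {
    "species_retained": 291,
    "pct_species_altered_24h": 56.0,       # t2 vs t0, corrected p < 0.05
    "pct_diff_total_DG_t1_vs_t0": -29.92,
    "pct_diff_total_TG_t1_vs_t0": -24.28,
    "pct_diff_total_DG_t2_vs_t1": +64.06,
    "pct_diff_total_TG_t2_vs_t1": +58.62,
    "pct_diff_total_FA_t2_vs_t0": -74.5,
    "pct_diff_total_OxPL_t1_vs_t0": +29.87,
}


def check_deposited_reproduction(accession_dir, outdir, *,
                                 seed: int = 0) -> Dict[str, float]:
    """Rerun the pipeline on a local copy of the deposited study and return
    the recomputed headline quantities next to :data:`DEPOSITED_REFERENCE`.

    ``accession_dir`` must contain the accession tables exported to the
    pipeline's real-mode CSVs (``peak_areas.csv``, ``samples.csv``,
    ``clinical.csv``, ``troponin.csv``).  Raises ``FileNotFoundError`` when
    the accession has not been downloaded.
    """
    root = Path(accession_dir)
    if not root.exists():
        load_accession(root)  # raises with download instructions
    needed = ["peak_areas.csv", "samples.csv", "clinical.csv"]
    missing = [n for n in needed if not (root / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"accession tables {missing} not found under {root}; download "
            "MetaboLights MTBLS3839 and export its assay/sample tables to "
            "the real-mode CSV schemas first")

    cfg = PipelineConfig(
        seed=seed, outdir=str(outdir), mode="real",
        real_peak_areas=str(root / "peak_areas.csv"),
        real_samples=str(root / "samples.csv"),
        real_clinical=str(root / "clinical.csv"),
        real_troponin=str(root / "troponin.csv")
        if (root / "troponin.csv").exists() else None)
    manifest = run_pipeline(cfg)

    import pandas as pd
    out = Path(outdir)
    pw = pd.read_csv(out / "pairwise_results.csv")
    cp = pd.read_csv(out / "class_pairwise.csv").set_index(
        ["lipid_class", "a", "b"])
    t02 = pw[(pw["a"] == "t0") & (pw["b"] == "t2")]
    got = {
        "species_retained": manifest["counts"]["retained_species"],
        "pct_species_altered_24h": 100.0 * t02["significant"].mean(),
        "pct_diff_total_DG_t1_vs_t0": cp.loc[("DG", "t0", "t1"), "pct_diff"],
        "pct_diff_total_TG_t1_vs_t0": cp.loc[("TG", "t0", "t1"), "pct_diff"],
        "pct_diff_total_DG_t2_vs_t1": cp.loc[("DG", "t1", "t2"), "pct_diff"],
        "pct_diff_total_TG_t2_vs_t1": cp.loc[("TG", "t1", "t2"), "pct_diff"],
        "pct_diff_total_FA_t2_vs_t0": cp.loc[("FA", "t0", "t2"), "pct_diff"],
        "pct_diff_total_OxPL_t1_vs_t0": cp.loc[("OxPL", "t0", "t1"), "pct_diff"],
    }
    return got
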