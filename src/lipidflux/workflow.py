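"""End-to-end pipeline orchestration: config, stages, manifest, report.

One YAML config drives the run; every method-ambiguous choice (CF
convention, CoV threshold, Bonferroni family, log-ratio base) is a named
key.  Stages write plain CSV/JSON artifacts into the output directory and a
run manifest records the config hash, seed, row counts and file digests so
that identical config+seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import injury, qc, temporal
from .panel import default_panel, load_panel
from .quantitation import deisotope, quantify
from .synthetic import (GroundTruth, StudyDesign, generate_cohort,
                        generate_acquisition)

__all__ = ["PipelineConfig", "ValidationError", "run_pipeline", "write_report",
           "load_config", "load_real_inputs", "load_accession"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "normalize", "filter", "temporal",
          "injury", "report")

_FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Bad configuration or malformed input table."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "lipidflux_out"
    mode: str = "synthetic"                  # synthetic | real
    panel_path: Optional[str] = None
    design: Dict = field(default_factory=dict)
    truth: Dict = field(default_factory=dict)
    cf_convention: str = "divide"
    norm_method: str = "serrf"               # serrf | loess
    serrf_trees: int = 500
    serrf_k: int = 10
    cov_threshold: float = 20.0
    bonferroni_family: str = "per_species"
    log_ratio_base: float = 2.0
    n_boot: int = 2000
    real_peak_areas: Optional[str] = None
    real_samples: Optional[str] = None
    real_clinical: Optional[str] = None
    real_troponin: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValidationError(f"mode must be synthetic|real, got {self.mode!r}")
        if self.norm_method not in ("serrf", "loess"):
            raise ValidationError(f"unknown norm_method {self.norm_method!r}")
        if self.cf_convention not in ("divide", "multiply"):
            raise ValidationError(f"unknown cf_convention {self.cf_convention!r}")
        if self.bonferroni_family not in ("per_species", "study_wide"):
            raise ValidationError(
                f"unknown bonferroni_family {self.bonferroni_family!r}")
        if not (0 < self.cov_threshold <= 100) and self.cov_threshold != 0:
            raise ValidationError("cov_threshold must be in [0, 100]")
        if self.mode == "real":
            for key in ("real_peak_areas", "real_samples", "real_clinical"):
                if not getattr(self, key):
                    raise ValidationError(f"real mode requires {key}")

    def config_hash(self) -> str:
        # where outputs land does not affect what they contain
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# real-mode input
# ---------------------------------------------------------------------------

_PEAK_COLS = ["sample_id", "sample_type", "batch", "injection_order",
              "transition_id", "area"]
_CLIN_COLS = ["subject_id", "group", "age", "sex_male", "bmi", "smoker",
              "diabetes", "ischemic_time_min", "mace"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns {missing}")


def load_real_inputs(cfg: PipelineConfig):
    peak = pd.read_csv(cfg.real_peak_areas)
    _require_columns(peak, _PEAK_COLS, "peak areas table")
    samples = pd.read_csv(cfg.real_samples)
    _require_columns(samples, ["sample_id", "sample_type", "batch",
                               "injection_order"], "sample metadata")
    clinical = pd.read_csv(cfg.real_clinical)
    _require_columns(clinical, _CLIN_COLS, "clinical table")
    troponin = None
    if cfg.real_troponin:
        troponin = pd.read_csv(cfg.real_troponin)
        _require_columns(troponin, ["subject_id", "hours", "tnt_ng_l"],
                         "troponin table")
    return peak, samples, clinical, troponin


def load_accession(root) -> Dict[str, Path]:
    """Locate a locally downloaded MetaboLights MTBLS3839 study folder.

    The deposited raw study is not redistributable with this package; point
    ``root`` at a local copy to run the accession-gated regression checks.
    Raises ``FileNotFoundError`` with download instructions when absent.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(
            f"MetaboLights study folder not found at {root}. Download "
            "accession MTBLS3839 from https://www.ebi.ac.uk/metabolights/ "
            "and pass its local path to run the deposited-data checks.")
    hits = {p.name: p for p in root.glob("*.tsv")}
    if not hits:
        raise FileNotFoundError(
            f"no MetaboLights .tsv tables under {root}; expected the "
            "MTBLS3839 sample/assay tables")
    return hits


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config, *, seed: Optional[int] = None,
                 outdir: Optional[str] = None,
                 stages: Sequence[str] = STAGES) -> Dict:
    """Execute the pipeline and return the run manifest (also written to disk).

    ``config`` is a path to a YAML file or a :class:`PipelineConfig`.
    Any prefix of the stage list can be run; later invocations pick up the
    CSVs written earlier into the same output directory.
    """
    cfg = load_config(config) if not isinstance(config, PipelineConfig) \
        else replace(config)
    if seed is not None:
        cfg.seed = int(seed)
    if outdir is not None:
        cfg.outdir = str(outdir)
    cfg.validate()
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stages: {sorted(bad)}")

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(cfg.panel_path) if cfg.panel_path else default_panel()

    manifest: Dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "mode": cfg.mode, "stages": list(stages),
                      "files": {}, "counts": {}}

    def record(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_csv(df, path)
        manifest["files"][name] = _digest(path)
        manifest["counts"][name] = len(df)

    def read(name: str) -> pd.DataFrame:
        path = out / name
        if not path.exists():
            raise ValidationError(
                f"stage input {name} not found in {out}; run earlier stages first")
        return pd.read_csv(path)

    # ---- simulate ----------------------------------------------------------
    if "simulate" in stages:
        if cfg.mode == "synthetic":
            design = StudyDesign(**{**cfg.design, "seed": cfg.seed})
            truth_kwargs = dict(cfg.truth)
            truth = GroundTruth(**truth_kwargs)
            cohort = generate_cohort(design, truth, panel)
            peak, samples, true_long = generate_acquisition(
                design, truth, panel, cohort)
            record("peak_areas.csv", peak)
            record("samples.csv", samples)
            record("clinical.csv", cohort["clinical"])
            record("troponin.csv", cohort["troponin"])
            record("ground_truth_concentrations.csv", true_long)
            gt = {"design": asdict(design),
                  "timepoint_multipliers": truth.timepoint_multipliers,
                  "troponin_effects": truth.troponin_effects,
                  "group_effects": truth.group_effects}
            (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
            manifest["files"]["ground_truth.json"] = _digest(out / "ground_truth.json")
        else:
            peak, samples, clinical, troponin = load_real_inputs(cfg)
            record("peak_areas.csv", peak)
            record("samples.csv", samples)
            record("clinical.csv", clinical)
            if troponin is not None:
                record("troponin.csv", troponin)

    # ---- quantify ----------------------------------------------------------
    if "quantify" in stages:
        peak = read("peak_areas.csv")
        conc = quantify(deisotope(peak, panel), panel,
                        cf_convention=cfg.cf_convention)
        record("concentrations.csv", conc)

    # ---- normalize ---------------------------------------------------------
    if "normalize" in stages:
        conc = read("concentrations.csv")
        samples = read("samples.csv")
        if cfg.norm_method == "serrf":
            norm = qc.serrf_normalize(conc, samples, trees=cfg.serrf_trees,
                                      k_correlated=cfg.serrf_k, seed=cfg.seed)
        else:
            norm = qc.loess_normalize(conc, samples)
        record("concentrations_normalized.csv", norm)

    # ---- filter ------------------------------------------------------------
    if "filter" in stages:
        norm = read("concentrations_normalized.csv")
        samples = read("samples.csv")
        filtered, metrics = qc.qc_filter(norm, samples,
                                         threshold_pct=cfg.cov_threshold)
        record("concentrations_filtered.csv", filtered)
        record("qc_metrics.csv", metrics)
        manifest["counts"]["retained_species"] = int(metrics["retained"].sum())
        try:
            pca = qc.pca_qc(norm, samples)
            qc_report = {"retained": int(metrics["retained"].sum()),
                         "dropped": metrics.loc[~metrics["retained"]]
                         .groupby("reason").size().to_dict(),
                         "pca_dispersion": pca["types"]}
        except qc.QCError as e:
            qc_report = {"retained": int(metrics["retained"].sum()),
                         "pca_error": str(e)}
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=1))
        manifest["files"]["qc_report.json"] = _digest(out / "qc_report.json")

    # ---- temporal stats ----------------------------------------------------
    if "temporal" in stages:
        conc = read("concentrations_filtered.csv")
        samples = read("samples.csv")
        res = temporal.run_temporal_stats(
            conc, samples, bonferroni_family=cfg.bonferroni_family,
            n_boot=cfg.n_boot, seed=cfg.seed)
        record("anova_results.csv", res["anova"])
        record("pairwise_results.csv", res["pairwise"])
        record("class_summary.csv", res["class_summary"])
        record("class_pairwise.csv", res["class_pairwise"])
        # within-class composition shifts for the major structural classes
        ratios = []
        for cls in ("PC", "PE", "PI", "SM"):
            try:
                r = temporal.within_class_log_ratio(
                    conc[conc["sample_id"].isin(
                        samples.loc[samples["sample_type"] == "study",
                                    "sample_id"])],
                    samples, cls, log_base=cfg.log_ratio_base)
                r = r.reset_index().melt(id_vars="species",
                                         var_name="timepoint",
                                         value_name="log_ratio")
                r["lipid_class"] = cls
                ratios.append(r)
            except ValueError:
                continue
        if ratios:
            record("fig_logratios.csv", pd.concat(ratios, ignore_index=True))
        # clustered heatmap ordering on timepoint mean profiles
        m = samples.drop_duplicates("sample_id").set_index("sample_id")
        study = conc[conc["sample_id"].map(m["sample_type"]) == "study"].copy()
        study["timepoint"] = study["sample_id"].map(m["timepoint"])
        prof = study.pivot_table(index="species", columns="timepoint",
                                 values="concentration", aggfunc="mean")
        try:
            hm = temporal.cluster_heatmap_data(prof)
            (out / "heatmap_order.json").write_text(json.dumps(
                {"row_order": list(hm["row_order"]),
                 "linkage": np.asarray(hm["linkage"]).tolist()}, indent=1))
            manifest["files"]["heatmap_order.json"] = _digest(
                out / "heatmap_order.json")
        except ValueError as e:
            log.warning("heatmap clustering skipped: %s", e)

    # ---- injury stats ------------------------------------------------------
    if "injury" in stages:
        conc = read("concentrations_filtered.csv")
        samples = read("samples.csv")
        clinical = read("clinical.csv")
        troponin = read("troponin.csv")
        res = injury.run_injury_stats(
            conc, samples, clinical, troponin,
            late_species=sorted(
                conc.loc[conc["lipid_class"].isin(
                    ["acylcarnitine", "LPC", "TG"]), "species"].unique())[:12])
        record("regression_results.csv", res["regression"])
        record("group_comparisons.csv", res["comparisons"])
        if res["late_phase"] is not None:
            record("late_phase.csv", res["late_phase"])
        record("delta_troponin.csv",
               res["deltas"].reset_index(names="subject_id"))

    # ---- report ------------------------------------------------------------
    if "report" in stages:
        results = {}
        for name in ("anova_results.csv", "pairwise_results.csv",
                     "class_pairwise.csv", "regression_results.csv",
                     "group_comparisons.csv"):
            if (out / name).exists():
                results[name] = pd.read_csv(out / name)
        report_files = write_report(manifest, results, out)
        for f in report_files:
            manifest["files"][f.name] = _digest(f)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

_REPORT_SCHEMAS = {
    "pairwise_results.csv": ["species", "a", "b", "p_corrected", "pct_diff"],
    "class_pairwise.csv": ["lipid_class", "a", "b", "p_corrected", "pct_diff"],
    "regression_results.csv": ["species", "timepoint", "b", "p", "significant"],
    "group_comparisons.csv": ["species", "grouping", "log2_fc", "p"],
}


def write_report(manifest: Dict, results: Dict[str, pd.DataFrame],
                 outdir) -> List[Path]:
    """Render a Markdown + JSON summary of a run; validates table schemas."""
    out = Path(outdir)
    for name, df in results.items():
        schema = _REPORT_SCHEMAS.get(name)
        if schema:
            missing = [c for c in schema if c not in df.columns]
            if missing:
                raise ValidationError(
                    f"results table {name} missing column(s) {missing}")

    lines = ["# lipidflux run report", "",
             f"- config hash: `{manifest.get('config_hash', 'n/a')}`",
             f"- seed: {manifest.get('seed', 'n/a')}", ""]
    summary: Dict = {"seed": manifest.get("seed")}

    pw = results.get("pairwise_results.csv")
    if pw is not None and len(pw):
        frac = {}
        for (a, b), g in pw.groupby(["a", "b"]):
            frac[f"{a}_vs_{b}"] = round(float(g["significant"].mean()), 4)
        summary["fraction_significant_species"] = frac
        lines.append("## Temporal changes")
        for pair, f in frac.items():
            lines.append(f"- {pair}: {100*f:.1f}% of species significant "
                         "(corrected p < 0.05)")
        lines.append("")

    cp = results.get("class_pairwise.csv")
    if cp is not None and len(cp):
        lines.append("## Class-total percent differences (significant only)")
        sig = cp[cp["significant"]] if "significant" in cp.columns else cp
        if len(sig):
            for _, r in sig.iterrows():
                lines.append(f"- {r['lipid_class']} {r['a']}→{r['b']}: "
                             f"{r['pct_diff']:+.2f}% (corrected p = "
                             f"{r['p_corrected']:.2g})")
        else:
            lines.append("- no significant lipid classes")
        lines.append("")

    reg = results.get("regression_results.csv")
    if reg is not None:
        sig = reg[reg["significant"] == True]  # noqa: E712
        names = sorted(sig["species"].unique()) if len(sig) else []
        summary["injury_associated_species"] = names
        lines.append("## Injury-associated lipids (delta cTnT regression)")
        if names:
            for sp in names:
                rows = sig[sig["species"] == sp]
                tps = ", ".join(f"{r['timepoint']} (B={r['b']:+.0f})"
                                for _, r in rows.iterrows())
                lines.append(f"- {sp}: {tps}")
        else:
            lines.append("- no significant species")
        lines.append("")

    if not results:
        lines.append("_no results tables present: no significant species_")

    md = out / "report.md"
    md.write_text("\n".join(lines))
    js = out / "report.json"
    js.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return [md, js]
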