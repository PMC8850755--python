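"""Synthetic STEMI reperfusion lipidomics study generator.

Emulates the full acquisition of a targeted plasma-lipidomics study of
myocardial reperfusion: an 80-patient STEMI cohort sampled pre-PCI (t0),
2 h (t1) and 24 h (t2) post-PCI, a 30-patient late-phase subset adding 48 h
(t3) and 30 d (t4), and 50 matched controls; batches of 60 study samples
interleaved with 20 pooled-plasma QCs (PQC), 6 matrix-free technical QCs
(TQC), 4 reference-plasma (SRM) injections and 12 blanks; smooth
injection-order drift and batch offsets; M+2 isotope interference; and
planted biology — class-level temporal fold changes (neutral lipids dip at
2 h then overshoot at 24 h, free fatty acids collapse by 24 h, oxidized
phospholipids rise acutely) and per-species associations with the troponin
rise (delta cTnT) that downstream statistics should recover.

Everything is driven by one seed through named sub-streams, so each stage
can be regenerated independently and a fixed seed gives bit-identical tables.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .panel import Panel, default_panel
from .quantitation import _interference_pairs, _species_factors

__all__ = ["StudyDesign", "GroundTruth", "SyntheticStudy",
           "generate_cohort", "generate_acquisition", "generate_study",
           "TIMEPOINTS", "LATE_TIMEPOINTS"]

TIMEPOINTS = ("t0", "t1", "t2")          # pre-PCI, 2 h, 24 h post-PCI
LATE_TIMEPOINTS = ("t3", "t4")           # 48 h, 30 d post-PCI


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG of the study seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes, sampling schedule and per-batch acquisition layout."""

    n_stemi: int = 80
    n_control: int = 50
    n_late_subset: int = 30
    batch_study: int = 60
    batch_pqc: int = 20
    batch_tqc: int = 6
    batch_srm: int = 4
    batch_blank: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_late_subset > self.n_stemi:
            raise ValueError("n_late_subset must be <= n_stemi")
        for f in ("n_stemi", "n_control", "batch_study", "batch_pqc",
                  "batch_tqc", "batch_srm", "batch_blank"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def injections_per_batch(self) -> int:
        return (self.batch_study + self.batch_pqc + self.batch_tqc
                + self.batch_srm + self.batch_blank)

    @property
    def n_study_samples(self) -> int:
        return (self.n_stemi * len(TIMEPOINTS)
                + self.n_late_subset * len(LATE_TIMEPOINTS) + self.n_control)


#: Plasma class-total abundances (uM); ordering encodes the observed rank:
#: top-5 CE > PC > PC(O) > LPC > SM, bottom-5 (ascending) acylcarnitine,
#: Hex3Cer, LPC(O), GM3, PE(P).
DEFAULT_CLASS_ABUNDANCE: Dict[str, float] = {
    "CE": 3000.0, "PC": 2200.0, "PC(O)": 900.0, "LPC": 700.0, "SM": 550.0,
    "TG": 450.0, "PE": 300.0, "FA": 260.0, "DG": 200.0, "Cer": 90.0,
    "PI": 120.0, "PE(O)": 100.0, "PS": 60.0, "HexCer": 40.0, "PG": 25.0,
    "LPE": 20.0, "dhCer": 15.0, "Hex2Cer": 12.0, "PC(P)": 10.0, "OxPL": 8.0,
    "PE(P)": 5.0, "GM3": 4.0, "LPC(O)": 3.0, "Hex3Cer": 2.0,
    "acylcarnitine": 1.5,
}

#: Temporal fold multipliers relative to t0, per class (species overrides via
#: GroundTruth.timepoint_multipliers with a species name as key).
DEFAULT_TIMEPOINT_MULTIPLIERS: Dict[str, Dict[str, float]] = {
    # neutral lipids: dip at 2 h, overshoot by 24 h (t2 = t1 * 1.64 / 1.59)
    "DG": {"t1": 0.70, "t2": 1.148, "t3": 0.90, "t4": 1.00},
    "TG": {"t1": 0.76, "t2": 1.208, "t3": 0.85, "t4": 0.95},
    # free fatty acids collapse over the first 24 h
    "FA": {"t1": 0.60, "t2": 0.26, "t3": 0.45, "t4": 0.85},
    # oxidized phospholipids rise acutely after reperfusion
    "OxPL": {"t1": 1.30, "t2": 1.00, "t3": 1.00, "t4": 1.00},
    # acylcarnitines decline with a nadir at 48 h
    "acylcarnitine": {"t1": 0.80, "t2": 0.70, "t3": 0.55, "t4": 0.90},
    "LPC": {"t1": 0.85, "t2": 0.80, "t3": 0.70, "t4": 0.95},
    "PC": {"t1": 0.85, "t2": 0.85, "t3": 0.90, "t4": 1.00},
    "PC(O)": {"t1": 0.85, "t2": 0.85, "t3": 0.90, "t4": 1.00},
    "PE": {"t1": 0.80, "t2": 0.85, "t3": 0.90, "t4": 1.00},
    "PE(O)": {"t1": 0.80, "t2": 0.85, "t3": 0.90, "t4": 1.00},
    "PI": {"t1": 0.85, "t2": 0.85, "t3": 0.90, "t4": 1.00},
    "LPE": {"t1": 0.85, "t2": 0.80, "t3": 0.90, "t4": 1.00},
    "CE": {"t1": 0.90, "t2": 0.85, "t3": 0.95, "t4": 1.00},
    "SM": {"t1": 0.90, "t2": 0.85, "t3": 0.95, "t4": 1.00},
    "Cer": {"t1": 0.90, "t2": 1.15, "t3": 1.05, "t4": 1.00},
    # remaining classes unchanged (multiplier 1.0)
}

#: Regression coefficient of delta cTnT (ng/L) per natural-log-unit of the
#: subject's latent species level; the acylcarnitine 18:2 association is
#: positive, the TG/LPC/PI markers negative.
DEFAULT_TROPONIN_EFFECTS: Dict[str, float] = {
    "acylcarnitine 18:2": 2000.0,
    "TG 16:0_17:0_18:0": -1000.0,   # sum composition TG 51:0
    "LPC 17:1": -900.0,
    "PI 34:1": -600.0,
}

#: STEMI-vs-control fold at presentation (class keys and species overrides).
DEFAULT_GROUP_EFFECTS: Dict[str, float] = {
    "acylcarnitine": 1.6, "LPC": 1.5,
    "acylcarnitine 18:2": 1.3, "LPC 17:1": 1.25,
}

#: Species planted to fail QC in the default study.
DEFAULT_HIGH_NOISE = ["PC 40:8", "PE 42:8", "PS 42:7", "PS 42:8", "SM 41:2",
                      "Cer 26:1", "HexCer 26:1", "TG 18:2_18:2_22:4",
                      "DG 18:1_22:6", "LPC(O-22:0)"]
DEFAULT_BLANK_CONTAMINANTS = ["PG 32:0", "Hex2Cer 26:0", "dhCer 26:0",
                              "GM3 26:0"]


@dataclass(frozen=True)
class GroundTruth:
    """Planted biology plus acquisition nuisance parameters."""

    class_abundance: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ABUNDANCE))
    timepoint_multipliers: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_TIMEPOINT_MULTIPLIERS.items()})
    troponin_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TROPONIN_EFFECTS))
    group_effects: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))

    subject_sigma: float = 0.294          # between-subject lognormal sd (~CV 30%)
    within_sigma: float = 0.15            # within-subject biological sd
    drift_amplitude: float = 0.35         # mean relative drift over a batch
    batch_sigma: float = 0.15             # lognormal sd of batch offsets
    measurement_sigma: float = 0.08       # injection-level multiplicative noise
    high_noise_sigma: float = 0.45
    high_noise_species: Tuple[str, ...] = tuple(DEFAULT_HIGH_NOISE)
    blank_contaminants: Tuple[str, ...] = tuple(DEFAULT_BLANK_CONTAMINANTS)
    carryover: float = 0.01               # blank analyte level vs study median

    troponin_baseline_median: float = 150.0   # ng/L
    troponin_baseline_sigma: float = 0.6
    delta_intercept: float = 2500.0           # ng/L
    delta_noise_sd: float = 500.0
    ischemic_time_effect: float = 2.0         # ng/L per minute above median
    area_scale: float = 1.0e6                 # nominal ISTD peak area

    def multiplier(self, species_name: str, lipid_class: str, tp: str) -> float:
        if tp == "t0" or tp == "ctrl":
            base = 1.0
        else:
            table = self.timepoint_multipliers
            if species_name in table:
                base = table[species_name].get(tp, 1.0)
            else:
                base = table.get(lipid_class, {}).get(tp, 1.0)
        return base

    def group_fold(self, species_name: str, lipid_class: str) -> float:
        return (self.group_effects.get(lipid_class, 1.0)
                * self.group_effects.get(species_name, 1.0))

    def validate(self) -> None:
        for k, v in self.class_abundance.items():
            if v <= 0:
                raise ValueError(f"class abundance for {k} must be > 0")
        for key, table in self.timepoint_multipliers.items():
            for tp, m in table.items():
                if m <= 0:
                    raise ValueError(f"multiplier {key}/{tp} must be > 0")


@dataclass
class SyntheticStudy:
    """Bundle of every table a synthetic run produces."""

    design: StudyDesign
    peak_areas: pd.DataFrame          # long per-injection transition areas
    samples: pd.DataFrame             # injection metadata
    clinical: pd.DataFrame            # per-subject covariates + MACE
    troponin: pd.DataFrame            # long serial troponin (STEMI only)
    true_concentrations: pd.DataFrame  # study-sample ground-truth conc (long)
    base_concentrations: pd.Series    # per-species t0 STEMI population level


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

_TROPONIN_HOURS = np.array([0.0, 6.0, 12.0, 24.0, 48.0, 72.0])
_TROPONIN_SHAPE = np.array([0.0, 0.55, 0.90, 1.00, 0.70, 0.45])


def generate_cohort(design: StudyDesign, truth: GroundTruth, panel: Panel
                    ) -> Dict[str, object]:
    """Simulate subjects: covariates, latent lipid states, serial troponin.

    The troponin rise is built so the planted species associations hold by
    construction: ``delta = intercept + sum_i effect_i * latent_i +
    ischemic-time term + noise`` with ``latent_i`` the subject's lognormal
    deviation for species i (shared across timepoints).  The peak of the
    serial troponin equals baseline + delta exactly.
    """
    truth.validate()
    species = panel.analyte_species
    names = [s.canonical_name for s in species]

    rng_cov = _stream(design.seed, "covariates")
    rng_lat = _stream(design.seed, "latent")
    rng_tn = _stream(design.seed, "troponin")

    n_s, n_c = design.n_stemi, design.n_control
    subjects = [f"S{i+1:03d}" for i in range(n_s)] + \
               [f"C{i+1:03d}" for i in range(n_c)]
    group = ["STEMI"] * n_s + ["control"] * n_c

    age = np.concatenate([
        np.clip(rng_cov.normal(63.7, 12.2, n_s), 30, 95),
        np.clip(rng_cov.normal(60.9, 10.7, n_c), 30, 95)])
    sex_male = np.concatenate([
        (rng_cov.random(n_s) < 0.675), (rng_cov.random(n_c) < 0.62)])
    bmi = np.clip(np.exp(rng_cov.normal(np.log(28.0), 0.15, n_s + n_c)), 17, 55)
    smoker = np.concatenate([
        (rng_cov.random(n_s) < 0.275), (rng_cov.random(n_c) < 0.12)])
    diabetes = np.concatenate([
        (rng_cov.random(n_s) < 0.20), (rng_cov.random(n_c) < 0.14)])
    ischemic = np.concatenate([
        np.clip(np.exp(rng_cov.normal(np.log(150.0), 0.55, n_s)), 20, 1000),
        np.full(n_c, np.nan)])

    latent = pd.DataFrame(
        rng_lat.normal(0.0, truth.subject_sigma, size=(n_s + n_c, len(names))),
        index=subjects, columns=names)

    effects = np.array([truth.troponin_effects.get(n, 0.0) for n in names])
    lat_term = latent.iloc[:n_s].to_numpy() @ effects
    isch_term = truth.ischemic_time_effect * (ischemic[:n_s] - 150.0)
    noise = rng_tn.normal(0.0, truth.delta_noise_sd, n_s)
    delta = np.maximum(truth.delta_intercept + lat_term + isch_term + noise, 50.0)

    baseline = np.exp(rng_tn.normal(np.log(truth.troponin_baseline_median),
                                    truth.troponin_baseline_sigma, n_s))
    mace_p = 0.5 / (1.0 + np.exp(-(delta - 3000.0) / 800.0))
    mace = rng_tn.random(n_s) < mace_p

    clinical = pd.DataFrame({
        "subject_id": subjects, "group": group, "age": np.round(age, 1),
        "sex_male": sex_male.astype(int), "bmi": np.round(bmi, 2),
        "smoker": smoker.astype(int), "diabetes": diabetes.astype(int),
        "ischemic_time_min": np.round(ischemic, 1),
        "mace": np.concatenate([mace, np.zeros(n_c, bool)]).astype(int),
    })

    tn_rows = []
    for i, sid in enumerate(subjects[:n_s]):
        series = baseline[i] + delta[i] * _TROPONIN_SHAPE
        for h, v in zip(_TROPONIN_HOURS, series):
            tn_rows.append((sid, h, round(float(v), 2)))
    troponin = pd.DataFrame(tn_rows, columns=["subject_id", "hours", "tnt_ng_l"])

    return {"clinical": clinical, "troponin": troponin, "latent": latent,
            "delta_ctnt": pd.Series(delta, index=subjects[:n_s])}


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------

def _batch_layout(n_study: int, design: StudyDesign) -> List[str]:
    """Injection-type sequence for one batch: leading blanks and PQC block,
    study samples in blocks of ~10 with interleaved PQC/TQC, SRM near the
    end, trailing blanks.  Defaults give a 10:1 study:PQC interleave."""
    lead_blanks = min(design.batch_blank // 2, design.batch_blank)
    trail_blanks = design.batch_blank - lead_blanks
    lead_pqc = min(10, design.batch_pqc)
    inter_pqc = min(design.batch_tqc, design.batch_pqc - lead_pqc)
    layout: List[str] = ["blank"] * lead_blanks + ["pqc"] * lead_pqc
    n_blocks = max(inter_pqc, 1)
    block = max(1, int(np.ceil(n_study / n_blocks))) if n_study else 1
    placed = 0
    for b in range(n_blocks):
        take = min(block, n_study - placed)
        # the interleaved PQC sits mid-block so the 10:1 study:PQC cadence
        # holds strictly inside the study-sample span of the run
        first, second = take - take // 2, take // 2
        layout += ["study"] * first
        placed += take
        if b < inter_pqc and take:
            layout.append("pqc")
        layout += ["study"] * second
        if b < design.batch_tqc:
            layout.append("tqc")
    layout += ["study"] * (n_study - placed)
    layout += ["srm"] * design.batch_srm
    layout += ["pqc"] * (design.batch_pqc - lead_pqc - inter_pqc)
    layout += ["blank"] * trail_blanks
    return layout


def generate_acquisition(design: StudyDesign, truth: GroundTruth, panel: Panel,
                         cohort: Optional[Dict[str, object]] = None
                         ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit the raw MRM acquisition for the whole study.

    Returns ``(peak_areas, samples, true_concentrations)``: a long
    per-injection transition table, the injection metadata, and the planted
    study-sample concentrations the pipeline should recover.
    """
    if cohort is None:
        cohort = generate_cohort(design, truth, panel)
    latent: pd.DataFrame = cohort["latent"]

    analytes = panel.analyte_species
    names = [s.canonical_name for s in analytes]
    classes = np.array([s.lipid_class for s in analytes])

    rng_base = _stream(design.seed, "base_conc")
    rng_acq = _stream(design.seed, "acquisition")
    rng_order = _stream(design.seed, "runorder")

    # per-species population level: class totals split by lognormal weights
    weights = np.exp(rng_base.normal(0.0, 1.0, len(names)))
    base = np.empty(len(names))
    for cls in set(classes):
        m = classes == cls
        w = weights[m] / weights[m].sum()
        base[m] = truth.class_abundance.get(cls, 10.0) * w
    base_conc = pd.Series(base, index=names)

    # ----- study-sample concentrations ------------------------------------
    stemi = [s for s in latent.index if s.startswith("S")][: design.n_stemi]
    controls = [s for s in latent.index if s.startswith("C")][: design.n_control]
    sample_defs: List[Tuple[str, str, str]] = []   # (sample_id, subject, tp)
    for sid in stemi:
        for tp in TIMEPOINTS:
            sample_defs.append((f"{sid}_{tp}", sid, tp))
    for sid in stemi[: design.n_late_subset]:
        for tp in LATE_TIMEPOINTS:
            sample_defs.append((f"{sid}_{tp}", sid, tp))
    for sid in controls:
        sample_defs.append((f"{sid}_ctrl", sid, "ctrl"))

    mult = np.ones((len(sample_defs), len(names)))
    tps = [tp for _, _, tp in sample_defs]
    group_fold = np.array([truth.group_fold(n, c) for n, c in zip(names, classes)])
    for j, (n, c) in enumerate(zip(names, classes)):
        per_tp = {tp: truth.multiplier(n, c, tp)
                  for tp in set(tps)}
        mult[:, j] = [per_tp[tp] for tp in tps]
    subj_dev = latent.loc[[s for _, s, _ in sample_defs]].to_numpy()
    is_ctrl = np.array([tp == "ctrl" for tp in tps])
    within = rng_acq.normal(0.0, truth.within_sigma, mult.shape)
    conc = base[None, :] * mult * np.exp(subj_dev + within)
    conc[is_ctrl] /= group_fold[None, :]

    true_conc = pd.DataFrame(conc, columns=names,
                             index=[sid for sid, _, _ in sample_defs])

    pqc_conc = conc.mean(axis=0)
    srm_conc = base * 0.9

    # ----- batches and run order ------------------------------------------
    order = rng_order.permutation(len(sample_defs))
    n_batches = max(1, int(np.ceil(len(sample_defs) / max(design.batch_study, 1))))

    inj_rows = []      # (sample_id, sample_type, batch, order, conc_row_idx)
    for b in range(n_batches):
        chunk = order[b * design.batch_study:(b + 1) * design.batch_study]
        layout = _batch_layout(len(chunk), design)
        counters = {"pqc": 0, "tqc": 0, "srm": 0, "blank": 0}
        it = iter(chunk)
        for pos, typ in enumerate(layout, start=1):
            if typ == "study":
                idx = next(it)
                inj_rows.append((sample_defs[idx][0], "study", b + 1, pos, idx))
            else:
                counters[typ] += 1
                sid = f"{typ.upper()}_B{b+1}_{counters[typ]:02d}"
                inj_rows.append((sid, typ, b + 1, pos, -1))

    samples = pd.DataFrame(inj_rows, columns=[
        "sample_id", "sample_type", "batch", "injection_order", "_idx"])
    subj_map = {sid: subj for sid, subj, _ in sample_defs}
    tp_map = {sid: tp for sid, _, tp in sample_defs}
    samples["subject_id"] = samples["sample_id"].map(subj_map).fillna("")
    samples["timepoint"] = samples["sample_id"].map(tp_map).fillna("")

    # ----- expected concentrations per injection --------------------------
    n_inj = len(samples)
    inj_conc = np.zeros((n_inj, len(names)))
    styp = samples["sample_type"].to_numpy()
    idxs = samples["_idx"].to_numpy()
    inj_conc[styp == "study"] = conc[idxs[styp == "study"]]
    inj_conc[styp == "pqc"] = pqc_conc
    inj_conc[styp == "srm"] = srm_conc
    # tqc (matrix-free) and blanks carry no analytes; blank carryover added
    # at the area stage below

    # ----- instrument model ------------------------------------------------
    cf_rf = []
    for s in analytes:
        cf, rf = _species_factors(s)
        cf_rf.append(cf * (rf if rf is not None else 0.1))  # physical floor
    cf_rf = np.array(cf_rf)
    istd_conc = np.array([panel.istd_for(c).concentration for c in classes])

    istd_species = []
    seen = set()
    for cls in dict.fromkeys(classes):
        a = panel.istd_for(cls)
        if a.species.canonical_name not in seen:
            seen.add(a.species.canonical_name)
            istd_species.append(a.species)
    istd_names = [s.canonical_name for s in istd_species]
    istd_spiked = np.array([panel.istd_for(s.lipid_class).concentration
                            for s in istd_species])

    all_species = analytes + istd_species
    all_names = names + istd_names
    n_sp = len(all_species)

    # expected areas: analyte = conc/istd_conc * CF*RF * scale; ISTD = scale
    expected = np.zeros((n_inj, n_sp))
    expected[:, :len(names)] = inj_conc / istd_conc[None, :] * cf_rf[None, :] \
        * truth.area_scale
    expected[:, len(names):] = truth.area_scale

    # blanks/tqc: analyte carryover relative to the median study area
    study_median = np.median(expected[styp == "study"][:, :len(names)], axis=0) \
        if (styp == "study").any() else np.zeros(len(names))
    carry = truth.carryover * study_median
    for t in ("blank", "tqc"):
        expected[styp == t, :len(names)] = carry[None, :]
    contam = np.isin(np.array(all_names[:len(names)]),
                     np.array(truth.blank_contaminants))
    if contam.any():
        expected[np.ix_(styp == "blank", np.where(contam)[0])] = \
            3.0 * study_median[contam][None, :]

    # drift: smooth logistic over injection order, class-correlated amplitudes
    batches = samples["batch"].to_numpy()
    orders = samples["injection_order"].to_numpy().astype(float)
    all_classes = np.array([s.lipid_class for s in all_species])
    drift = np.ones((n_inj, n_sp))
    batch_mult = np.ones((n_inj, n_sp))
    if truth.drift_amplitude > 0 or truth.batch_sigma > 0:
        for b in np.unique(batches):
            mask = batches == b
            per_batch = orders[mask]
            span = max(per_batch.max() - per_batch.min(), 1.0)
            z = (per_batch - per_batch.mean()) / (span / 8.0)
            sig = 1.0 / (1.0 + np.exp(-z)) - 0.5
            cls_amp = {c: rng_acq.normal(truth.drift_amplitude, 0.10)
                       for c in dict.fromkeys(all_classes)}
            amp = np.array([cls_amp[c] for c in all_classes]) \
                + rng_acq.normal(0.0, 0.05, n_sp)
            drift[mask] = 1.0 + sig[:, None] * amp[None, :]
            cls_off = {c: rng_acq.normal(0.0, truth.batch_sigma)
                       for c in dict.fromkeys(all_classes)}
            off = np.array([cls_off[c] for c in all_classes]) \
                + rng_acq.normal(0.0, 0.05, n_sp)
            batch_mult[mask] = np.exp(off)[None, :]
    drift = np.clip(drift, 0.05, None)

    sigma = np.full(n_sp, truth.measurement_sigma)
    hn = np.isin(np.array(all_names), np.array(truth.high_noise_species))
    sigma[hn] = truth.high_noise_sigma
    noise = np.exp(rng_acq.normal(0.0, 1.0, (n_inj, n_sp)) * sigma[None, :]) \
        if truth.measurement_sigma > 0 or hn.any() else np.ones((n_inj, n_sp))
    if truth.measurement_sigma == 0:
        noise[:, ~hn] = 1.0

    mono = expected * drift * batch_mult * noise

    # M+2 isotope interference between double-bond neighbours
    observed = mono.copy()
    col = {n: i for i, n in enumerate(all_names)}
    pairs = _interference_pairs(panel)
    for recv, src, p2 in pairs:
        rn, sn = recv.split("|")[0], src.split("|")[0]
        if rn in col and sn in col:
            observed[:, col[rn]] += p2 * mono[:, col[sn]]

    # ----- long table -------------------------------------------------------
    sample_ids = samples["sample_id"].to_numpy()
    frames = [pd.DataFrame({
        "sample_id": np.repeat(sample_ids, n_sp),
        "transition_id": np.tile([f"{n}|quantifier" for n in all_names], n_inj),
        "area": observed.ravel(),
    })]

    # FA qualifier transitions (fixed reference ratio 0.4, small extra noise)
    fa_cols = [i for i, s in enumerate(all_species) if s.lipid_class == "FA"]
    if fa_cols:
        qual = observed[:, fa_cols] * 0.4 * np.exp(
            rng_acq.normal(0.0, 0.05, (n_inj, len(fa_cols))))
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, len(fa_cols)),
            "transition_id": np.tile(
                [f"{all_names[i]}|qualifier" for i in fa_cols], n_inj),
            "area": qual.ravel(),
        }))

    # explicit M+2 monitor rows for the most abundant species (top decile)
    top = np.argsort(base)[-max(len(names) // 10, 1):]
    from .panel import molecular_carbons
    from .quantitation import isotope_m2_fraction
    m2 = np.array([isotope_m2_fraction(molecular_carbons(analytes[i]))
                   for i in top])
    frames.append(pd.DataFrame({
        "sample_id": np.repeat(sample_ids, len(top)),
        "transition_id": np.tile(
            [f"{names[i]}|isotope_m2" for i in top], n_inj),
        "area": (mono[:, top] * m2[None, :]).ravel(),
    }))

    peak = pd.concat(frames, ignore_index=True)
    meta = samples.drop(columns="_idx")
    peak = peak.merge(meta[["sample_id", "sample_type", "batch",
                            "injection_order"]], on="sample_id", how="left")
    peak = peak[["sample_id", "sample_type", "batch", "injection_order",
                 "transition_id", "area"]]

    true_long = true_conc.stack().rename("concentration").reset_index()
    true_long.columns = ["sample_id", "species", "concentration"]
    return peak, meta, true_long


def generate_study(design: Optional[StudyDesign] = None,
                   truth: Optional[GroundTruth] = None,
                   panel: Optional[Panel] = None) -> SyntheticStudy:
    """One-call synthetic study at the default conditions."""
    design = design or StudyDesign()
    truth = truth or GroundTruth()
    panel = panel or default_panel()
    cohort = generate_cohort(design, truth, panel)
    peak, samples, true_long = generate_acquisition(design, truth, panel, cohort)
    analytes = panel.analyte_species
    names = [s.canonical_name for s in analytes]
    classes = np.array([s.lipid_class for s in analytes])
    rng_base = _stream(design.seed, "base_conc")
    weights = np.exp(rng_base.normal(0.0, 1.0, len(names)))
    base = np.empty(len(names))
    for cls in set(classes):
        m = classes == cls
        base[m] = truth.class_abundance.get(cls, 10.0) * weights[m] / weights[m].sum()
    return SyntheticStudy(
        design=design, peak_areas=peak, samples=samples,
        clinical=cohort["clinical"], troponin=cohort["troponin"],
        true_concentrations=true_long,
        base_concentrations=pd.Series(base, index=names))
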