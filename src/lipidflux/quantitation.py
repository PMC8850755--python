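"""MRM semi-quantitation: deisotoping, ISTD ratios, correction/response factors.

Raw per-injection peak areas become per-sample concentrations in four steps:

1. **Deisotoping** — within a class, the M+2 isotopologue of a species with
   one more double bond co-elutes into the monoisotopic transition of its
   partner (precursor +2 Da).  Processing species in decreasing double-bond
   order, ``corrected(S) = observed(S) - p2(S') * corrected(S')`` where
   ``p2(C) = C*(C-1)/2 * a**2`` with the natural 13C abundance ``a = 0.0107``
   and C the full molecular carbon count.
2. **ISTD ratio** — concentration = (area / ISTD area) * spiked ISTD
   concentration, per class.
3. **Acyl-chain correction factor (CF)** for DG/TG: a species whose fragment
   signal is split over k distinct acyl-loss channels retains 1/k of it in
   the monitored transition, so the measured ratio is divided by the CF
   (0.5 / 0.33 / 0.66 rules; identical-chain species, like the ISTDs, are 1).
4. **CE response factor** — chain-length/saturation-dependent detection
   efficiency of cholesteryl esters, from calibration lines fitted on an
   equimolar CE mixture; the measured ratio is divided by it.

Missing or zero ISTD areas make the affected sample/class concentrations
missing (flagged), never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies
from .panel import Panel, molecular_carbons

__all__ = [
    "C13_ABUNDANCE", "isotope_m2_fraction",
    "correction_factor", "ce_response_factor", "ResponseFactorModel",
    "deisotope", "quantify", "fa_qualifier_check",
    "QuantitationError", "NonPositiveResponseError",
]

#: Natural abundance of 13C used in the M+2 interference model.
C13_ABUNDANCE = 0.0107

PEAK_COLUMNS = ["sample_id", "sample_type", "batch", "injection_order",
                "transition_id", "area"]


class QuantitationError(ValueError):
    pass


class NonPositiveResponseError(QuantitationError):
    """A response-factor line evaluated to y <= 0."""


def isotope_m2_fraction(carbons: int, a: float = C13_ABUNDANCE) -> float:
    """M+2 isotopologue area relative to the monoisotopic peak.

    Linearized two-heavy-atom term: ``C*(C-1)/2 * a**2``.
    """
    return carbons * (carbons - 1) / 2.0 * a * a


# ---------------------------------------------------------------------------
# correction / response factors
# ---------------------------------------------------------------------------

def correction_factor(species: LipidSpecies) -> float:
    """Acyl-chain correction factor for DG/TG fragmentation.

    DG with two distinct chains -> 0.5; identical -> 1.0.
    TG with three distinct chains -> 0.33; exactly two identical -> 0.66;
    all identical -> 1.0.  Every other class -> 1.0.

    Raises :class:`QuantitationError` for DG/TG species without a
    chain-resolved name (the rule needs the chains).
    """
    if species.lipid_class not in ("DG", "TG"):
        return 1.0
    chains = species.acyl_chains
    expected = 2 if species.lipid_class == "DG" else 3
    if chains is None or len(chains) != expected:
        raise QuantitationError(
            f"{species.name!r}: {species.lipid_class} correction factor needs a "
            f"chain-resolved name with {expected} acyl chains "
            "(or pass an explicit CF override)")
    n_distinct = len(set(chains))
    if species.lipid_class == "DG":
        return 0.5 if n_distinct == 2 else 1.0
    if n_distinct == 3:
        return 0.33
    if n_distinct == 2:
        return 0.66
    return 1.0


@dataclass(frozen=True)
class ResponseFactorModel:
    """Linear response-factor lines y = slope*x + intercept for CE species,
    selected solely by double-bond count (0 / 1 / >=2); x = carbon chain length."""

    saturated: Tuple[float, float] = (0.13, -0.71)
    monounsaturated: Tuple[float, float] = (1.13, -0.23)
    polyunsaturated: Tuple[float, float] = (-0.07, 1.54)

    def line(self, double_bonds: int) -> Tuple[float, float]:
        if double_bonds == 0:
            return self.saturated
        if double_bonds == 1:
            return self.monounsaturated
        return self.polyunsaturated

    def __call__(self, carbons: int, double_bonds: int) -> float:
        slope, intercept = self.line(double_bonds)
        y = slope * carbons + intercept
        if y <= 0:
            raise NonPositiveResponseError(
                f"CE response factor non-positive (y={y:.4g}) for "
                f"x={carbons}, {double_bonds} double bonds")
        return y


DEFAULT_RF_MODEL = ResponseFactorModel()


def ce_response_factor(carbons: int, double_bonds: int,
                       model: ResponseFactorModel = DEFAULT_RF_MODEL) -> float:
    """Evaluate the CE response-factor line for one species."""
    return model(carbons, double_bonds)


def _species_factors(species: LipidSpecies,
                     rf_model: ResponseFactorModel = DEFAULT_RF_MODEL,
                     ) -> Tuple[float, Optional[float]]:
    """(CF, RF) for a species; RF is None when the line is non-positive."""
    cf = correction_factor(species)
    rf: Optional[float] = 1.0
    if species.lipid_class == "CE" and species.deuterium == 0:
        try:
            rf = ce_response_factor(species.total_carbons,
                                    species.total_double_bonds, rf_model)
        except NonPositiveResponseError:
            rf = None
    return cf, rf


# ---------------------------------------------------------------------------
# deisotoping
# ---------------------------------------------------------------------------

def _interference_pairs(panel: Panel) -> List[Tuple[str, str, float]]:
    """(receiver transition_id, source transition_id, p2) pairs.

    The source S' has the same class/carbons/flags and one more double bond
    than the receiver; p2 uses the source's full molecular carbon count.
    """
    by_sum: Dict[tuple, List[LipidSpecies]] = {}
    for s in panel.species:
        by_sum.setdefault(s.sum_key, []).append(s)
    pairs = []
    for s in panel.species:
        cls, c, d, e, p, o = s.sum_key
        sources = by_sum.get((cls, c, d + 1, e, p, o), [])
        for src in sources:
            if src.deuterium or s.deuterium:
                continue
            p2 = isotope_m2_fraction(molecular_carbons(src))
            pairs.append((f"{s.canonical_name}|quantifier",
                          f"{src.canonical_name}|quantifier", p2))
    return pairs


def deisotope(table: pd.DataFrame, panel: Panel) -> pd.DataFrame:
    """Remove M+2 isotope interference from quantifier areas.

    Species are processed in decreasing double-bond order within each
    (class, carbons) chain, so each source is already corrected when its
    contribution is subtracted.  Negative results are clipped to 0 and the
    row flagged ``clipped``.
    """
    out = table.copy()
    if "flags" not in out.columns:
        out["flags"] = ""
    pairs = _interference_pairs(panel)
    if not pairs:
        return out

    db_of = {f"{s.canonical_name}|quantifier": s.total_double_bonds
             for s in panel.species}
    # descending source double-bond count => sources corrected before use
    pairs.sort(key=lambda t: -db_of[t[1]])

    wide = out.pivot_table(index="sample_id", columns="transition_id",
                           values="area", aggfunc="first")
    clipped: Dict[str, pd.Series] = {}
    for recv, src, p2 in pairs:
        if recv not in wide.columns or src not in wide.columns:
            continue
        corrected = wide[recv] - p2 * wide[src]
        neg = corrected < 0
        if neg.any():
            clipped.setdefault(recv, pd.Series(False, index=wide.index))
            clipped[recv] |= neg
        wide[recv] = corrected.clip(lower=0.0)

    long = wide.stack().rename("area_corrected").reset_index()
    out = out.merge(long, on=["sample_id", "transition_id"], how="left")
    got = out["area_corrected"].notna()
    out.loc[got, "area"] = out.loc[got, "area_corrected"]
    out = out.drop(columns="area_corrected")
    for recv, mask in clipped.items():
        flagged_samples = mask[mask].index
        sel = (out["transition_id"] == recv) & out["sample_id"].isin(flagged_samples)
        out.loc[sel, "flags"] = out.loc[sel, "flags"].where(
            out.loc[sel, "flags"] != "", "clipped")
    return out


# ---------------------------------------------------------------------------
# quantitation
# ---------------------------------------------------------------------------

def quantify(table: pd.DataFrame, panel: Panel, *,
             cf_convention: str = "divide",
             rf_model: ResponseFactorModel = DEFAULT_RF_MODEL,
             deisotoped: bool = True) -> pd.DataFrame:
    """Convert (deisotoped) peak areas to semi-quantitative concentrations.

    conc = (area_species / area_ISTD) * ISTD_conc / CF / RF  (divide
    convention; ``cf_convention='multiply'`` is the escape hatch since the
    source method only says the factors were "applied").

    Returns a long table (sample_id, species, lipid_class, concentration,
    flags); one row per (sample, analyte species).
    """
    if cf_convention not in ("divide", "multiply"):
        raise QuantitationError(f"unknown cf_convention {cf_convention!r}")
    if not deisotoped:
        table = deisotope(table, panel)

    areas = table.pivot_table(index="sample_id", columns="transition_id",
                              values="area", aggfunc="first")
    sample_ids = areas.index

    rows = []
    for s in panel.analyte_species:
        istd = panel.istd_for(s.lipid_class)
        tid = f"{s.canonical_name}|quantifier"
        istd_tid = f"{istd.species.canonical_name}|quantifier"
        cf, rf = _species_factors(s, rf_model)
        area = areas[tid] if tid in areas.columns else pd.Series(np.nan, index=sample_ids)
        istd_area = (areas[istd_tid] if istd_tid in areas.columns
                     else pd.Series(np.nan, index=sample_ids))

        flags = pd.Series("", index=sample_ids)
        if rf is None:
            conc = pd.Series(np.nan, index=sample_ids)
            flags[:] = "rf_nonpositive"
        else:
            bad_istd = istd_area.isna() | (istd_area <= 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = area / istd_area.where(~bad_istd)
            factor = cf * rf
            conc = (ratio * istd.concentration / factor if cf_convention == "divide"
                    else ratio * istd.concentration * factor)
            flags[bad_istd] = "istd_missing"
            flags[area.isna() & ~bad_istd] = "area_missing"
        rows.append(pd.DataFrame({
            "sample_id": sample_ids,
            "species": s.canonical_name,
            "lipid_class": s.lipid_class,
            "concentration": conc.values,
            "flags": flags.values,
        }))
    out = pd.concat(rows, ignore_index=True)
    neg = out["concentration"] < 0
    out.loc[neg, "concentration"] = 0.0
    return out


# ---------------------------------------------------------------------------
# FA qualifier check
# ---------------------------------------------------------------------------

def fa_qualifier_check(quantifier_area: float, qualifier_area: float,
                       reference_ratio: float, tolerance: float = 0.5) -> bool:
    """``True`` (pass) when qualifier/quantifier stays within ``tolerance``
    relative deviation of the PQC-established reference ratio.

    FA species carry a second, higher-collision-energy transition with the
    same masses; a diverging ratio indicates an interferent on one channel.
    """
    if reference_ratio <= 0:
        raise QuantitationError("reference ratio must be positive")
    if quantifier_area <= 0:
        return False
    ratio = qualifier_area / quantifier_area
    return abs(ratio - reference_ratio) <= tolerance * reference_ratio


def fa_qualifier_flags(table: pd.DataFrame, panel: Panel,
                       tolerance: float = 0.5) -> pd.DataFrame:
    """Per (sample, FA species) qualifier check against the PQC reference ratio.

    Returns columns (sample_id, species, ratio, reference_ratio, passed).
    Species whose PQC reference ratio cannot be established are omitted.
    """
    fa = [s for s in panel.species if s.lipid_class == "FA"]
    areas = table.pivot_table(index="sample_id", columns="transition_id",
                              values="area", aggfunc="first")
    meta = table.drop_duplicates("sample_id").set_index("sample_id")["sample_type"]
    pqc_ids = meta[meta == "pqc"].index
    out = []
    for s in fa:
        quant, qual = (f"{s.canonical_name}|quantifier",
                       f"{s.canonical_name}|qualifier")
        if quant not in areas.columns or qual not in areas.columns:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = areas[qual] / areas[quant]
        ref = ratio.reindex(pqc_ids).median()
        if not np.isfinite(ref) or ref <= 0:
            continue
        passed = [fa_qualifier_check(q, ql, ref, tolerance)
                  if np.isfinite(q) and np.isfinite(ql) else False
                  for q, ql in zip(areas[quant], areas[qual])]
        out.append(pd.DataFrame({
            "sample_id": areas.index, "species": s.canonical_name,
            "ratio": ratio.values, "reference_ratio": ref, "passed": passed}))
    if not out:
        return pd.DataFrame(columns=["sample_id", "species", "ratio",
                                     "reference_ratio", "passed"])
    return pd.concat(out, ignore_index=True)
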