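"""MRM panel data model: transitions, internal-standard map, validation.

The panel is config data, read from a CSV with columns::

    species,lipid_class,precursor_mz,product_mz,polarity,role,istd_species,istd_conc,istd_units

Every non-ISTD species' class must map to a class-specific internal standard
(ISTD), the quantitation anchor spiked before extraction.  A packaged default
panel reconstructs the screened assay: 322 species across 25 classes/
subclasses, with odd-chain or deuterated ISTDs per class.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List

import pandas as pd

from .nomenclature import LipidSpecies, parse_lipid_name

__all__ = [
    "MRMTransition", "IstdAssignment", "Panel", "PanelError",
    "load_panel", "default_panel", "BACKBONE_CARBONS", "molecular_carbons",
]

PANEL_COLUMNS = ["species", "lipid_class", "precursor_mz", "product_mz",
                 "polarity", "role", "istd_species", "istd_conc", "istd_units"]

ROLES = ("quantifier", "qualifier", "isotope_m1", "isotope_m2")

#: Non-acyl ("backbone") carbons added per class when estimating the full
#: molecular carbon count for isotope-interference correction.  Shorthand
#: totals count fatty-acyl carbons only; the glycerol/headgroup/steroid
#: scaffold also carries carbon.  Config data, overridable.
BACKBONE_CARBONS: Dict[str, int] = {
    "CE": 27,        # cholesterol
    "PC": 8, "PC(O)": 8, "PC(P)": 8, "LPC": 8, "LPC(O)": 8, "OxPL": 8,
    "PE": 5, "PE(O)": 5, "PE(P)": 5, "LPE": 5,
    "PI": 9, "PS": 6, "PG": 6,
    "SM": 5,         # shorthand totals include the sphingoid base
    "Cer": 0, "dhCer": 0,
    "HexCer": 6, "Hex2Cer": 12, "Hex3Cer": 18, "GM3": 29,
    "DG": 3, "TG": 3,
    "FA": 0,
    "acylcarnitine": 7,
}


def molecular_carbons(species: LipidSpecies) -> int:
    """Estimated full molecular carbon count (acyl totals + class backbone)."""
    return species.total_carbons + BACKBONE_CARBONS[species.lipid_class]


class PanelError(ValueError):
    """Panel configuration error (missing ISTD, duplicate rows, bad columns)."""


@dataclass(frozen=True)
class MRMTransition:
    species: LipidSpecies
    precursor_mz: float
    product_mz: float
    polarity: str          # "positive" | "negative"
    role: str              # quantifier | qualifier | isotope_m1 | isotope_m2
    scheduled_window: float = 60.0

    @property
    def transition_id(self) -> str:
        return f"{self.species.canonical_name}|{self.role}"


@dataclass(frozen=True)
class IstdAssignment:
    species: LipidSpecies
    concentration: float
    units: str


@dataclass
class Panel:
    """Validated MRM panel: transitions plus the class -> ISTD map."""

    transitions: List[MRMTransition]
    istd_map: Dict[str, IstdAssignment]

    def __post_init__(self):
        self._validate()

    # ---- views -----------------------------------------------------------
    @property
    def species(self) -> List[LipidSpecies]:
        """Unique species (ISTDs included), in panel order."""
        seen, out = set(), []
        for t in self.transitions:
            if t.species.key not in seen:
                seen.add(t.species.key)
                out.append(t.species)
        return out

    @property
    def analyte_species(self) -> List[LipidSpecies]:
        istd_names = {a.species.canonical_name for a in self.istd_map.values()}
        return [s for s in self.species if s.canonical_name not in istd_names]

    @property
    def classes(self) -> List[str]:
        seen, out = set(), []
        for s in self.species:
            if s.lipid_class not in seen:
                seen.add(s.lipid_class)
                out.append(s.lipid_class)
        return out

    @property
    def class_count(self) -> int:
        return len({s.lipid_class for s in self.analyte_species})

    def __len__(self) -> int:
        return len(self.analyte_species)

    def istd_for(self, lipid_class: str) -> IstdAssignment:
        return self.istd_map[lipid_class]

    def quantifier(self, species: LipidSpecies) -> MRMTransition:
        for t in self.transitions:
            if t.species.key == species.key and t.role == "quantifier":
                return t
        raise PanelError(f"no quantifier transition for {species.canonical_name}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.transitions:
            cls = t.species.lipid_class
            istd = self.istd_map.get(cls)
            rows.append({
                "species": t.species.canonical_name,
                "lipid_class": cls,
                "precursor_mz": t.precursor_mz,
                "product_mz": t.product_mz,
                "polarity": t.polarity,
                "role": t.role,
                "istd_species": istd.species.canonical_name if istd else "",
                "istd_conc": istd.concentration if istd else float("nan"),
                "istd_units": istd.units if istd else "",
            })
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)

    # ---- validation ------------------------------------------------------
    def _validate(self) -> None:
        seen = set()
        for t in self.transitions:
            if t.role not in ROLES:
                raise PanelError(f"unknown transition role {t.role!r}")
            k = (t.species.key, t.role)
            if k in seen:
                raise PanelError(
                    f"duplicate ({t.species.canonical_name}, {t.role}) transition")
            seen.add(k)

        by_species: Dict[tuple, set] = {}
        for t in self.transitions:
            by_species.setdefault(t.species.key, set()).add(t.role)
        for s in self.species:
            roles = by_species[s.key]
            if "quantifier" not in roles:
                raise PanelError(f"species {s.canonical_name} has no quantifier")
            if s.lipid_class == "FA" and "qualifier" not in roles:
                raise PanelError(
                    f"FA species {s.canonical_name} needs a qualifier transition")

        missing = sorted({s.lipid_class for s in self.analyte_species}
                         - set(self.istd_map))
        if missing:
            raise PanelError(
                "no internal standard assigned for classes: " + ", ".join(missing))


def load_panel(path) -> Panel:
    """Read and validate a panel CSV (columns as in :data:`PANEL_COLUMNS`)."""
    df = pd.read_csv(path)
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelError(f"panel CSV missing columns: {missing_cols}")

    transitions: List[MRMTransition] = []
    istd_map: Dict[str, IstdAssignment] = {}
    for _, row in df.iterrows():
        sp = parse_lipid_name(str(row["species"]))
        if sp.lipid_class != str(row["lipid_class"]):
            raise PanelError(
                f"row {row['species']!r}: declared class {row['lipid_class']!r} "
                f"!= parsed class {sp.lipid_class!r}")
        transitions.append(MRMTransition(
            species=sp,
            precursor_mz=float(row["precursor_mz"]),
            product_mz=float(row["product_mz"]),
            polarity=str(row["polarity"]),
            role=str(row["role"]),
        ))
        istd_name = row["istd_species"]
        if isinstance(istd_name, str) and istd_name.strip():
            istd_sp = parse_lipid_name(istd_name)
            conc = float(row["istd_conc"])
            units = str(row["istd_units"])
            prev = istd_map.get(sp.lipid_class)
            if prev is not None and (prev.species.canonical_name, prev.concentration) != (
                    istd_sp.canonical_name, conc):
                raise PanelError(
                    f"conflicting ISTD assignment for class {sp.lipid_class}")
            istd_map[sp.lipid_class] = IstdAssignment(istd_sp, conc, units)
    return Panel(transitions=transitions, istd_map=istd_map)


def default_panel() -> Panel:
    """The packaged default panel: 322 species across 25 classes."""
    ref = importlib.resources.files("lipidflux.data") / "default_panel.csv"
    with importlib.resources.as_file(ref) as path:
        return load_panel(path)
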