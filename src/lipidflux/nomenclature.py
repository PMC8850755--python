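"""Lipid shorthand nomenclature: parsing and canonical strings.

Species are identified at the sum-composition level — lipid class plus the
total number of fatty-acyl carbons and double bonds (e.g. ``TG 51:0``) — the
granularity a scheduled-MRM triple-quadrupole assay can resolve.  Ether and
plasmalogen (vinyl-ether) subclasses are written ``PC(O-36:3)`` / ``PE(P-38:4)``.
Chain-resolved names (``TG 16:0_17:0_18:0``) are kept when known because the
DG/TG correction factors depend on which acyl chains are identical.
Oxidized-phosphatidylcholine species circulate under trivial names (POVPC,
PGPC, ...); these are resolved through a packaged alias table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "LIPID_CLASSES",
    "OXPL_ALIASES",
    "LipidSpecies",
    "LipidNameError",
    "parse_lipid_name",
]

#: The 25 lipid classes/subclasses covered by the MRM panel.
LIPID_CLASSES = (
    "CE", "PC", "PC(O)", "PC(P)", "LPC", "LPC(O)",
    "PE", "PE(O)", "PE(P)", "LPE", "PI", "PS", "PG",
    "SM", "Cer", "dhCer", "HexCer", "Hex2Cer", "Hex3Cer", "GM3",
    "DG", "TG", "FA", "acylcarnitine", "OxPL",
)

_CLASS_LOOKUP = {c.lower(): c for c in LIPID_CLASSES}
# Accepted synonyms for class tokens (case-insensitive).
_CLASS_LOOKUP.update({
    "ac": "acylcarnitine",
    "car": "acylcarnitine",
    "dcer": "dhCer",
})

#: Trivial-name oxidized phospholipids: name -> (acyl carbons, double bonds).
#: All are 1-palmitoyl (16:0) sn-1 PCs with a truncated/oxidized sn-2 chain;
#: carbons count the two acyl chains, double bonds count C=C only.
OXPL_ALIASES = {
    "POVPC": (21, 0),   # 16:0 / 5-oxovaleroyl (5:0 CHO)
    "PONPC": (25, 0),   # 16:0 / 9-oxononanoyl
    "PGPC": (21, 0),    # 16:0 / glutaroyl (5:0 COOH)
    "PAzPC": (25, 0),   # 16:0 / azelaoyl (9:0 COOH)
    "KOdiAPC": (24, 1),  # 16:0 / 5-keto-6-octenedioyl
    "KDdiAPC": (28, 1),  # 16:0 / 4-keto-dodec-3-enedioyl
}
_ALIAS_LOOKUP = {k.lower(): k for k in OXPL_ALIASES}


class LipidNameError(ValueError):
    """Raised when a lipid shorthand string cannot be parsed."""

    def __init__(self, name: str, fragment: str, reason: str = ""):
        self.name = name
        self.fragment = fragment
        msg = f"cannot parse lipid name {name!r}: offending fragment {fragment!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at sum-composition identity: (class, carbons, double bonds, flags)."""

    name: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether_flag: bool = False
    plasmalogen_flag: bool = False
    oxidized_flag: bool = False
    acyl_chains: Optional[Tuple[Tuple[int, int], ...]] = None
    deuterium: int = 0  # isotope-labelled internal standards, e.g. CE 18:0(d6)

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise LipidNameError(self.name, self.lipid_class, "unknown class")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise LipidNameError(self.name, f"{self.total_carbons}:{self.total_double_bonds}",
                                 "negative composition")
        if self.acyl_chains is not None:
            c = sum(ch[0] for ch in self.acyl_chains)
            d = sum(ch[1] for ch in self.acyl_chains)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise LipidNameError(
                    self.name, "_".join(f"{a}:{b}" for a, b in self.acyl_chains),
                    f"chain sums {c}:{d} != totals {self.total_carbons}:{self.total_double_bonds}")

    # Identity used throughout the pipeline. Sum-composition isomers are not
    # distinguished, except that a chain-resolved name (needed for DG/TG
    # correction factors, and for odd-chain ISTDs that share a sum composition
    # with an analyte, e.g. TG 17:0_17:0_17:0 vs TG 51:0) keeps its chains.
    @property
    def key(self) -> tuple:
        # Named OxPL aliases (POVPC vs PGPC, ...) differ in oxidized-chain
        # chemistry, not acyl sums, so the trivial name is part of identity.
        alias = self.name if (self.oxidized_flag and self.name in OXPL_ALIASES) else None
        return (self.lipid_class, self.total_carbons, self.total_double_bonds,
                self.ether_flag, self.plasmalogen_flag, self.oxidized_flag,
                self.deuterium, self.acyl_chains, alias)

    @property
    def sum_key(self) -> tuple:
        """Sum-composition identity (chains ignored) — isotope-overlap matching."""
        return (self.lipid_class, self.total_carbons, self.total_double_bonds,
                self.ether_flag, self.plasmalogen_flag, self.oxidized_flag)

    @property
    def canonical_name(self) -> str:
        if self.oxidized_flag and self.name in OXPL_ALIASES:
            return self.name
        base = self.lipid_class
        suffix = f"(d{self.deuterium})" if self.deuterium else ""
        if self.acyl_chains is not None:
            chains = "_".join(f"{c}:{d}" for c, d in sorted(self.acyl_chains))
            return f"{base} {chains}{suffix}"
        if base.endswith("(O)") or base.endswith("(P)"):
            mod = base[-2]
            return (f"{base[:-3]}({mod}-{self.total_carbons}:"
                    f"{self.total_double_bonds}){suffix}")
        return f"{base} {self.total_carbons}:{self.total_double_bonds}{suffix}"


_DEUT_RE = re.compile(r"\s*\(d(\d+)\)\s*$")
_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:_(\d+):(\d+))*$")
_ETHER_INLINE_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\(\s*(?P<mod>[OPop])-(?P<c>\d+):(?P<d>\d+)\s*\)$")
_PLAIN_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*(?:\([OPop]\))?)\s+(?P<body>[\d:_]+)$")


def _resolve_class(token: str, name: str) -> str:
    cls = _CLASS_LOOKUP.get(token.lower())
    if cls is None:
        raise LipidNameError(name, token, "unknown class token")
    return cls


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepted grammars (class tokens case-insensitive)::

        CLASS C:D              e.g.  "PC 34:2", "acylcarnitine 18:2"
        CLASS(O-C:D)           e.g.  "PC(O-36:3)"        ether subclass
        CLASS(P-C:D)           e.g.  "PE(P-38:4)"        plasmalogen subclass
        CLASS(O) C:D           alternate ether spelling
        CLASS C1:D1_C2:D2[..]  chain-resolved, e.g. "TG 16:0_17:0_18:0"
        ALIAS                  named OxPL, e.g. "PGPC"
        ... (dN)               deuterated ISTD suffix, e.g. "CE 18:0(d6)"

    Round-trips: ``parse(parse(name).canonical_name)`` equals ``parse(name)``.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidNameError(str(name), "", "empty name")
    raw = name.strip()

    deut = 0
    m = _DEUT_RE.search(raw)
    body_str = raw
    if m:
        deut = int(m.group(1))
        body_str = raw[: m.start()].strip()

    # named OxPL aliases
    alias = _ALIAS_LOOKUP.get(body_str.lower())
    if alias is not None:
        c, d = OXPL_ALIASES[alias]
        return LipidSpecies(name=alias, lipid_class="OxPL", total_carbons=c,
                            total_double_bonds=d, oxidized_flag=True, deuterium=deut)

    m = _ETHER_INLINE_RE.match(body_str)
    if m:
        base = _resolve_class(m.group("cls"), raw)
        mod = m.group("mod").upper()
        cls = f"{base}({mod})"
        if cls not in LIPID_CLASSES:
            raise LipidNameError(raw, cls, "no such ether/plasmalogen subclass")
        return LipidSpecies(
            name=raw, lipid_class=cls,
            total_carbons=int(m.group("c")), total_double_bonds=int(m.group("d")),
            ether_flag=(mod == "O"), plasmalogen_flag=(mod == "P"), deuterium=deut)

    m = _PLAIN_RE.match(body_str)
    if not m:
        raise LipidNameError(raw, body_str, "unrecognized grammar")
    token, body = m.group("cls"), m.group("body")
    mod = ""
    if token.endswith(("(O)", "(o)", "(P)", "(p)")):
        mod = token[-2].upper()
        token = token[:-3]
    base = _resolve_class(token, raw)
    cls = f"{base}({mod})" if mod else base
    if cls not in LIPID_CLASSES:
        raise LipidNameError(raw, cls, "no such ether/plasmalogen subclass")

    if not _CHAIN_RE.match(body):
        raise LipidNameError(raw, body, "malformed composition")
    parts = body.split("_")
    comps = []
    for p in parts:
        c_s, d_s = p.split(":")
        comps.append((int(c_s), int(d_s)))
    kwargs = dict(ether_flag=(mod == "O"), plasmalogen_flag=(mod == "P"),
                  oxidized_flag=(cls == "OxPL"), deuterium=deut)
    if len(comps) == 1:
        return LipidSpecies(name=raw, lipid_class=cls, total_carbons=comps[0][0],
                            total_double_bonds=comps[0][1], **kwargs)
    chains = tuple(sorted(comps))
    return LipidSpecies(
        name=raw, lipid_class=cls,
        total_carbons=sum(c for c, _ in chains),
        total_double_bonds=sum(d for _, d in chains),
        acyl_chains=chains, **kwargs)
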