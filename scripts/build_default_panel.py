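"""Maintainer script: regenerate the packaged default MRM panel CSV.

322 analyte species over 25 classes; class-specific ISTDs from the printed
standards list; m/z from a simple additive mass model (representative config
data, not measured values)."""



from pathlib import Path

import pandas as pd

from lipidflux.nomenclature import parse_lipid_name, OXPL_ALIASES
from lipidflux.panel import Panel, MRMTransition, IstdAssignment, load_panel, PANEL_COLUMNS

CH2, H2 = 14.01565, 2.01565

# approximate monoisotopic "base" mass per class at 0 acyl carbons, after adduct
BASE = {
    "CE": 386.35 + 18.034,      # [M+NH4]+
    "PC": 257.10 + 1.007, "PC(O)": 243.12 + 1.007, "PC(P)": 241.11 + 1.007,
    "LPC": 241.11 + 1.007, "LPC(O)": 227.13 + 1.007,
    "PE": 215.06 + 1.007, "PE(O)": 201.08 + 1.007, "PE(P)": 199.06 + 1.007,
    "LPE": 199.06 + 1.007,
    "PI": 336.07 + 18.034, "PS": 259.05 + 1.007, "PG": 246.05 + 18.034,
    "SM": 258.11 + 1.007,
    "Cer": 281.27 + 1.007, "dhCer": 283.28 + 1.007,
    "HexCer": 443.32 + 1.007, "Hex2Cer": 605.37 + 1.007, "Hex3Cer": 767.43 + 1.007,
    "GM3": 896.46 + 1.007,
    "DG": 92.05 + 18.034, "TG": 92.05 + 18.034,
    "FA": 46.01 - 1.007,        # [M-H]-
    "acylcarnitine": 161.11 + 1.007,
    "OxPL": 257.10 + 1.007,
}
# product ion rule per class
PRODUCT = {
    "CE": 369.35, "PC": 184.07, "PC(O)": 184.07, "PC(P)": 184.07,
    "LPC": 184.07, "LPC(O)": 184.07, "OxPL": 184.30,
    "SM": 184.07, "PE": "nl141", "PE(O)": "nl141", "PE(P)": "nl141",
    "LPE": "nl141", "PI": "nl277", "PS": "nl185", "PG": "nl189",
    "Cer": 264.27, "dhCer": 266.28, "HexCer": 264.27, "Hex2Cer": 264.27,
    "Hex3Cer": 264.27, "GM3": 264.27,
    "DG": "nl_fa", "TG": "nl_fa", "FA": "self", "acylcarnitine": 85.03,
}


def mz(cls, c, d):
    return round(BASE[cls] + CH2 * c - H2 * d, 3)


def product_mz(cls, c, d, chains=None):
    rule = PRODUCT[cls]
    pre = mz(cls, c, d)
    if rule == "nl141":
        return round(pre - 141.02, 3)
    if rule == "nl277":
        return round(pre - 277.06, 3)
    if rule == "nl185":
        return round(pre - 185.01, 3)
    if rule == "nl189":
        return round(pre - 189.04, 3)
    if rule == "nl_fa":
        ch = chains[0] if chains else (c // 2, 0)
        fa_mass = 46.01 + CH2 * ch[0] - H2 * ch[1]
        return round(pre - fa_mass - 17.027, 3)
    if rule == "self":
        return pre
    return rule


ISTDS = {  # class -> (istd name, conc, units)
    "CE": ("CE 18:0(d6)", 10.0, "uM"),
    "PC": ("PC 13:0_13:0", 10.0, "uM"),
    "PC(O)": ("PC 13:0_13:0", 10.0, "uM"),
    "PC(P)": ("PC 13:0_13:0", 10.0, "uM"),
    "LPC": ("LPC 13:0", 10.0, "uM"),
    "LPC(O)": ("LPC 13:0", 10.0, "uM"),
    "PE": ("PE 17:0_17:0", 10.0, "uM"),
    "PE(O)": ("PE 17:0_17:0", 10.0, "uM"),
    "PE(P)": ("PE 17:0_17:0", 10.0, "uM"),
    "LPE": ("LPE 14:0", 5.0, "uM"),
    "PI": ("PG 17:0_17:0", 5.0, "uM"),
    "PS": ("PS 17:0_17:0", 5.0, "uM"),
    "PG": ("PG 17:0_17:0", 5.0, "uM"),
    "SM": ("SM 12:0", 10.0, "uM"),
    "Cer": ("Cer 17:0", 5.0, "uM"),
    "dhCer": ("dhCer 8:0", 5.0, "uM"),
    "HexCer": ("HexCer 16:0(d3)", 2.0, "uM"),
    "Hex2Cer": ("Hex2Cer 16:0(d3)", 2.0, "uM"),
    "Hex3Cer": ("Hex3Cer 17:0", 2.0, "uM"),
    "GM3": ("Hex3Cer 17:0", 2.0, "uM"),
    "DG": ("DG 15:0_15:0", 10.0, "uM"),
    "TG": ("TG 17:0_17:0_17:0", 10.0, "uM"),
    "FA": ("FA 15:0(d3)", 50.0, "uM"),
    "acylcarnitine": ("acylcarnitine 14:0(d3)", 1.0, "uM"),
    "OxPL": ("PC 9:0_9:0", 1.0, "uM"),
}


def grid(cs, ds):
    return [(c, d) for c in cs for d in ds]


SPECIES = {}  # class -> list of names

SPECIES["CE"] = [f"CE {c}:{d}" for c, d in [
    (14, 0), (15, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2),
    (18, 3), (20, 0), (20, 3), (20, 4), (20, 5), (22, 5), (22, 6)]]  # 15

pc = ([(30, 0), (30, 1), (31, 0), (32, 0), (32, 1), (32, 2), (33, 1), (33, 2)]
      + grid([34], [0, 1, 2, 3, 4]) + grid([35], [1, 2]) + grid([36], [0, 1, 2, 3, 4, 5, 6])
      + [(38, 2), (40, 4)]
      + grid([37], [4]) + grid([38], [3, 4, 5, 6]) + grid([39], [6])
      + grid([40], [5, 6, 7, 8]) + [(41, 6), (42, 6)])
SPECIES["PC"] = [f"PC {c}:{d}" for c, d in pc]  # 8+4+2+6+1+4+1+4+2 = 32? recount below

SPECIES["PC(O)"] = [f"PC(O-{c}:{d})" for c, d in
                    grid([32, 34, 36, 38], [0, 1, 2, 3]) + [(40, 4), (40, 6)]]  # 18
SPECIES["PC(P)"] = [f"PC(P-{c}:{d})" for c, d in
                    grid([32, 34, 36, 38], [1, 2]) + [(40, 4), (40, 6)]]  # 10
SPECIES["LPC"] = [f"LPC {c}:{d}" for c, d in [
    (14, 0), (15, 0), (16, 0), (16, 1), (17, 0), (17, 1), (18, 0), (18, 1),
    (18, 2), (18, 3), (20, 3), (20, 4), (20, 5), (22, 6)]]  # 14
SPECIES["LPC(O)"] = [f"LPC(O-{c}:{d})" for c, d in
                     [(16, 0), (16, 1), (18, 0), (18, 1), (20, 0), (22, 0)]]  # 6
pe = ([(32, 1), (33, 1), (34, 1), (34, 2), (35, 1), (35, 2), (36, 1), (36, 2),
       (36, 3), (36, 4), (37, 4), (38, 3), (38, 4), (38, 5), (38, 6), (39, 6),
       (40, 4), (40, 5), (40, 6), (40, 7), (41, 6), (42, 6), (42, 7), (42, 8)])
SPECIES["PE"] = [f"PE {c}:{d}" for c, d in pe]  # 24
SPECIES["PE(O)"] = [f"PE(O-{c}:{d})" for c, d in
                    grid([34, 36, 38], [1, 2, 3]) + [(40, 4)]]  # 10
SPECIES["PE(P)"] = [f"PE(P-{c}:{d})" for c, d in
                    grid([34, 36, 38], [1, 2, 4]) + [(40, 6)]]  # 10
SPECIES["LPE"] = [f"LPE {c}:{d}" for c, d in
                  [(16, 0), (18, 0), (18, 1), (18, 2), (20, 4), (20, 5), (22, 5), (22, 6)]]  # 8
SPECIES["PI"] = [f"PI {c}:{d}" for c, d in
                 [(32, 0), (32, 1), (34, 0), (34, 1), (34, 2), (36, 1), (36, 2), (36, 3),
                  (36, 4), (38, 3), (38, 4), (38, 5), (40, 5), (40, 6)]]  # 14
SPECIES["PS"] = [f"PS {c}:{d}" for c, d in
                 [(34, 1), (36, 1), (36, 2), (38, 3), (38, 4), (38, 5), (40, 5), (40, 6),
                  (42, 7), (42, 8)]]  # 10
SPECIES["PG"] = [f"PG {c}:{d}" for c, d in
                 [(32, 0), (32, 1), (34, 1), (34, 2), (36, 1), (36, 2), (36, 4), (38, 5)]]  # 8
SPECIES["SM"] = [f"SM {c}:{d}" for c, d in
                 [(31, 1), (32, 1), (32, 2), (33, 1), (34, 1), (34, 2), (35, 1), (36, 1),
                  (36, 2), (37, 1), (37, 2), (38, 1), (38, 2), (39, 1), (40, 1), (40, 2),
                  (41, 2), (42, 2)]]  # 18
SPECIES["Cer"] = [f"Cer {c}:{d}" for c, d in
                  [(16, 0), (18, 0), (20, 0), (22, 0), (23, 0), (24, 0), (24, 1), (25, 0),
                   (26, 0), (26, 1)]]  # 10
SPECIES["dhCer"] = [f"dhCer {c}:{d}" for c, d in
                    [(16, 0), (18, 0), (20, 0), (22, 0), (24, 0), (24, 1), (25, 0), (26, 0)]]  # 8
SPECIES["HexCer"] = [f"HexCer {c}:{d}" for c, d in
                     [(16, 0), (18, 0), (20, 0), (22, 0), (23, 0), (24, 0), (24, 1),
                      (25, 0), (26, 0), (26, 1)]]  # 10
SPECIES["Hex2Cer"] = [f"Hex2Cer {c}:{d}" for c, d in
                      [(16, 0), (18, 0), (22, 0), (24, 0), (24, 1), (26, 0)]]  # 6
SPECIES["Hex3Cer"] = [f"Hex3Cer {c}:{d}" for c, d in
                      [(16, 0), (18, 0), (22, 0), (24, 0), (24, 1)]]  # 5
SPECIES["GM3"] = [f"GM3 {c}:{d}" for c, d in
                  [(16, 0), (18, 0), (22, 0), (24, 0), (24, 1), (26, 0)]]  # 6
SPECIES["DG"] = ["DG " + "_".join(p) for p in [
    ("14:0", "18:1"), ("15:0", "18:1"), ("16:0", "16:0"), ("16:0", "18:1"),
    ("16:0", "18:2"), ("16:1", "18:2"), ("17:0", "18:1"), ("18:0", "18:0"),
    ("18:0", "18:1"), ("18:1", "18:1"), ("18:1", "18:2"), ("18:2", "18:2"),
    ("16:0", "20:5"), ("18:1", "20:4"), ("16:0", "22:6"), ("18:1", "22:6")]]  # 16
SPECIES["TG"] = ["TG " + "_".join(p) for p in [
    ("14:0", "16:0", "16:0"), ("14:0", "16:0", "18:1"), ("15:0", "16:0", "18:1"),
    ("16:0", "16:0", "16:0"), ("16:0", "16:0", "18:0"), ("16:0", "16:0", "18:1"),
    ("16:0", "16:0", "18:2"), ("16:0", "17:0", "18:0"), ("16:0", "17:0", "18:1"),
    ("16:0", "18:0", "18:1"), ("16:0", "18:1", "18:1"), ("16:0", "18:1", "18:2"),
    ("16:0", "18:2", "18:2"), ("17:0", "18:1", "18:1"), ("18:0", "18:1", "18:1"),
    ("18:1", "18:1", "18:1"), ("18:1", "18:1", "18:2"), ("18:1", "18:2", "18:2"),
    ("18:2", "18:2", "18:2"), ("18:1", "18:1", "20:3"), ("14:0", "18:1", "18:2"),
    ("17:0", "18:0", "18:1"), ("16:0", "18:1", "22:6"), ("18:1", "18:1", "20:4"),
    ("16:1", "18:2", "18:2"), ("14:0", "16:1", "18:1"), ("16:0", "16:0", "20:0"),
    ("18:0", "18:0", "18:0"), ("16:0", "18:2", "20:5"), ("18:2", "18:2", "22:4")]]  # 30
SPECIES["FA"] = [f"FA {c}:{d}" for c, d in
                 [(14, 0), (16, 0), (16, 1), (17, 0), (18, 0), (18, 1), (18, 2), (18, 3),
                  (20, 3), (20, 4), (20, 5), (22, 4), (22, 5), (22, 6)]]  # 14
SPECIES["acylcarnitine"] = [f"acylcarnitine {c}:{d}" for c, d in
                            [(12, 0), (14, 0), (14, 1), (16, 0), (16, 1), (18, 0),
                             (18, 1), (18, 2), (20, 0), (20, 4)]]  # 10
SPECIES["OxPL"] = list(OXPL_ALIASES)  # 6

counts = {k: len(v) for k, v in SPECIES.items()}
total = sum(counts.values())
print(counts, "total:", total)
assert total == 322, total
assert len(counts) == 25

rows = []


def add_rows(name, role="quantifier"):
    sp = parse_lipid_name(name)
    cls = sp.lipid_class
    c, d = sp.total_carbons, sp.total_double_bonds
    istd_name, istd_conc, istd_units = ISTDS[cls]
    pre = mz(cls, c, d)
    prod = product_mz(cls, c, d, sp.acyl_chains)
    if role == "qualifier":  # FA second transition: same masses, higher CE
        prod = pre
    pol = "negative" if cls == "FA" else "positive"
    rows.append(dict(species=sp.canonical_name, lipid_class=cls, precursor_mz=pre,
                     product_mz=prod, polarity=pol, role=role,
                     istd_species=istd_name, istd_conc=istd_conc,
                     istd_units=istd_units))


for cls, names in SPECIES.items():
    for name in names:
        add_rows(name)
        if cls == "FA":
            add_rows(name, role="qualifier")

for cls, (istd_name, conc, units) in ISTDS.items():
    if any(r["species"] == parse_lipid_name(istd_name).canonical_name for r in rows):
        continue
    add_rows(istd_name)
    if parse_lipid_name(istd_name).lipid_class == "FA":
        add_rows(istd_name, role="qualifier")

df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
out = str(Path(__file__).resolve().parents[1] / "src/lipidflux/data/default_panel.csv")
df.to_csv(out, index=False)
print("wrote", out, len(df), "rows")

p = load_panel(out)
print("analytes:", len(p), "classes:", p.class_count)
assert len(p) == 322 and p.class_count == 25
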