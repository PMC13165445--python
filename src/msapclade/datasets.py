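"""Published reference tables for a 14-cultivar Fittonia panel.

These are the printed summary tables from a molecular/cytometric survey of
14 commercially cultivated Fittonia (nerve plant) varieties: per-cultivar
MSAP band-type counts, per-primer-combination fragment tallies, and
flow-cytometry 2C values with their replicate SDs.  They serve as worked
inputs for the index and genome-size calculators and as calibration ranges
for the synthetic generator; the underlying band matrices themselves were
never published.
"""

from __future__ import annotations

#: Per-cultivar MSAP band-type counts.
#: Columns: type I total, methylation-sensitive subset of type I, type II,
#: type III, type IV, total amplified bands.
MSAP_TYPE_COUNTS: dict[str, dict[str, int]] = {
    "Frankie":      {"type_i_total": 213, "type_i_ms": 101, "type_ii": 210, "type_iii": 155, "type_iv": 90,  "total": 668},
    "Titanic":      {"type_i_total": 208, "type_i_ms": 68,  "type_ii": 181, "type_iii": 144, "type_iv": 135, "total": 668},
    "White Anne":   {"type_i_total": 207, "type_i_ms": 92,  "type_ii": 213, "type_iii": 149, "type_iv": 99,  "total": 668},
    "Red Anne":     {"type_i_total": 213, "type_i_ms": 90,  "type_ii": 211, "type_iii": 157, "type_iv": 87,  "total": 668},
    "Fortissima":   {"type_i_total": 207, "type_i_ms": 92,  "type_ii": 202, "type_iii": 164, "type_iv": 95,  "total": 668},
    "Angel Snow":   {"type_i_total": 221, "type_i_ms": 66,  "type_ii": 194, "type_iii": 144, "type_iv": 108, "total": 667},
    "Red Star":     {"type_i_total": 204, "type_i_ms": 88,  "type_ii": 216, "type_iii": 154, "type_iv": 94,  "total": 668},
    "Black Star":   {"type_i_total": 203, "type_i_ms": 87,  "type_ii": 215, "type_iii": 158, "type_iv": 92,  "total": 668},
    "Red Vein":     {"type_i_total": 211, "type_i_ms": 90,  "type_ii": 213, "type_iii": 159, "type_iv": 85,  "total": 668},
    "Mini-Josan":   {"type_i_total": 210, "type_i_ms": 94,  "type_ii": 210, "type_iii": 157, "type_iv": 91,  "total": 668},
    "Leather Leaf": {"type_i_total": 211, "type_i_ms": 99,  "type_ii": 212, "type_iii": 157, "type_iv": 87,  "total": 667},
    "Jacmita":      {"type_i_total": 208, "type_i_ms": 96,  "type_ii": 212, "type_iii": 151, "type_iv": 98,  "total": 669},
    "Red Angel":    {"type_i_total": 210, "type_i_ms": 93,  "type_ii": 209, "type_iii": 156, "type_iv": 91,  "total": 668},
    "Superba":      {"type_i_total": 200, "type_i_ms": 95,  "type_ii": 209, "type_iii": 156, "type_iv": 104, "total": 669},
}

#: AFLP primer-pair combinations: (combination, fragments, variable fragments).
AFLP_PRIMER_COUNTS: list[tuple[str, int, int]] = [
    ("EcoRI+AAG/MseI+CAC", 53, 32),
    ("EcoRI+AGC/MseI+CAC", 58, 37),
    ("EcoRI+ACA/MseI+CAG", 54, 23),
    ("EcoRI+ACT/MseI+CAG", 44, 27),
    ("EcoRI+ACC/MseI+CAT", 94, 54),
    ("EcoRI+AGC/MseI+CAT", 36, 24),
    ("EcoRI+AAC/MseI+CTA", 40, 13),
    ("EcoRI+ACC/MseI+CTA", 32, 20),
    ("EcoRI+ACT/MseI+CTA", 53, 31),
    ("EcoRI+AGG/MseI+CTA", 44, 26),
    ("EcoRI+AAC/MseI+CTT", 19, 4),
    ("EcoRI+AGG/MseI+CTT", 22, 1),
]

#: MSAP primer combinations: (combination, fragments, HpaII-variable,
#: MspI-variable).
MSAP_PRIMER_COUNTS: list[tuple[str, int, int, int]] = [
    ("EcoRI+ACA/HM+ACT", 80, 34, 14),
    ("EcoRI+ACC/HM+ACT", 58, 49, 47),
    ("EcoRI+ACT/HM+ACT", 80, 60, 77),
    ("EcoRI+AGG/HM+ACT", 60, 23, 10),
    ("EcoRI+AAC/HM+ACT", 41, 29, 20),
    ("EcoRI+ACG/HM+ACT", 34, 18, 32),
    ("EcoRI+AAC/HM+AAC", 40, 19, 19),
    ("EcoRI+ACG/HM+AAC", 30, 24, 26),
    ("EcoRI+AAC/HM+AAT", 50, 18, 22),
    ("EcoRI+ACA/HM+AAT", 60, 22, 23),
    ("EcoRI+ACG/HM+AAT", 70, 45, 34),
    ("EcoRI+ACT/HM+AAT", 64, 23, 50),
]

#: Flow-cytometry 2C values: cultivar -> (mean pg, replicate SD pg).
TWO_C_VALUES: dict[str, tuple[float, float]] = {
    "Red Anne":     (2.92, 0.06),
    "Leather Leaf": (2.89, 0.08),
    "Fortissima":   (2.88, 0.06),
    "Red Angel":    (2.86, 0.04),
    "Mini Josan":   (2.89, 0.04),
    "Superba":      (2.85, 0.06),
    "Jacmita":      (2.86, 0.01),
    "Black Star":   (2.94, 0.05),
    "Red Star":     (2.88, 0.04),
    "White Anne":   (2.87, 0.03),
    "Frankie":      (2.91, 0.04),
    "Red Vein":     (2.86, 0.05),
    "Titanic":      (2.74, 0.02),
    "Angel Snow":   (2.73, 0.03),
}

#: The two-cultivar cluster consistently separated from the other twelve.
CLADE_I: tuple[str, str] = ("Titanic", "Angel Snow")
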