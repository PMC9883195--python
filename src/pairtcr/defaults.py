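"""Default marker and signature gene sets.

The marker sets follow the classic immune markers used for manual annotation
of mouse immune cells (Cd3d/Cd4/Cd8a for T-cell compartments, Klrb1c for NK
cells, Cd68/Csf1r/Adgre1 for macrophages, ...).  The M1/M2 polarization lists
are conventional stand-ins drawn from the polarization-marker literature and
are configuration inputs, not hard-coded truth: callers may supply their own
lists as GMT or two-column TSV files.
"""

from __future__ import annotations

# cell-type label -> marker gene symbols (mouse-style capitalisation)
DEFAULT_MARKER_SETS: dict[str, list[str]] = {
    "Cd4_T": [
        "Cd4", "Cd40lg", "Icos", "Il7r", "Cd28",
        "Ctla4", "Tnfrsf4", "Cd5", "Lat", "Tcf7",
    ],
    "Cd8_T": [
        "Cd8a", "Cd8b1", "Cd3d", "Cd3e", "Cd3g",
        "Lck", "Cd2", "Thy1", "Trbc2", "Cd247",
    ],
    "NKT": [
        "Zbtb16", "Klrk1", "Klrc1", "Cd160", "Il2rb",
        "Klra1", "Slamf1", "Slamf6", "Vsir", "Cd244a",
    ],
    "NK": [
        "Klrb1c", "Ncr1", "Eomes", "Klra4", "Klra8",
        "Itga2", "Tbx21", "Txk", "Klri2", "Serpinb9",
    ],
    "B": [
        "Cd19", "Ms4a1", "Cd79a", "Cd79b", "Ighm",
        "Ighd", "Pax5", "Ebf1", "Fcmr", "Cr2",
    ],
    "Macrophage": [
        "Cd68", "Csf1r", "Adgre1", "Fcgr1", "Itgam",
        "Mertk", "C1qa", "C1qb", "Lyz2", "Cd14",
    ],
}

# signature id -> gene symbols
DEFAULT_SIGNATURE_SETS: dict[str, list[str]] = {
    "M1": [
        "Nos2", "Il1b", "Il6", "Tnf", "Cd80",
        "Cd86", "Cxcl9", "Cxcl10", "Il12b", "Ptgs2",
    ],
    "M2": [
        "Arg1", "Mrc1", "Chil3", "Retnla", "Il10",
        "Tgfb1", "Cd163", "Ccl22", "Mgl2", "Clec7a",
    ],
    "cytotoxicity": [
        "Gzma", "Gzmb", "Gzmk", "Prf1", "Ifng",
        "Faslg", "Klrd1", "Ctsw", "Cst7", "Rab27a",
    ],
}

T_CELL_TYPES = ("Cd4_T", "Cd8_T", "NKT")
TISSUES = ("blood_d0", "blood_d15", "tumor_d15")
GROUPS = ("normal", "sephin1")

#: tissue -> display name used in exported composition tables
TISSUE_DISPLAY = {
    "blood_d0": "Day 0_Blood",
    "blood_d15": "Day 15_Blood",
    "tumor_d15": "Day 15_Tumor",
}
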