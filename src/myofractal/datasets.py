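"""Bundled reference dataset: eight chicken breeds, two muscles, seven genes.

The package ships the complete published panel of qPCR fold-change values
for seven early-myogenesis genes (MSTN, GHR, MEF2C, MYOD1, MYOG, MYH1,
MYF5; housekeeping reference TBP) measured in breast and thigh muscle of
E14 embryos of eight breeds spanning the meat, dual-purpose, egg and game
utility types, together with the matching breed phenotypes (body weights,
embryonic NO metabolite levels) and the per-breed rank windows used for
the published fractal-dimension fits.
"""

from __future__ import annotations

from .data_model import FCRecord, FCTable, PhenotypeRecord, RankWindow

__all__ = [
    "BREEDS",
    "BREED_CODES",
    "GENES",
    "HOUSEKEEPING_GENE",
    "DEFAULT_INTERCEPT_MODES",
    "load_reference_expression",
    "load_reference_phenotypes",
    "load_reference_windows",
    "load_reference_dataset",
]

GENES = ("MSTN", "GHR", "MEF2C", "MYOD1", "MYOG", "MYH1", "MYF5")
HOUSEKEEPING_GENE = "TBP"

BREED_CODES = {
    "BR": "Broiler",
    "WC": "White Cornish",
    "PRW": "Plymouth Rock White",
    "YC": "Yurlov Crower",
    "BB": "Brahma Buff",
    "OMF": "Orloff Mille Fleur",
    "LR": "Layer",
    "UG": "Uzbek Game",
}
BREEDS = tuple(BREED_CODES)

# Signed fold changes per breed, in the fixed gene order of GENES.
_BREAST_FC = {
    "BR": (11.55, 6.63, 6.59, 11.31, 7.46, -41760.00, -7.57),
    "WC": (4.89, 5.62, 2.91, 2.19, -4.32, -16.22, -685.02),
    "PRW": (6.59, 4.35, 4.0, 2.87, 78.25, -24.42, -4.76),
    "YC": (121.9, 69.1, 302.3, -7.11, 2.04, 1.07, -5.90),
    "BB": (41.07, 31.78, 219.8, -25.46, -1.95, -1.73, -8.57),
    "OMF": (2.41, 3.32, 2.33, 16.11, 5.58, -16270.00, -37.53),
    "LR": (4.72, 4.79, 4.14, 4.59, 1.03, -29.45, -66.26),
    "UG": (1.18, 2.51, 1.45, -81.01, -106.9, -11990.00, -4.47),
}
_THIGH_FC = {
    "BR": (3.86, 3.07, 2.36, 18.77, 6.73, -10020.00, -6.45),
    "WC": (4.03, 3.05, -1.69, -12.13, -4640.29, -335.46, -25531.63),
    "PRW": (4.5, 2.95, -1.02, 13.18, 1.39, -115.36, -33.36),
    "YC": (46.53, 26.1, 494.56, 28.44, 1.39, 2.3, 195.36),
    "BB": (8.86, 3.72, 63.39, 8.78, -2.70, 1.37, 38.02),
    "OMF": (-1.28, 1.62, 1.78, 6.06, 3.63, -8481.00, -18.90),
    "LR": (1.25, 1.31, 2.46, 1.08, -78.25, 6.23, -87.43),
    "UG": (3.25, 4.92, -4.79, -13.93, -118.60, -17560.00, -2.43),
}

# breed -> (bw1, bw14, bw28, nod µM, nitrate µM, breed_type)
_PHENOTYPES = {
    "BR": (47.5, 305.0, 1157.0, 3.3, 145.4, "meat"),
    "WC": (49.3, 291.7, 1287.5, 9.5, 152.2, "meat"),
    "PRW": (44.9, 265.2, 1058.4, 141.8, 0.0, "dual_purpose"),
    "YC": (39.0, 101.3, 240.0, 149.6, 0.0, "dual_purpose"),
    "BB": (38.2, 107.5, 241.7, 36.0, 100.0, "dual_purpose"),
    "OMF": (35.5, 93.1, 167.8, 131.5, 0.0, "dual_purpose"),
    "LR": (42.4, 79.8, 222.4, 138.9, 0.0, "egg"),
    "UG": (41.3, 92.4, 223.7, 8.8, 143.4, "game"),
}

# Nominal category labels used by the published ANOVA comparisons.  PRW, the
# maternal line of the broiler cross, is assigned to "meat" there.
_CATEGORIES = {
    "BR": {"nod": "low", "nitrate": "high", "no_oxidation": "high", "breed_type": "meat"},
    "WC": {"nod": "low", "nitrate": "high", "no_oxidation": "high", "breed_type": "meat"},
    "PRW": {"nod": "high", "nitrate": "low", "no_oxidation": "low", "breed_type": "meat"},
    "YC": {"nod": "high", "nitrate": "low", "no_oxidation": "low", "breed_type": "no"},
    "BB": {"nod": "low", "nitrate": "high", "no_oxidation": "high", "breed_type": "no"},
    "OMF": {"nod": "high", "nitrate": "low", "no_oxidation": "low", "breed_type": "no"},
    "LR": {"nod": "high", "nitrate": "low", "no_oxidation": "low", "breed_type": "no"},
    "UG": {"nod": "low", "nitrate": "high", "no_oxidation": "high", "breed_type": "no"},
}

# breed -> tissue -> rank window of the published dimension fits
_WINDOWS = {
    "BR": {"breast": (1, 6), "thigh": (1, 4)},
    "WC": {"breast": (1, 6), "thigh": (3, 7)},
    "PRW": {"breast": (1, 4), "thigh": (1, 4)},
    "YC": {"breast": (1, 6), "thigh": (1, 4)},
    "BB": {"breast": (2, 7), "thigh": (1, 4)},
    "OMF": {"breast": (2, 6), "thigh": (1, 4)},
    "LR": {"breast": (1, 6), "thigh": (1, 4)},
    "UG": {"breast": (1, 6), "thigh": (1, 4)},
}

# (breed, tissue) pairs whose published rank-exponential fit used a free
# intercept; every other fit is through the origin.  This map reproduces the
# published per-breed slopes and is configuration, not logic: the prose
# description of which breeds have a = 0 does not fully determine it.
DEFAULT_INTERCEPT_MODES = {
    ("BR", "breast"): "free_intercept",
    ("BR", "thigh"): "free_intercept",
    ("WC", "breast"): "free_intercept",
    ("UG", "thigh"): "free_intercept",
}


def load_reference_expression() -> FCTable:
    """The full 8-breed x 2-tissue x 7-gene signed fold-change panel."""
    records = []
    for tissue, data in (("breast", _BREAST_FC), ("thigh", _THIGH_FC)):
        for breed in BREEDS:
            for gene, fc in zip(GENES, data[breed]):
                records.append(FCRecord(breed, tissue, gene, fc))
    return FCTable(records, housekeeping_gene=HOUSEKEEPING_GENE)


def load_reference_phenotypes() -> list[PhenotypeRecord]:
    return [
        PhenotypeRecord(
            breed=breed, bw1=v[0], bw14=v[1], bw28=v[2],
            nod=v[3], nitrate=v[4], breed_type=v[5],
            categories=_CATEGORIES[breed],
        )
        for breed, v in _PHENOTYPES.items()
    ]


def load_reference_windows() -> dict[str, dict[str, RankWindow]]:
    return {
        breed: {tissue: RankWindow(*w) for tissue, w in per.items()}
        for breed, per in _WINDOWS.items()
    }


def load_reference_dataset() -> tuple[
    FCTable, list[PhenotypeRecord], dict[str, dict[str, RankWindow]]
]:
    """Expression table, phenotype records and dimension-fit rank windows."""
    return (
        load_reference_expression(),
        load_reference_phenotypes(),
        load_reference_windows(),
    )
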