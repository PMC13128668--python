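"""Amino-acid property tables used by the physicochemical descriptors.

All tables cover exactly the 20 standard residues. Scales are classical
published ones (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity,
Grantham polarity/volume, Chou–Fasman secondary-structure propensities,
residue masses, isoelectric points); autocorrelation descriptors z-score
them over the 20 residues, so each scale contributes shape, not units.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# number of sense codons per amino acid (standard genetic code; sums to 61)
CODON_COUNTS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}
assert sum(CODON_COUNTS.values()) == 61

# --- property scales (indexed by AA order above) -------------------------

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}
_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
_ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}
_GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
_GRANTHAM_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
_CHOU_FASMAN_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06,
}
_CHOU_FASMAN_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70,
}

#: ordered (name, scale) pairs used by the Moran autocorrelation default
MORAN_PROPERTIES: list[tuple[str, dict[str, float]]] = [
    ("hydropathy_KD", _KYTE_DOOLITTLE),
    ("hydrophilicity_HW", _HOPP_WOODS),
    ("residue_mass", _RESIDUE_MASS),
    ("isoelectric_point", _ISOELECTRIC_POINT),
    ("polarity_Grantham", _GRANTHAM_POLARITY),
    ("volume_Grantham", _GRANTHAM_VOLUME),
    ("helix_propensity_CF", _CHOU_FASMAN_HELIX),
    ("sheet_propensity_CF", _CHOU_FASMAN_SHEET),
]


def scale_vector(scale: dict[str, float], standardize: bool = True) -> np.ndarray:
    """Scale as a 20-vector in AA order, optionally z-scored over residues."""
    v = np.array([scale[a] for a in AA], dtype=float)
    if standardize:
        v = (v - v.mean()) / v.std()  # population std over the 20 residues
    return v


# --- CTD: 3-class partitions of the alphabet for 7 attributes ------------
# Standard Dubchak-style groupings used throughout the descriptor toolkits.

CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

for _name, _groups in CTD_ATTRIBUTES.items():
    assert sorted("".join(_groups)) == sorted(AA), _name


def ctd_class_array(attribute: str) -> np.ndarray:
    """Class index (0/1/2) per residue, in AA order."""
    groups = CTD_ATTRIBUTES[attribute]
    out = np.empty(20, dtype=np.int64)
    for cls, members in enumerate(groups):
        for a in members:
            out[AA_INDEX[a]] = cls
    return out


def physicochemical_distance_matrix() -> np.ndarray:
    """20x20 inter-residue distance for the sequence-order coupling numbers.

    Euclidean distance over three z-scored scales (hydropathy,
    hydrophilicity, residue mass) — the quasi-sequence-order convention.
    Symmetric with zero diagonal.
    """
    props = np.stack(
        [
            scale_vector(_KYTE_DOOLITTLE),
            scale_vector(_HOPP_WOODS),
            scale_vector(_RESIDUE_MASS),
        ],
        axis=1,
    )  # (20, 3)
    diff = props[:, None, :] - props[None, :, :]
    return np.sqrt((diff**2).mean(axis=2))


def grantham_like_distance_matrix() -> np.ndarray:
    """Alternative distance built from polarity and volume scales."""
    props = np.stack(
        [scale_vector(_GRANTHAM_POLARITY), scale_vector(_GRANTHAM_VOLUME)], axis=1
    )
    diff = props[:, None, :] - props[None, :, :]
    return np.sqrt((diff**2).mean(axis=2))
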