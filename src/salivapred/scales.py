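"""Amino-acid property scales, 3-class groupings and structural propensities.

All tables are keyed by the 20 canonical one-letter codes. Autocorrelation
descriptors consume scales standardized over the 20 amino-acid values
(mean 0, population sd 1); composition-style summaries use the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class PropertyScale:
    """A per-residue physicochemical scale plus its standardized form."""

    name: str
    raw: dict[str, float]
    standardized: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if set(self.raw) != AA_SET:
            missing = AA_SET - set(self.raw)
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        vals = np.array([self.raw[a] for a in AA_ALPHABET], dtype=float)
        sd = vals.std()  # population sd over the 20 residues
        if sd == 0:
            raise ValueError(f"scale {self.name!r} is constant")
        std = (vals - vals.mean()) / sd
        object.__setattr__(
            self, "standardized", {a: float(v) for a, v in zip(AA_ALPHABET, std)}
        )

    def values(self, standardized: bool = True) -> np.ndarray:
        src = self.standardized if standardized else self.raw
        return np.array([src[a] for a in AA_ALPHABET], dtype=float)


@dataclass(frozen=True)
class GroupingScheme:
    """Partition of the 20 amino acids into three physicochemical classes."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        joined = "".join(self.groups)
        if len(self.groups) != 3 or sorted(joined) != sorted(AA_ALPHABET):
            raise ValueError(
                f"grouping {self.name!r} must partition the 20 amino acids into 3 classes"
            )

    def class_of(self) -> dict[str, int]:
        return {aa: k for k, grp in enumerate(self.groups) for aa in grp}


# Kyte & Doolittle hydropathy
KD_HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Hopp & Woods hydrophilicity
HYDROPHILICITY = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

# Bhaskaran & Ponnuswamy average flexibility
FLEXIBILITY = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
    "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
    "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
    "Y": 0.420, "V": 0.386,
}

# Grantham polarity
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
    "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
    "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

# Charton & Charton polarizability
POLARIZABILITY = {
    "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128, "Q": 0.180,
    "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186, "L": 0.186, "K": 0.219,
    "M": 0.221, "F": 0.290, "P": 0.131, "S": 0.062, "T": 0.108, "W": 0.409,
    "Y": 0.298, "V": 0.140,
}

# Fauchere et al. normalized van der Waals volume
VDW_VOLUME = {
    "A": 1.00, "R": 6.13, "N": 2.95, "D": 2.78, "C": 2.43, "Q": 3.95, "E": 3.78,
    "G": 0.00, "H": 4.66, "I": 4.00, "L": 4.00, "K": 4.77, "M": 4.43, "F": 5.89,
    "P": 2.72, "S": 1.60, "T": 2.60, "W": 8.08, "Y": 6.47, "V": 3.00,
}

# Charton steric parameter
STERIC = {
    "A": 0.52, "R": 0.68, "N": 0.76, "D": 0.76, "C": 0.62, "Q": 0.68, "E": 0.68,
    "G": 0.00, "H": 0.70, "I": 1.02, "L": 0.98, "K": 0.68, "M": 0.78, "F": 0.70,
    "P": 0.36, "S": 0.53, "T": 0.50, "W": 0.70, "Y": 0.70, "V": 0.76,
}

# Zimmerman isoelectric point
ISOELECTRIC = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.05, "Q": 5.65, "E": 3.22,
    "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74, "M": 5.74, "F": 5.48,
    "P": 6.30, "S": 5.68, "T": 5.66, "W": 5.89, "Y": 5.66, "V": 5.96,
}

DEFAULT_SCALES: tuple[PropertyScale, ...] = (
    PropertyScale("kd_hydrophobicity", KD_HYDROPHOBICITY),
    PropertyScale("hydrophilicity", HYDROPHILICITY),
    PropertyScale("flexibility", FLEXIBILITY),
    PropertyScale("polarity", POLARITY),
    PropertyScale("polarizability", POLARIZABILITY),
    PropertyScale("vdw_volume", VDW_VOLUME),
    PropertyScale("steric", STERIC),
    PropertyScale("isoelectric", ISOELECTRIC),
)

# Standard 3-class partitions used by composition/transition/distribution
# descriptors (Dubchak-style).
DEFAULT_GROUPINGS: tuple[GroupingScheme, ...] = (
    GroupingScheme("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    GroupingScheme("vdw_volume", ("GASTPDC", "NVEQIL", "MHKFRYW")),
    GroupingScheme("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    GroupingScheme("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    GroupingScheme("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    GroupingScheme("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    GroupingScheme("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
)

# Chou-Fasman conformational propensities (helix, sheet, turn-as-coil)
CHOU_FASMAN = {
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}

# Side-chain charge at physiological pH: full charges for K/R/D/E, a
# fractional 0.1 for His (pKa ~6).
CHARGE = {aa: 0.0 for aa in AA_ALPHABET}
CHARGE.update({"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0})

# FoldIndex-style per-residue net charge (His treated as neutral)
FOLDINDEX_CHARGE = {aa: 0.0 for aa in AA_ALPHABET}
FOLDINDEX_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})


def scale_by_name(name: str) -> PropertyScale:
    for s in DEFAULT_SCALES:
        if s.name == name:
            return s
    raise KeyError(f"unknown property scale: {name!r}")


def grouping_by_name(name: str) -> GroupingScheme:
    for g in DEFAULT_GROUPINGS:
        if g.name == name:
            return g
    raise KeyError(f"unknown grouping scheme: {name!r}")
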