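"""Amino-acid property scales and the elementary substitution-change features.

The tables are embedded constants:

* residue volumes (Richards 1974), cubic angstroms;
* side-chain transfer free energies (Engelman-Steitz-Goldman 1986), kcal/mol,
  positive values favouring the membrane interior;
* charge classes at physiological pH (K, R positive; D, E negative; His neutral);
* BLOSUM62, loaded from Biopython's substitution-matrix collection.

Volume changes are reported as V(ref) - V(alt), so a *negative* change means a
larger residue was introduced; the four-bin partition of that change has edges
at -42, 0 and +42 A^3 with left-open/right-closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Align import substitution_matrices

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Richards (1974) residue volumes, A^3.
RICHARDS_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Engelman-Steitz-Goldman (1986) transfer free energies, kcal/mol.
GES_HYDROPHOBICITY = {
    "F": 3.7, "M": 3.4, "I": 3.1, "L": 2.8, "V": 2.6,
    "C": 2.0, "W": 1.9, "A": 1.6, "T": 1.2, "G": 1.0,
    "S": 0.6, "P": -0.2, "Y": -0.7, "H": -3.0, "Q": -4.1,
    "N": -4.8, "E": -8.2, "K": -8.8, "D": -9.2, "R": -12.3,
}

POSITIVE_AA = frozenset("KR")
NEGATIVE_AA = frozenset("DE")

# dG >= 1.0 kcal/mol: the ten classically apolar residues (Gly in, Ser out).
HYDROPHOBIC_THRESHOLD = 1.0
HYDROPHOBIC_AA = frozenset(
    aa for aa, dg in GES_HYDROPHOBICITY.items() if dg >= HYDROPHOBIC_THRESHOLD
)


class VolumeBin(str, Enum):
    """Four-bin partition of the substitution volume change (A^3)."""

    LT_MINUS42 = "lt_minus42"
    MINUS42_TO_0 = "minus42_to_0"
    ZERO_TO_42 = "zero_to_42"
    GT_42 = "gt_42"


class ChargeTransition(str, Enum):
    GAIN_POSITIVE = "gain_positive"
    LOSS_POSITIVE = "loss_positive"
    NONE = "none"


def _load_blosum62() -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load("BLOSUM62")
    return {
        (a, b): int(mat[a, b]) for a in STANDARD_AA for b in STANDARD_AA
    }


@dataclass(frozen=True)
class AminoAcidScales:
    """Bundle of the embedded property tables used for featurization."""

    volume: dict[str, float] = field(default_factory=lambda: dict(RICHARDS_VOLUME))
    hydrophobicity: dict[str, float] = field(
        default_factory=lambda: dict(GES_HYDROPHOBICITY)
    )
    positive: frozenset[str] = POSITIVE_AA
    negative: frozenset[str] = NEGATIVE_AA
    hydrophobic: frozenset[str] = HYDROPHOBIC_AA
    blosum62: dict[tuple[str, str], int] = field(default_factory=_load_blosum62)

    def charge_class(self, aa: str) -> str:
        _check_aa(aa)
        if aa in self.positive:
            return "positive"
        if aa in self.negative:
            return "negative"
        return "neutral"


def default_scales() -> AminoAcidScales:
    return AminoAcidScales()


def _check_aa(aa: str) -> None:
    if aa not in STANDARD_AA:
        raise ValueError(f"unknown amino acid {aa!r}")


def volume_change(ref_aa: str, alt_aa: str, scales: AminoAcidScales | None = None) -> float:
    """V(ref) - V(alt) in A^3; negative when a larger residue is introduced."""
    scales = scales or default_scales()
    _check_aa(ref_aa)
    _check_aa(alt_aa)
    return scales.volume[ref_aa] - scales.volume[alt_aa]


def volume_bin(delta: float) -> VolumeBin:
    """Map a volume change onto the four-bin partition (edges -42, 0, +42)."""
    if delta <= -42.0:
        return VolumeBin.LT_MINUS42
    if delta <= 0.0:
        return VolumeBin.MINUS42_TO_0
    if delta <= 42.0:
        return VolumeBin.ZERO_TO_42
    return VolumeBin.GT_42


def charge_transition(
    ref_aa: str, alt_aa: str, scales: AminoAcidScales | None = None
) -> ChargeTransition:
    scales = scales or default_scales()
    _check_aa(ref_aa)
    _check_aa(alt_aa)
    ref_pos = ref_aa in scales.positive
    alt_pos = alt_aa in scales.positive
    if not ref_pos and alt_pos:
        return ChargeTransition.GAIN_POSITIVE
    if ref_pos and not alt_pos:
        return ChargeTransition.LOSS_POSITIVE
    return ChargeTransition.NONE


def hydrophobic_loss(
    ref_aa: str, alt_aa: str, scales: AminoAcidScales | None = None
) -> bool:
    """True when a hydrophobic residue is replaced by a non-hydrophobic one."""
    scales = scales or default_scales()
    _check_aa(ref_aa)
    _check_aa(alt_aa)
    return ref_aa in scales.hydrophobic and alt_aa not in scales.hydrophobic
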