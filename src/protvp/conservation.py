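"""Position-specific conservation from a multiple sequence alignment.

A column's score is the inner product of its gap-excluded residue frequencies
with the BLOSUM62 row of the reference residue, i.e. the expected substitution
score of the observed column against the reference.  Scores are then ranked
(descending: high self-substitution score = conserved) and cut into ten
equal-frequency bins; decile 1 is the most conserved tenth and a residue
counts as conserved when its decile is <= 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aa_scales import STANDARD_AA, AminoAcidScales, default_scales

CONSERVED_MAX_DECILE = 5
LOW_COVERAGE_FRACTION = 0.5


@dataclass
class MSA:
    """Aligned, equal-length rows; the first row is the reference by default."""

    names: list[str]
    rows: list[str]
    reference_row: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if not self.reference_row:
            self.reference_row = self.names[0]
        if self.reference_row not in self.names:
            raise ValueError(f"reference row {self.reference_row!r} not in alignment")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> str:
        return self.rows[self.names.index(self.reference_row)]

    def reference_position_to_column(self) -> dict[int, int]:
        """Map ungapped reference position (1-based) -> alignment column (0-based)."""
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.reference):
            if ch != "-":
                pos += 1
                mapping[pos] = col
        return mapping

    def reference_sequence(self) -> str:
        return self.reference.replace("-", "")


@dataclass
class ConservationProfile:
    """Per reference-position raw score and conservation decile (1 = most conserved)."""

    raw_score: dict[int, float]
    decile: dict[int, int]
    low_confidence: set[int] = field(default_factory=set)

    def is_conserved(self, position: int) -> bool:
        return is_conserved(self.decile[position])


def column_frequencies(msa: MSA, column: int) -> dict[str, float]:
    """Residue proportions in one column, gaps excluded."""
    if not 0 <= column < msa.column_count:
        raise IndexError(f"column {column} out of range")
    counts: dict[str, int] = {}
    for row in msa.rows:
        ch = row[column].upper()
        if ch == "-":
            continue
        counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {aa: c / total for aa, c in counts.items()}


def position_score(
    msa: MSA, position: int, scales: AminoAcidScales | None = None
) -> float:
    """Frequency-weighted BLOSUM62 score of a column against the reference residue."""
    scales = scales or default_scales()
    mapping = msa.reference_position_to_column()
    if position not in mapping:
        raise ValueError(f"position {position} is not an ungapped reference position")
    col = mapping[position]
    ref_aa = msa.reference[col].upper()
    if ref_aa not in STANDARD_AA:
        raise ValueError(f"non-standard reference residue {ref_aa!r} at {position}")
    freqs = column_frequencies(msa, col)
    return sum(
        f * scales.blosum62[(ref_aa, aa)] for aa, f in freqs.items() if aa in STANDARD_AA
    )


def conservation_decile(profile_scores: dict[int, float]) -> dict[int, int]:
    """Equal-frequency decile per position; 1 = most conserved (highest score).

    Ties are broken by ascending position index so that the assignment is
    deterministic; bin sizes differ by at most one.
    """
    if len(profile_scores) < 10:
        raise ValueError("need at least 10 scored positions for deciles")
    positions = sorted(profile_scores)
    order = sorted(positions, key=lambda p: (-profile_scores[p], p))
    n = len(order)
    edges = np.linspace(0, n, 11).round().astype(int)
    deciles: dict[int, int] = {}
    for d in range(10):
        for p in order[edges[d] : edges[d + 1]]:
            deciles[p] = d + 1
    return deciles


def is_conserved(decile: int) -> bool:
    if not 1 <= decile <= 10:
        raise ValueError(f"decile {decile} outside [1, 10]")
    return decile <= CONSERVED_MAX_DECILE


def build_profile(msa: MSA, scales: AminoAcidScales | None = None) -> ConservationProfile:
    """Score every ungapped reference position and assign deciles."""
    scales = scales or default_scales()
    mapping = msa.reference_position_to_column()
    scores: dict[int, float] = {}
    low: set[int] = set()
    n_rows = len(msa.rows)
    for pos, col in mapping.items():
        scores[pos] = position_score(msa, pos, scales)
        non_gap = sum(1 for row in msa.rows if row[col] != "-")
        if non_gap / n_rows < LOW_COVERAGE_FRACTION:
            low.add(pos)
    return ConservationProfile(
        raw_score=scores, decile=conservation_decile(scores), low_confidence=low
    )
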