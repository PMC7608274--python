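"""Assembly of the eight pathogenicity-criteria features per variant.

The criteria, as a feature vector:

  f1  variant lies in a modelled region (binary)
  f2  loss of a positive charge inside an S4 voltage-sensor segment (binary)
  f3  gain of a positive charge anywhere (binary)
  f4  loss of a hydrophobic residue inside domain I (binary)
  f5  conservation decile of the position, 1-10 (1 = most conserved)
  f6  position in the intracellular (lower) half of domain I (binary)
  f7  volume-change bin of the substitution (4 levels)
  f8  clash score: ingested contact score when provided and selected,
      else the internal sphere-overlap proxy (real, <= 0; missing when f1 = 0)

Structural features (f6, f8) are missing for unmodelled positions; rows are
never dropped for missingness since f1 itself is a feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aa_scales import (
    AminoAcidScales,
    ChargeTransition,
    VolumeBin,
    charge_transition,
    default_scales,
    hydrophobic_loss,
    volume_bin,
    volume_change,
)
from .conservation import ConservationProfile
from .io_formats import TopologyAnnotation, VariantRecord
from .structure_features import (
    ClashEnvironment,
    ProteinModel,
    Side,
    clash_score,
    in_modelled_region,
    sidedness,
)

FEATURE_COLUMNS = ["f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8"]

DOMAIN_I = "I"
S4_SEGMENT = "S4"


class ReferenceMismatchError(ValueError):
    """Variant reference residue disagrees with the model/alignment reference."""


@dataclass
class FeatureVector:
    f1_modelled: int
    f2_s4_loss_positive: int
    f3_gain_positive: int
    f4_domainI_hydrophobic_loss: int
    f5_conservation_decile: int | None
    f6_domainI_intracellular: int | None
    f7_volume_bin: VolumeBin
    f8_clash_score: float | None
    clash_source: str = "internal"

    def as_row(self) -> dict:
        return {
            "f1": self.f1_modelled,
            "f2": self.f2_s4_loss_positive,
            "f3": self.f3_gain_positive,
            "f4": self.f4_domainI_hydrophobic_loss,
            "f5": self.f5_conservation_decile,
            "f6": self.f6_domainI_intracellular,
            "f7": self.f7_volume_bin.value,
            "f8": self.f8_clash_score,
            "clash_source": self.clash_source,
        }


def _in_interval(position: int, interval: tuple[int, int]) -> bool:
    lo, hi = interval
    return lo <= position <= hi


def _in_any_s4(topology: TopologyAnnotation, position: int) -> bool:
    return any(_in_interval(position, iv) for iv in topology.segments_named(S4_SEGMENT))


def featurize_variant(
    variant: VariantRecord,
    model: ProteinModel,
    topology: TopologyAnnotation,
    profile: ConservationProfile,
    scales: AminoAcidScales | None = None,
    reference_sequence: dict[int, str] | None = None,
    use_ingested_clash: bool = False,
    clash_environment: ClashEnvironment | None = None,
) -> FeatureVector:
    """Compute the eight criteria for one variant.

    ``reference_sequence`` maps position -> reference amino acid for the whole
    protein (including unmodelled positions); when absent the model's own
    sequence is used for modelled positions.  A mismatch between the variant's
    ref_aa and the reference is a hard error, never a silent renumbering.
    """
    scales = scales or default_scales()
    pos = variant.position

    expected = None
    if reference_sequence is not None:
        expected = reference_sequence.get(pos)
    else:
        res = model.residue(pos)
        expected = res.aa if res is not None else None
    if expected is not None and expected != variant.ref_aa:
        raise ReferenceMismatchError(
            f"position {pos}: variant reference {variant.ref_aa} does not match "
            f"protein reference {expected}"
        )

    modelled = in_modelled_region(topology, pos)
    transition = charge_transition(variant.ref_aa, variant.alt_aa, scales)
    in_domain_i = DOMAIN_I in topology.domain_ranges and _in_interval(
        pos, topology.domain_ranges[DOMAIN_I]
    )

    f2 = int(transition is ChargeTransition.LOSS_POSITIVE and _in_any_s4(topology, pos))
    f3 = int(transition is ChargeTransition.GAIN_POSITIVE)
    f4 = int(hydrophobic_loss(variant.ref_aa, variant.alt_aa, scales) and in_domain_i)
    f5 = profile.decile.get(pos)
    f7 = volume_bin(volume_change(variant.ref_aa, variant.alt_aa, scales))

    f6: int | None = None
    f8: float | None = None
    source = "internal"
    if modelled:
        side = sidedness(model, topology, pos)
        f6 = int(in_domain_i and side.side is Side.INTRACELLULAR)
        if use_ingested_clash and "probe" in variant.external_scores:
            f8 = variant.external_scores["probe"]
            source = "probe"
        else:
            f8 = clash_score(
                model, pos, variant.alt_aa, environment=clash_environment
            ).score

    return FeatureVector(
        f1_modelled=int(modelled),
        f2_s4_loss_positive=f2,
        f3_gain_positive=f3,
        f4_domainI_hydrophobic_loss=f4,
        f5_conservation_decile=f5,
        f6_domainI_intracellular=f6,
        f7_volume_bin=f7,
        f8_clash_score=f8,
        clash_source=source,
    )


def featurize_cohort(
    variants: list[VariantRecord],
    model: ProteinModel,
    topology: TopologyAnnotation,
    profile: ConservationProfile,
    scales: AminoAcidScales | None = None,
    reference_sequence: dict[int, str] | None = None,
    use_ingested_clash: bool = False,
) -> pd.DataFrame:
    """One row per variant, columns f1..f8 + label (+ hgvs_p, clash_source)."""
    if not variants:
        raise ValueError("empty variant list")
    scales = scales or default_scales()
    env = ClashEnvironment(model)
    rows = []
    for i, v in enumerate(variants):
        try:
            fv = featurize_variant(
                v, model, topology, profile, scales,
                reference_sequence=reference_sequence,
                use_ingested_clash=use_ingested_clash,
                clash_environment=env,
            )
        except Exception as exc:
            raise type(exc)(f"row {i} ({v.hgvs_p}): {exc}") from exc
        row = {"hgvs_p": v.hgvs_p, **fv.as_row(), "label": v.label}
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["hgvs_p", *FEATURE_COLUMNS, "label", "clash_source"]]
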