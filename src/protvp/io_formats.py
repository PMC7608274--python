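"""Readers/writers for the formats the pipeline touches, plus HGVS p. parsing.

Formats: PDB structures (via gemmi, first chain, ATOM records), aligned FASTA
alignments (via Biopython), TSV variant tables (hgvs_p column or ref/pos/alt
columns, optional label and free score columns) and TSV topology tables
(kind/id/start/end rows describing modelled ranges, CTD, domains I-IV,
segments S1-S6 and the intracellular reference residue).

Residue numbering convention: author numbering in the PDB and 1-based protein
numbering in variant tables; agreement is enforced downstream by a reference
amino-acid check at featurization time.  All intervals are inclusive on both
ends.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import pandas as pd
from Bio import SeqIO

from .aa_scales import ONE_TO_THREE, STANDARD_AA, THREE_TO_ONE
from .conservation import MSA
from .structure_features import VDW_RADII, Atom, ProteinModel, Residue

Interval = tuple[int, int]

_HGVS_RE = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})\)?$")

_LABELS = {"D", "N", "unknown"}


class FormatError(ValueError):
    """Malformed input file or notation."""


@dataclass
class VariantRecord:
    """One missense change in protein numbering with optional external scores."""

    ref_aa: str
    position: int
    alt_aa: str
    label: str = "unknown"
    external_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_aa not in STANDARD_AA or self.alt_aa not in STANDARD_AA:
            raise ValueError(
                f"non-standard amino acid in {self.ref_aa}{self.position}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"not missense: {self.ref_aa}{self.position}{self.alt_aa}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {sorted(_LABELS)}, got {self.label!r}")

    @property
    def hgvs_p(self) -> str:
        return format_protein_hgvs(self.ref_aa, self.position, self.alt_aa)

    def key(self) -> tuple[str, int, str]:
        return (self.ref_aa, self.position, self.alt_aa)


@dataclass
class TopologyAnnotation:
    """Modelled ranges, CTD, domain/segment intervals and the reference residue."""

    modelled_ranges: list[Interval]
    ctd_range: Interval
    domain_ranges: dict[str, Interval]
    segment_ranges: dict[tuple[str, str], Interval]
    reference_residue: int
    sequence_length: int

    def __post_init__(self) -> None:
        self.modelled_ranges = sorted(tuple(r) for r in self.modelled_ranges)
        for lo, hi in [*self.modelled_ranges, self.ctd_range, *self.domain_ranges.values(),
                       *self.segment_ranges.values()]:
            if not (1 <= lo <= hi <= self.sequence_length):
                raise ValueError(f"interval {lo}-{hi} outside [1, {self.sequence_length}]")
        for (lo, hi), (lo2, hi2) in zip(self.modelled_ranges, self.modelled_ranges[1:]):
            if hi >= lo2:
                raise ValueError(f"modelled ranges {lo}-{hi} and {lo2}-{hi2} overlap")
        for (dom, seg), (lo, hi) in self.segment_ranges.items():
            if dom not in self.domain_ranges:
                raise ValueError(f"segment {seg} references unknown domain {dom}")
            dlo, dhi = self.domain_ranges[dom]
            if not (dlo <= lo and hi <= dhi):
                raise ValueError(
                    f"segment {dom}/{seg} ({lo}-{hi}) outside domain {dom} ({dlo}-{dhi})"
                )
        if not any(lo <= self.reference_residue <= hi for lo, hi in self.modelled_ranges):
            raise ValueError(
                f"reference residue {self.reference_residue} not in a modelled range"
            )

    def segments_named(self, segment_id: str) -> list[Interval]:
        return [iv for (_, seg), iv in self.segment_ranges.items() if seg == segment_id]


# ---------------------------------------------------------------------------
# HGVS protein notation


def parse_protein_hgvs(text: str) -> tuple[str, int, str]:
    """Parse ``p.(Leu216Arg)`` / ``p.Leu216Arg`` into (ref, position, alt)."""
    m = _HGVS_RE.match(text.strip())
    if m is None:
        raise FormatError(f"malformed HGVS protein notation: {text!r}")
    ref3, pos, alt3 = m.groups()
    if ref3 not in THREE_TO_ONE or alt3 not in THREE_TO_ONE:
        raise FormatError(f"unknown amino-acid code in {text!r}")
    ref, alt = THREE_TO_ONE[ref3], THREE_TO_ONE[alt3]
    if ref == alt:
        raise FormatError(f"not missense: {text!r}")
    return ref, int(pos), alt


def format_protein_hgvs(ref_aa: str, position: int, alt_aa: str) -> str:
    return f"p.({ONE_TO_THREE[ref_aa]}{position}{ONE_TO_THREE[alt_aa]})"


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a TSV of variants (hgvs_p column, or ref/pos/alt columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if "hgvs_p" in cols:
        parsed = [parse_protein_hgvs(t) for t in df["hgvs_p"]]
    elif {"ref", "pos", "alt"} <= cols:
        parsed = [(r, int(p), a) for r, p, a in zip(df["ref"], df["pos"], df["alt"])]
    else:
        raise FormatError(
            f"{path}: need an 'hgvs_p' column or 'ref'/'pos'/'alt' columns"
        )
    meta = {"hgvs_p", "ref", "pos", "alt", "label"}
    score_cols = [c for c in df.columns if c not in meta]
    records: list[VariantRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for i, (ref, pos, alt) in enumerate(parsed):
        label = "unknown"
        if "label" in cols and pd.notna(df["label"].iloc[i]):
            label = str(df["label"].iloc[i])
        scores: dict[str, float] = {}
        for c in score_cols:
            raw = df[c].iloc[i]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            # tolerate unicode minus as printed in some tables
            scores[c] = float(str(raw).replace("−", "-"))
        rec = VariantRecord(ref, pos, alt, label, scores)
        if rec.key() in seen:
            warnings.warn(f"duplicate variant row {rec.hgvs_p}; kept", stacklevel=2)
        seen.add(rec.key())
        records.append(rec)
    return records


def write_variant_table(records: list[VariantRecord], path: str | Path) -> None:
    score_cols: list[str] = []
    for r in records:
        for c in r.external_scores:
            if c not in score_cols:
                score_cols.append(c)
    rows = []
    for r in records:
        row = {
            "hgvs_p": r.hgvs_p,
            "ref": r.ref_aa,
            "pos": r.position,
            "alt": r.alt_aa,
            "label": r.label,
        }
        for c in score_cols:
            row[c] = r.external_scores.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structures


def read_structure(path: str | Path) -> ProteinModel:
    """Read a single-chain PDB into a ProteinModel.

    First chain taken when several are present; alternate locations resolved
    to the highest-occupancy conformer; non-standard residues skipped with a
    warning; hydrogens kept if present.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0 or len(structure[0]) == 0:
        raise FormatError(f"{path}: no ATOM records")
    chain = structure[0][0]
    residues: list[Residue] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        one = THREE_TO_ONE.get(res.name.capitalize())
        if one is None or info is None or not info.is_amino_acid():
            warnings.warn(f"skipping non-standard residue {res.name} {res.seqid.num}",
                          stacklevel=2)
            continue
        # resolve alternate locations to the highest-occupancy conformer
        best: dict[str, gemmi.Atom] = {}
        order: list[str] = []
        for a in res:
            if a.name not in best:
                best[a.name] = a
                order.append(a.name)
            elif a.occ > best[a.name].occ:
                best[a.name] = a
        atoms = [
            Atom(
                best[n].name,
                best[n].element.name,
                (best[n].pos.x, best[n].pos.y, best[n].pos.z),
                VDW_RADII.get(best[n].element.name, 1.70),
            )
            for n in order
        ]
        if atoms:
            residues.append(Residue(res.seqid.num, one, atoms))
    if not residues:
        raise FormatError(f"{path}: no standard amino-acid residues")
    return ProteinModel(residues, chain_id=chain.name)


def write_structure(model: ProteinModel, path: str | Path) -> None:
    """Write a ProteinModel as a minimal PDB file (fixed-width ATOM records)."""
    lines = []
    serial = 0
    for res in model.residues:
        res3 = ONE_TO_THREE[res.aa].upper()
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.xyz
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res3} {model.chain_id:1s}"
                f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# alignments


def read_alignment(path: str | Path, reference_row: str | None = None) -> MSA:
    """Read an aligned FASTA; the first row is the reference unless named."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"{path}: rows of unequal length {sorted(lengths)}")
    names = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return MSA(names=names, rows=rows, reference_row=reference_row or names[0])


def write_alignment(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# topology tables


def read_topology(path: str | Path, sequence_length: int | None = None) -> TopologyAnnotation:
    """Read a TSV topology table (columns: kind, id, start, end).

    ``kind`` is one of modelled | ctd | domain | segment | reference | length.
    Segment ids are written ``I:S4`` (domain:segment).  ``sequence_length``
    may be given as a ``length`` row or as an argument.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"kind", "id", "start", "end"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: topology table needs columns {sorted(required)}")
    modelled: list[Interval] = []
    ctd: Interval | None = None
    domains: dict[str, Interval] = {}
    segments: dict[tuple[str, str], Interval] = {}
    reference: int | None = None
    for _, row in df.iterrows():
        kind = row["kind"].strip().lower()
        if kind == "length":
            sequence_length = int(row["start"])
            continue
        if kind == "reference":
            reference = int(row["start"])
            continue
        lo, hi = int(row["start"]), int(row["end"])
        if kind == "modelled":
            modelled.append((lo, hi))
        elif kind == "ctd":
            ctd = (lo, hi)
        elif kind == "domain":
            domains[row["id"].strip()] = (lo, hi)
        elif kind == "segment":
            dom, _, seg = row["id"].strip().partition(":")
            if not seg:
                raise FormatError(f"{path}: segment id must be 'domain:segment'")
            segments[(dom, seg)] = (lo, hi)
        else:
            raise FormatError(f"{path}: unknown topology kind {kind!r}")
    if ctd is None or reference is None or not modelled:
        raise FormatError(f"{path}: topology needs modelled, ctd and reference rows")
    if sequence_length is None:
        sequence_length = max(hi for _, hi in [*modelled, ctd, *domains.values()])
    return TopologyAnnotation(
        modelled_ranges=modelled,
        ctd_range=ctd,
        domain_ranges=domains,
        segment_ranges=segments,
        reference_residue=reference,
        sequence_length=sequence_length,
    )


def write_topology(topology: TopologyAnnotation, path: str | Path) -> None:
    rows = [("length", "", topology.sequence_length, topology.sequence_length)]
    rows += [("modelled", "", lo, hi) for lo, hi in topology.modelled_ranges]
    rows.append(("ctd", "", *topology.ctd_range))
    rows += [("domain", d, lo, hi) for d, (lo, hi) in topology.domain_ranges.items()]
    rows += [
        ("segment", f"{d}:{s}", lo, hi)
        for (d, s), (lo, hi) in topology.segment_ranges.items()
    ]
    rows.append(("reference", "", topology.reference_residue, topology.reference_residue))
    pd.DataFrame(rows, columns=["kind", "id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
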