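"""Desk-scale synthetic structures, alignments and variant cohorts.

The generators emulate the statistical shape of a membrane-channel variant
study without any external data:

* ``make_helix_bundle`` — ideal alpha-helices (backbone N, CA, C, O plus CB)
  stood on a circle with the long axis along z, assigned cyclically to
  domains I-IV and segments S1-S6; the membrane plane is z = 0 and the
  reference (intracellular anchor) residue is the one with the lowest CA.
  Unmodelled linkers/termini and a C-terminal domain give the topology the
  features the pipeline discriminates on.
* ``make_msa`` — rows mutated from the reference at per-position rates, near
  zero inside designated conserved blocks and high elsewhere.
* ``make_cohorts`` — disease (D) and benign (N) cohorts drawn from the full
  single-substitution universe with a planted log-odds score over the eight
  criteria; the Bayes-optimal AUC of the generating mixture is computed
  exactly by summation over the universe, and the score scale is calibrated
  by bisection so that this AUC equals the requested target.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aa_scales import STANDARD_AA, default_scales
from .conservation import MSA, ConservationProfile, build_profile
from .feature_assembly import FEATURE_COLUMNS, featurize_cohort
from .io_formats import TopologyAnnotation, VariantRecord
from .structure_features import Atom, ProteinModel, Residue, VDW_RADII, nerf_place

_DOMAINS = ("I", "II", "III", "IV")
_SEGMENTS = ("S1", "S2", "S3", "S4", "S5", "S6")

# residue alphabet used for fixture sequences (varied but uncontroversial)
_FIXTURE_AAS = "LIVFAMTSGWYNQKRDEH"


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic fixture.

    Defaults model a small polytopic membrane protein: eight 24-residue
    transmembrane helices (domain I complete, S1-S2 of domain II), 4-residue
    unmodelled linkers, an unmodelled C-terminal domain, a 24-row alignment
    and cohorts of 70 disease / 320 benign variants with a planted
    Bayes-optimal AUC of 0.90.
    """

    n_helices: int = 8
    helix_length: int = 24
    rise_per_residue: float = 1.5
    twist_deg: float = 100.0
    bundle_radius: float = 11.0
    linker_length: int = 4
    nterm_unmodelled: int = 8
    ctd_length: int = 30
    msa_rows: int = 24
    conserved_mutation_rate: float = 0.02
    background_mutation_rate: float = 0.5
    n_disease: int = 70
    n_benign: int = 320
    target_auc: float = 0.90
    effect_logodds: dict[str, float] = field(
        default_factory=lambda: {
            "f1": 1.6,   # modelled-region enrichment of disease variants
            "f2": 1.0,   # S4 loss of positive charge
            "f3": 1.0,   # gain of positive charge
            "f4": 0.6,   # hydrophobic loss in domain I
            "conserved": 1.6,  # decile <= 5
            "f6": 0.5,   # intracellular half of domain I
            "f7_lt_minus42": 0.8,  # larger residue introduced
            "clash": 1.2,  # scaled overlap penalty
        }
    )
    seed: int = 0


def _helix_phi_psi() -> tuple[float, float, float]:
    return -57.0, -47.0, 180.0


def _build_helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone (N, CA, C, O) built by NeRF from phi/psi."""
    phi, psi, omega = _helix_phi_psi()
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = nerf_place(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.2, -60.0)
    residues.append({"N": n, "CA": ca, "C": c})
    for i in range(1, n_res):
        prev = residues[-1]
        n_new = nerf_place(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        ca_new = nerf_place(prev["CA"], prev["C"], n_new, 1.458, 121.7, omega)
        c_new = nerf_place(prev["C"], n_new, ca_new, 1.525, 111.2, phi)
        residues.append({"N": n_new, "CA": ca_new, "C": c_new})
    for i, res in enumerate(residues):
        nxt = residues[i + 1]["N"] if i + 1 < n_res else None
        if nxt is None:
            ref = res["N"]
            res["O"] = nerf_place(ref, res["CA"], res["C"], 1.231, 120.5, 135.0)
        else:
            res["O"] = nerf_place(nxt, res["CA"], res["C"], 1.231, 120.5, 180.0)
    return residues


def _align_to_z(residues: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
    """Rotate so the helix axis (first PC of CA coords) lies along +z."""
    cas = np.array([r["CA"] for r in residues])
    centre = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centre)
    axis = vt[0]
    if axis[2] < 0 or (axis[2] == 0 and (cas[-1] - cas[0]) @ axis < 0):
        axis = -axis
    if (cas[-1] - cas[0]) @ axis < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, cth = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)
    out = []
    for r in residues:
        out.append({k: rot @ (p - centre) for k, p in r.items()})
    return out


def make_helix_bundle(spec: FixtureSpec | None = None) -> tuple[ProteinModel, TopologyAnnotation, dict[int, str]]:
    """Build the bundle, its topology and the full reference sequence.

    Returns ``(model, topology, reference_sequence)`` where the sequence also
    covers the unmodelled linkers, N-terminus and CTD.
    """
    spec = spec or FixtureSpec()
    if spec.n_helices < 2:
        raise ValueError("need at least two helices")
    rng = np.random.default_rng(spec.seed)

    template = _align_to_z(_build_helix_backbone(spec.helix_length))
    span = max(r["CA"][2] for r in template) - min(r["CA"][2] for r in template)
    if spec.bundle_radius <= 0 or span <= 0:
        raise ValueError("geometrically impossible fixture spec")

    residues: list[Residue] = []
    modelled: list[tuple[int, int]] = []
    segment_ranges: dict[tuple[str, str], tuple[int, int]] = {}
    sequence: dict[int, str] = {}

    pos = 0
    for _ in range(spec.nterm_unmodelled):
        pos += 1
        sequence[pos] = _FIXTURE_AAS[rng.integers(len(_FIXTURE_AAS))]

    for h in range(spec.n_helices):
        theta = 2 * math.pi * h / spec.n_helices
        offset = np.array(
            [spec.bundle_radius * math.cos(theta), spec.bundle_radius * math.sin(theta), 0.0]
        )
        flip = h % 2 == 1  # antiparallel bundle
        start = pos + 1
        for i in range(spec.helix_length):
            pos += 1
            aa = _FIXTURE_AAS[rng.integers(len(_FIXTURE_AAS))]
            sequence[pos] = aa
            coords = template[i]
            atoms = []
            for name in ("N", "CA", "C", "O"):
                p = coords[name].copy()
                if flip:
                    p = np.array([p[0], -p[1], -p[2]])
                p = p + offset
                atoms.append(
                    Atom(name, name[0], tuple(float(v) for v in p), VDW_RADII[name[0]])
                )
            residues.append(Residue(pos, aa, atoms))
        end = pos
        modelled.append((start, end))
        dom = _DOMAINS[h // len(_SEGMENTS)]
        seg = _SEGMENTS[h % len(_SEGMENTS)]
        segment_ranges[(dom, seg)] = (start, end)
        for _ in range(spec.linker_length):
            pos += 1
            sequence[pos] = _FIXTURE_AAS[rng.integers(len(_FIXTURE_AAS))]

    ctd_start = pos + 1
    for _ in range(spec.ctd_length):
        pos += 1
        sequence[pos] = _FIXTURE_AAS[rng.integers(len(_FIXTURE_AAS))]
    sequence_length = pos

    model = ProteinModel(residues)
    # add CB to every residue so clash scoring has a non-trivial environment
    model = _with_cb(model)

    domain_ranges: dict[str, tuple[int, int]] = {}
    for (dom, _), (lo, hi) in segment_ranges.items():
        if dom in domain_ranges:
            dlo, dhi = domain_ranges[dom]
            domain_ranges[dom] = (min(dlo, lo), max(dhi, hi))
        else:
            domain_ranges[dom] = (lo, hi)

    ca_z = {r.index: r.atom("CA").xyz[2] for r in model.residues}
    reference_residue = min(ca_z, key=ca_z.get)

    topology = TopologyAnnotation(
        modelled_ranges=modelled,
        ctd_range=(ctd_start, sequence_length),
        domain_ranges=domain_ranges,
        segment_ranges=segment_ranges,
        reference_residue=reference_residue,
        sequence_length=sequence_length,
    )
    return model, topology, sequence


def _with_cb(model: ProteinModel) -> ProteinModel:
    from .structure_features import place_sidechain

    new_residues = []
    for r in model.residues:
        atoms = list(r.atoms)
        if r.aa != "G" and r.atom("CB") is None:
            cb = place_sidechain(model, r.index, "A", 0)
            atoms.extend(cb)
        new_residues.append(Residue(r.index, r.aa, atoms))
    return ProteinModel(new_residues, chain_id=model.chain_id)


def make_msa(
    reference_sequence: dict[int, str],
    spec: FixtureSpec | None = None,
    conserved_blocks: list[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> MSA:
    """Mutate the reference into ``msa_rows`` orthologue-like rows.

    Positions inside ``conserved_blocks`` mutate at the conserved rate
    (default ~0), all others at the background rate.
    """
    spec = spec or FixtureSpec()
    if spec.msa_rows < 2:
        raise ValueError("need at least two alignment rows")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    positions = sorted(reference_sequence)
    ref_row = "".join(reference_sequence[p] for p in positions)
    conserved_blocks = conserved_blocks or []

    def rate(p: int) -> float:
        in_block = any(lo <= p <= hi for lo, hi in conserved_blocks)
        return spec.conserved_mutation_rate if in_block else spec.background_mutation_rate

    names = ["reference"] + [f"ortholog_{i}" for i in range(1, spec.msa_rows)]
    rows = [ref_row]
    for _ in range(1, spec.msa_rows):
        chars = []
        for p in positions:
            if rng.random() < rate(p):
                choices = [aa for aa in STANDARD_AA if aa != reference_sequence[p]]
                chars.append(choices[rng.integers(19)])
            else:
                chars.append(reference_sequence[p])
        rows.append("".join(chars))
    return MSA(names=names, rows=rows, reference_row="reference")


# ---------------------------------------------------------------------------
# cohort generation with planted effects


def _universe(reference_sequence: dict[int, str]) -> list[VariantRecord]:
    out = []
    for pos in sorted(reference_sequence):
        ref = reference_sequence[pos]
        if ref not in STANDARD_AA:
            continue
        for alt in STANDARD_AA:
            if alt != ref:
                out.append(VariantRecord(ref, pos, alt, label="unknown"))
    return out


def _planted_score(features: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    """Linear log-odds score of the planted effects over the criteria table."""
    s = np.zeros(len(features))
    s += effects.get("f1", 0.0) * features["f1"].to_numpy(float)
    s += effects.get("f2", 0.0) * features["f2"].to_numpy(float)
    s += effects.get("f3", 0.0) * features["f3"].to_numpy(float)
    s += effects.get("f4", 0.0) * features["f4"].to_numpy(float)
    decile = features["f5"].to_numpy(float)
    s += effects.get("conserved", 0.0) * (decile <= 5).astype(float)
    f6 = features["f6"].to_numpy(float)
    s += effects.get("f6", 0.0) * np.nan_to_num(f6)
    s += effects.get("f7_lt_minus42", 0.0) * (
        features["f7"].to_numpy() == "lt_minus42"
    ).astype(float)
    clash = np.nan_to_num(features["f8"].to_numpy(float))  # <= 0, missing -> 0
    s += effects.get("clash", 0.0) * np.minimum(1.0, -clash / 2.0)
    return s


def _mixture_auc(score: np.ndarray, w_d: np.ndarray, w_n: np.ndarray) -> float:
    """Exact AUC between the D and N sampling distributions over the universe."""
    order = np.argsort(score, kind="stable")
    s, wd, wn = score[order], w_d[order], w_n[order]
    wd = wd / wd.sum()
    wn = wn / wn.sum()
    # group tied scores
    boundaries = np.r_[np.where(np.diff(s) != 0)[0] + 1, len(s)]
    start = 0
    cum_n = 0.0
    auc = 0.0
    for b in boundaries:
        pd_mass = wd[start:b].sum()
        pn_mass = wn[start:b].sum()
        auc += pd_mass * (cum_n + 0.5 * pn_mass)
        cum_n += pn_mass
        start = b
    return float(auc)


def _sampling_weights(score: np.ndarray, scale: float) -> tuple[np.ndarray, np.ndarray]:
    centred = score - score.mean()
    p = 1.0 / (1.0 + np.exp(-scale * centred))
    return p, 1.0 - p


@dataclass
class CohortResult:
    disease: list[VariantRecord]
    benign: list[VariantRecord]
    analytic_auc: float
    score_scale: float
    universe_features: pd.DataFrame
    planted_score: np.ndarray


def make_cohorts(
    model: ProteinModel,
    topology: TopologyAnnotation,
    profile: ConservationProfile,
    reference_sequence: dict[int, str],
    spec: FixtureSpec | None = None,
    seed: int | None = None,
    universe_features: pd.DataFrame | None = None,
) -> CohortResult:
    """Sample D and N cohorts with a calibrated Bayes-optimal AUC.

    Every possible single substitution is featurized; the planted log-odds
    score s(v) splits the universe into a disease pool (probability
    sigma(c * s)) and a benign pool (1 - sigma); c is found by bisection so
    the exact mixture AUC equals ``spec.target_auc`` (a target of 0.5, i.e.
    all effects off, corresponds to c = 0).  Cohorts are drawn i.i.d. from
    the two pools, so duplicates are possible, as in real surveys.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    variants = _universe(reference_sequence)
    if universe_features is None:
        universe_features = featurize_cohort(
            variants, model, topology, profile,
            reference_sequence=reference_sequence,
        )
    score = _planted_score(universe_features, spec.effect_logodds)

    if abs(spec.target_auc - 0.5) < 1e-9 or np.allclose(score, score[0]):
        scale = 0.0
    else:
        lo, hi = 0.0, 1.0
        while _mixture_auc(score, *_sampling_weights(score, hi)) < spec.target_auc:
            hi *= 2.0
            if hi > 1e4:
                raise ValueError(
                    f"target AUC {spec.target_auc} unattainable on this fixture "
                    f"(max {_mixture_auc(score, *_sampling_weights(score, hi)):.3f})"
                )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _mixture_auc(score, *_sampling_weights(score, mid)) < spec.target_auc:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)

    w_d, w_n = _sampling_weights(score, scale)
    analytic = _mixture_auc(score, w_d, w_n)
    idx_d = rng.choice(len(variants), size=spec.n_disease, p=w_d / w_d.sum())
    idx_n = rng.choice(len(variants), size=spec.n_benign, p=w_n / w_n.sum())
    disease = [
        VariantRecord(variants[i].ref_aa, variants[i].position, variants[i].alt_aa, "D")
        for i in idx_d
    ]
    benign = [
        VariantRecord(variants[i].ref_aa, variants[i].position, variants[i].alt_aa, "N")
        for i in idx_n
    ]
    return CohortResult(
        disease=disease, benign=benign, analytic_auc=analytic, score_scale=scale,
        universe_features=universe_features, planted_score=score,
    )


def cohort_feature_table(result: CohortResult) -> pd.DataFrame:
    """Feature rows for the sampled cohorts, looked up from the universe table."""
    table = result.universe_features.set_index("hgvs_p")
    rows = []
    for v in result.disease + result.benign:
        row = table.loc[v.hgvs_p].to_dict()
        row["hgvs_p"] = v.hgvs_p
        row["label"] = v.label
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["hgvs_p", *FEATURE_COLUMNS, "label", "clash_source"]]


def default_conserved_blocks(topology: TopologyAnnotation) -> list[tuple[int, int]]:
    """Conserve the modelled helices (as transmembrane cores tend to be)."""
    return list(topology.modelled_ranges)
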