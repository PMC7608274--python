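"""Geometry, side-chain placement and the sphere-overlap clash score."""

import math

import numpy as np
import pytest

from protvp._sidechain import ROTAMER_CHIS, SIDECHAIN_TEMPLATES
from protvp.aa_scales import STANDARD_AA
from protvp.io_formats import TopologyAnnotation
from protvp.structure_features import (
    Atom,
    ClashEnvironment,
    InsufficientAtomsError,
    ProteinModel,
    Residue,
    Side,
    VDW_RADII,
    centre_of_mass,
    clash_score,
    in_modelled_region,
    place_sidechain,
    sidedness,
    _rotamer_penalty,
)


def atom(name, element, x, y, z):
    return Atom(name, element, (x, y, z), VDW_RADII[element])


def single_residue_model(index=1, aa="A", origin=(0.0, 0.0, 0.0)):
    ox, oy, oz = origin
    return ProteinModel(
        [
            Residue(index, aa, [
                atom("N", "N", ox - 0.525, oy + 1.362, oz),
                atom("CA", "C", ox, oy, oz),
                atom("C", "C", ox + 1.526, oy, oz),
            ])
        ]
    )


# -- centre of mass -----------------------------------------------------


def test_centre_of_mass_single_atom():
    m = ProteinModel([Residue(1, "G", [atom("CA", "C", 1, 2, 3)])])
    np.testing.assert_allclose(centre_of_mass(m), [1, 2, 3])


def test_centre_of_mass_symmetry():
    m = ProteinModel([Residue(1, "G", [atom("CA", "C", 1, 0, 0), atom("C", "C", -1, 0, 0)])])
    np.testing.assert_allclose(centre_of_mass(m), [0, 0, 0], atol=1e-12)


def test_centre_of_mass_matches_brute_force(small_bundle):
    model, _, _ = small_bundle
    total = np.zeros(3)
    n = 0
    for r in model.residues:
        for a in r.atoms:
            total += a.coords
            n += 1
    np.testing.assert_allclose(centre_of_mass(model), total / n, atol=1e-12)


def test_centre_of_mass_empty_model_errors():
    with pytest.raises(ValueError):
        centre_of_mass(ProteinModel([]))


# -- modelled region ----------------------------------------------------


def test_in_modelled_region_inclusive_boundaries():
    topo = TopologyAnnotation(
        modelled_ranges=[(67, 414), (516, 766), (858, 1580)],
        ctd_range=(1581, 1977), domain_ranges={}, segment_ranges={},
        reference_residue=383, sequence_length=1977,
    )
    assert in_modelled_region(topo, 216)
    assert not in_modelled_region(topo, 434)
    assert in_modelled_region(topo, 414) and not in_modelled_region(topo, 415)
    assert in_modelled_region(topo, 67) and not in_modelled_region(topo, 66)


# -- sidedness ----------------------------------------------------------


def three_point_model():
    """Reference at -z, query A at -z (same side), query B at +z (opposite)."""
    residues = [
        Residue(1, "K", [atom("N", "N", 0, 1.4, -10.5), atom("CA", "C", 0, 0, -10),
                         atom("C", "C", 1.5, 0, -10)]),
        Residue(2, "A", [atom("CA", "C", 0, 0, -5)]),
        Residue(3, "A", [atom("CA", "C", 0, 0, 8.333333333)]),
        Residue(4, "A", [atom("CA", "C", 0, 0, 12)]),
    ]
    return ProteinModel(residues)


def topo_for(model, ctd=(90, 100), n=100, ref=1):
    return TopologyAnnotation(
        modelled_ranges=[(1, 10)], ctd_range=ctd, domain_ranges={},
        segment_ranges={}, reference_residue=ref, sequence_length=n,
    )


def test_sidedness_collinear_same_side_is_intracellular():
    m = three_point_model()
    topo = topo_for(m)
    res = sidedness(m, topo, 2)
    assert res.side is Side.INTRACELLULAR
    assert res.angle_deg < 45


def test_sidedness_opposite_side_is_extracellular():
    m = three_point_model()
    topo = topo_for(m)
    res = sidedness(m, topo, 4)
    assert res.side is Side.EXTRACELLULAR
    assert res.angle_deg > 135


def test_sidedness_ctd_excluded():
    m = three_point_model()
    topo = TopologyAnnotation(
        modelled_ranges=[(1, 10)], ctd_range=(3, 5), domain_ranges={},
        segment_ranges={}, reference_residue=1, sequence_length=100,
    )
    res = sidedness(m, topo, 4)
    assert res.side is Side.EXCLUDED and res.angle_deg is None


def test_sidedness_unmodelled_excluded():
    m = three_point_model()
    topo = topo_for(m)
    assert sidedness(m, topo, 50).side is Side.EXCLUDED


def test_reference_residue_is_intracellular(small_bundle):
    model, topo, _ = small_bundle
    res = sidedness(model, topo, topo.reference_residue)
    assert res.side is Side.INTRACELLULAR
    assert res.angle_deg == pytest.approx(0.0, abs=1e-9)


def test_sidedness_invariant_under_rigid_motion(small_bundle):
    model, topo, _ = small_bundle
    rng = np.random.default_rng(5)
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    shift = np.array([12.0, -7.0, 3.0])
    moved = ProteinModel([
        Residue(r.index, r.aa, [
            Atom(a.name, a.element, tuple(rot @ a.coords + shift), a.radius)
            for a in r.atoms
        ])
        for r in model.residues
    ])
    for r in model.residues:
        assert sidedness(model, topo, r.index).side is sidedness(moved, topo, r.index).side


def test_sidedness_partitions_non_excluded_residues(small_bundle):
    model, topo, _ = small_bundle
    sides = {r.index: sidedness(model, topo, r.index).side for r in model.residues}
    assert set(sides.values()) == {Side.INTRACELLULAR, Side.EXTRACELLULAR}


# -- side-chain placement -----------------------------------------------


def test_place_sidechain_glycine_empty():
    m = single_residue_model()
    assert place_sidechain(m, 1, "G", 0) == []


def test_place_sidechain_alanine_cb_geometry():
    m = single_residue_model()
    (cb,) = place_sidechain(m, 1, "A", 0)
    ca = m.residues[0].atom("CA").coords
    n = m.residues[0].atom("N").coords
    c = m.residues[0].atom("C").coords
    assert np.linalg.norm(cb.coords - ca) == pytest.approx(1.53, abs=1e-6)
    cos_n = np.dot(n - ca, cb.coords - ca) / (
        np.linalg.norm(n - ca) * np.linalg.norm(cb.coords - ca)
    )
    # tetrahedral-ish N-CA-CB angle
    assert 100 < math.degrees(math.acos(cos_n)) < 120
    assert np.linalg.norm(cb.coords - c) > 2.0


@pytest.mark.parametrize("aa", sorted(STANDARD_AA))
def test_placement_count_matches_rotamer_table(aa):
    m = single_residue_model()
    placements = [place_sidechain(m, 1, aa, r) for r in range(len(ROTAMER_CHIS[aa]))]
    assert len(placements) == len(ROTAMER_CHIS[aa])
    for atoms in placements:
        assert len(atoms) == len(SIDECHAIN_TEMPLATES[aa])
        # bonded geometry: every atom within 2 A of its template parent
        placed = {a.name: a.coords for a in atoms}
        placed.update({n: m.residues[0].atom(n).coords for n in ("N", "CA", "C")})
        for (name, _, (_, _, parent), bond, _, _) in SIDECHAIN_TEMPLATES[aa]:
            d = np.linalg.norm(placed[name] - placed[parent])
            assert d == pytest.approx(bond, abs=1e-6)


def test_place_sidechain_missing_backbone_errors():
    m = ProteinModel([Residue(1, "A", [atom("CA", "C", 0, 0, 0)])])
    with pytest.raises(InsufficientAtomsError):
        place_sidechain(m, 1, "V", 0)


def test_rotamers_are_distinct_conformations():
    m = single_residue_model()
    coords = [
        tuple(np.round(a.coords, 3).tolist() for a in place_sidechain(m, 1, "L", r))
        for r in range(len(ROTAMER_CHIS["L"]))
    ]
    assert len({str(c) for c in coords}) == len(coords)


# -- clash score --------------------------------------------------------


def two_residue_fixture(env_offset):
    """Mutated residue 1 plus one far-away CA-anchored environment atom.

    ``env_offset`` places the environment atom relative to where the alanine
    CB lands, so overlap depth is controlled exactly.
    """
    base = single_residue_model()
    (cb,) = place_sidechain(base, 1, "A", 0)
    env_pos = cb.coords + np.asarray(env_offset)
    residues = base.residues + [
        Residue(2, "G", [Atom("CA", "C", tuple(env_pos), VDW_RADII["C"])])
    ]
    return ProteinModel(residues)


def test_clash_glycine_always_zero(small_bundle):
    model, _, _ = small_bundle
    for r in model.residues[:5]:
        res = clash_score(model, r.index, "G")
        assert res.score == 0.0 and res.n_overlapping_atoms == 0


def test_clash_isolated_residue_zero():
    m = single_residue_model()
    assert clash_score(m, 1, "W").score == 0.0


def test_clash_crafted_overlap_matches_hand_formula():
    # environment atom 0.4 A inside the contact distance of the alanine CB
    r_sum = VDW_RADII["C"] + VDW_RADII["C"]
    m = two_residue_fixture((r_sum - 0.4, 0.0, 0.0))
    res = clash_score(m, 1, "A")
    assert res.score == pytest.approx(-(0.4**2), abs=1e-9)
    assert res.n_overlapping_atoms == 1
    # scale multiplies the score
    assert clash_score(m, 1, "A", scale=10.0).score == pytest.approx(-10 * 0.4**2)


def test_clash_no_overlap_when_contact_distance_respected():
    r_sum = 2 * VDW_RADII["C"]
    m = two_residue_fixture((r_sum + 0.01, 0.0, 0.0))
    assert clash_score(m, 1, "A").score == 0.0


def test_clash_matches_exhaustive_pair_rotamer_enumeration(small_bundle):
    """Brute-force oracle: enumerate all rotamers and all atom pairs directly."""
    model, _, _ = small_bundle
    env_atoms = [
        (np.asarray(a.xyz), a.radius, r.index)
        for r in model.residues for a in r.atoms
    ]
    for position in (model.residues[2].index, model.residues[7].index):
        for alt in ("W", "R", "S"):
            best = None
            for rot in range(len(ROTAMER_CHIS[alt])):
                atoms = place_sidechain(model, position, alt, rot)
                penalty = 0.0
                for sc in atoms:
                    for pos_e, rad_e, idx_e in env_atoms:
                        if idx_e == position:
                            continue
                        d = float(np.linalg.norm(sc.coords - pos_e))
                        overlap = sc.radius + rad_e - d
                        if overlap > 0:
                            penalty += overlap**2
                if best is None or penalty < best:
                    best = penalty
            got = clash_score(model, position, alt)
            assert got.score == pytest.approx(-best, abs=1e-9)


def test_clash_chosen_rotamer_is_minimal(small_bundle):
    model, _, _ = small_bundle
    env = ClashEnvironment(model)
    position = model.residues[4].index
    res = clash_score(model, position, "F", environment=env)
    penalties = [
        _rotamer_penalty(env, position, place_sidechain(model, position, "F", r), 5.0)[0]
        for r in range(len(ROTAMER_CHIS["F"]))
    ]
    assert -res.score == pytest.approx(min(penalties), abs=1e-12)
    assert penalties[res.rotamer_id] == pytest.approx(min(penalties), abs=1e-12)


def test_clash_translation_rotation_invariant():
    r_sum = 2 * VDW_RADII["C"]
    m = two_residue_fixture((r_sum - 0.3, 0.1, -0.2))
    rng = np.random.default_rng(11)
    rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    shift = np.array([3.0, -4.0, 5.0])
    moved = ProteinModel([
        Residue(r.index, r.aa, [
            Atom(a.name, a.element, tuple(rot @ a.coords + shift), a.radius)
            for a in r.atoms
        ])
        for r in m.residues
    ])
    assert clash_score(moved, 1, "A").score == pytest.approx(
        clash_score(m, 1, "A").score, abs=1e-9
    )


def test_clash_adding_environment_atom_monotone():
    r_sum = 2 * VDW_RADII["C"]
    m = two_residue_fixture((r_sum - 0.3, 0.0, 0.0))
    base_score = clash_score(m, 1, "A").score
    (cb,) = place_sidechain(m, 1, "A", 0)
    extra = Residue(3, "G", [Atom("CA", "C", tuple(cb.coords + [0, r_sum - 0.2, 0]), VDW_RADII["C"])])
    bigger = ProteinModel(m.residues + [extra])
    assert clash_score(bigger, 1, "A").score <= base_score


def test_clash_ca_only_model_errors():
    m = ProteinModel([
        Residue(1, "A", [atom("CA", "C", 0, 0, 0)]),
        Residue(2, "A", [atom("CA", "C", 3, 0, 0)]),
    ])
    with pytest.raises(InsufficientAtomsError):
        clash_score(m, 1, "V")
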