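"""Idealized side-chain templates and a compact backbone-independent rotamer set.

Each template entry places one heavy atom from three previously placed atoms
via internal coordinates (NeRF construction):

    (name, element, (i, j, k), bond, angle, torsion)

where ``i, j, k`` name reference atoms (backbone N/CA/C or earlier side-chain
atoms), ``bond`` is the j-name..new distance in angstroms, ``angle`` the
k..j..new angle in degrees and ``torsion`` either a fixed dihedral in degrees
or ``("chi", n, offset)`` meaning chi_n plus a fixed offset.  Geometry uses
standard ideal bond lengths/angles; ring closure is approximate, which is
adequate for an ordinal overlap score.

Rotamer chi tuples are the common side-chain conformers (modal values of the
backbone-independent rotamer distributions, at most 9 per residue type).
"""

from __future__ import annotations

FixedTorsion = float
ChiTorsion = tuple[str, int, float]
TemplateAtom = tuple[str, str, tuple[str, str, str], float, float, "FixedTorsion | ChiTorsion"]

# improper dihedral N-C-CA-CB = +122.6 deg fixes the L configuration
_CB = ("CB", "C", ("N", "C", "CA"), 1.53, 110.5, 122.6)


def _chain(*entries: TemplateAtom) -> list[TemplateAtom]:
    return [_CB, *entries]


# fmt: off
SIDECHAIN_TEMPLATES: dict[str, list[TemplateAtom]] = {
    "G": [],
    "A": _chain(),
    "S": _chain(("OG",  "O", ("N", "CA", "CB"), 1.41, 110.8, ("chi", 1, 0.0))),
    "C": _chain(("SG",  "S", ("N", "CA", "CB"), 1.81, 113.8, ("chi", 1, 0.0))),
    "T": _chain(("OG1", "O", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0.0)),
                ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0))),
    "V": _chain(("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
                ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122.0))),
    "L": _chain(("CG",  "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
                ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
                ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122.0))),
    "I": _chain(("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
                ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
                ("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0))),
    "M": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
                ("SD",  "S", ("CA", "CB", "CG"), 1.81, 112.7, ("chi", 2, 0.0)),
                ("CE",  "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0.0))),
    "P": _chain(("CG",  "C", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
                ("CD",  "C", ("CA", "CB", "CG"), 1.51, 106.1, ("chi", 2, 0.0))),
    "F": _chain(("CG",  "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
                ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
                ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
                ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
                ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
                ("CZ",  "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)),
    "Y": _chain(("CG",  "C", ("N", "CA", "CB"), 1.51, 113.9, ("chi", 1, 0.0)),
                ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0.0)),
                ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180.0)),
                ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 121.2, 180.0),
                ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 121.2, 180.0),
                ("CZ",  "C", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
                ("OH",  "O", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0)),
    "W": _chain(("CG",  "C", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
                ("CD1", "C", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0.0)),
                ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.7, ("chi", 2, 180.0)),
                ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
                ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
                ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
                ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
                ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
                ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0)),
    "D": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 113.1, ("chi", 1, 0.0)),
                ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.2, ("chi", 2, 0.0)),
                ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.2, ("chi", 2, 180.0))),
    "N": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
                ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.9, ("chi", 2, 0.0)),
                ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.5, ("chi", 2, 180.0))),
    "E": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
                ("CD",  "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
                ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.2, ("chi", 3, 0.0)),
                ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.2, ("chi", 3, 180.0))),
    "Q": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
                ("CD",  "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
                ("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.9, ("chi", 3, 0.0)),
                ("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.5, ("chi", 3, 180.0))),
    "K": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
                ("CD",  "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
                ("CE",  "C", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0.0)),
                ("NZ",  "N", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0))),
    "R": _chain(("CG",  "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
                ("CD",  "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
                ("NE",  "N", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3, 0.0)),
                ("CZ",  "C", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0.0)),
                ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
                ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)),
    "H": _chain(("CG",  "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
                ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
                ("CD2", "C", ("CA", "CB", "CG"), 1.36, 131.1, ("chi", 2, 180.0)),
                ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
                ("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0)),
}

# Common conformers; chi tuples in degrees, one tuple per rotamer.
ROTAMER_CHIS: dict[str, list[tuple[float, ...]]] = {
    "G": [()],
    "A": [()],
    "S": [(-65.0,), (180.0,), (65.0,)],
    "C": [(-65.0,), (180.0,), (65.0,)],
    "T": [(-60.0,), (180.0,), (60.0,)],
    "V": [(175.0,), (-60.0,), (65.0,)],
    "P": [(-25.0, 37.0), (25.0, -34.0)],
    "L": [(-65.0, 175.0), (177.0, 65.0), (-85.0, 65.0), (180.0, 180.0)],
    "I": [(-60.0, 170.0), (-60.0, -60.0), (180.0, 165.0), (62.0, 170.0)],
    "M": [(-65.0, 180.0, 180.0), (-65.0, -65.0, -70.0), (180.0, 180.0, 180.0),
          (180.0, 65.0, 75.0), (-65.0, 180.0, 75.0), (62.0, 180.0, 180.0)],
    "F": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0), (-85.0, -30.0)],
    "Y": [(-65.0, 90.0), (180.0, 80.0), (62.0, 90.0), (-85.0, -30.0)],
    "W": [(-65.0, 95.0), (-65.0, -90.0), (180.0, -105.0), (180.0, 90.0), (62.0, -90.0)],
    "H": [(-65.0, -70.0), (180.0, -165.0), (180.0, 60.0), (62.0, -75.0)],
    "D": [(-70.0, -15.0), (180.0, 0.0), (62.0, 0.0)],
    "N": [(-65.0, -20.0), (180.0, 0.0), (62.0, -75.0), (-65.0, 120.0)],
    "E": [(-65.0, 180.0, -10.0), (180.0, 180.0, 0.0), (-65.0, -65.0, -40.0),
          (62.0, 180.0, 0.0), (180.0, 65.0, 10.0)],
    "Q": [(-65.0, 180.0, 0.0), (180.0, 180.0, 0.0), (-65.0, -65.0, -40.0),
          (62.0, 180.0, 0.0), (180.0, 65.0, 10.0)],
    "K": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
          (-65.0, -65.0, 180.0, 180.0), (62.0, 180.0, 180.0, 180.0),
          (180.0, 65.0, 180.0, 180.0)],
    "R": [(-65.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
          (-65.0, -65.0, 180.0, 180.0), (62.0, 180.0, 180.0, 85.0),
          (180.0, 65.0, 65.0, 85.0)],
}
# fmt: on


def n_chi(aa: str) -> int:
    """Number of chi angles the template of ``aa`` consumes."""
    chis = {0}
    for _, _, _, _, _, torsion in SIDECHAIN_TEMPLATES[aa]:
        if isinstance(torsion, tuple):
            chis.add(torsion[1])
    return max(chis)
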