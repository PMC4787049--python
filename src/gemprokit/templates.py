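"""Idealized side-chain geometry templates for grafting.

Each entry lists side-chain heavy atoms beyond CB in buildable order:
(atom name, element, (refA, refB, refC), bond length A, angle deg at refC,
dihedral deg A-B-C-D). CB itself is placed from the backbone with an exact
N-CA-CB angle (see geometry.place_cb); chi angles default to extended (180),
branches at -60. Ring geometries are idealized and approximately planar --
good enough for clash relief, not for refinement against density.

vdW radii (A) used by the clash term and by SASA.
"""

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70

# (name, element, (A, B, C), bond, angle, dihedral)
SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "G": [],
    "A": [],
    "S": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, 180.0)],
    "C": [("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, 180.0)],
    "T": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, 180.0),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -60.0)],
    "V": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, 180.0),
          ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, -60.0)],
    "L": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, 180.0),
          ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, 180.0),
          ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, 60.0)],
    "I": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, 180.0),
          ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, -60.0),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 180.0)],
    "M": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
          ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
          ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, 180.0)],
    "D": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
          ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, 0.0),
          ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 180.0)],
    "N": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, 180.0),
          ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, 0.0),
          ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 180.0)],
    "E": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
          ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
          ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 180.0)],
    "Q": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
          ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
          ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 180.0)],
    "K": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
          ("CE", "C", ("CB", "CG", "CD"), 1.508, 111.9, 180.0),
          ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.7, 180.0)],
    "R": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, 180.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
          ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
          ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "H": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, 180.0),
          ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, 90.0),
          ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.0, -90.0),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, 180.0),
          ("NE2", "N", ("CG", "ND1", "CE1"), 1.374, 108.4, 0.0)],
    "F": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, 180.0),
          ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
          ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, -90.0),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "Y": [("CG", "C", ("N", "CA", "CB"), 1.512, 113.9, 180.0),
          ("CD1", "C", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
          ("CD2", "C", ("CA", "CB", "CG"), 1.389, 120.8, -90.0),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "W": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, 180.0),
          ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
          ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.6, -90.0),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.1, 180.0),
          ("CE2", "C", ("CG", "CD1", "NE1"), 1.370, 109.0, 0.0),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
          ("CZ2", "C", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
          ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.368, 121.1, 0.0)],
    "P": [("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, -35.0)],
}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}
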