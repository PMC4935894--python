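"""Standard base geometries in the standard nucleic-acid reference frame.

Coordinates follow the community standard reference frame for base-pair
geometry (Olson et al., J Mol Biol 2001; the convention used by 3DNA):
each base is planar (z = 0), the frame origin sits near the centre of an
idealised Watson-Crick pair, the x-axis points into the major groove and
the y-axis runs along the pseudo-dyad toward the glycosidic bond.  In this
convention the two bases of an ideal pair are related by a 180-degree
rotation about x, i.e. by negating y and z.

Only heavy atoms are tabulated.  Ring atoms are used for frame fitting and
for the stacking-overlap polygons; exocyclic atoms (amino/keto groups and
methyls) are carried for completeness but never enter the overlap area.

The sugar-phosphate backbone template is schematic: atom positions have
chemically plausible bond lengths but are not energy-minimised.  The
pipeline only requires consistent topology, a correct C1' anchor
(identical for purines and pyrimidines in this frame) and exact ring
geometry, all of which the table provides.
"""

from __future__ import annotations

import numpy as np

# Base heavy atoms, standard reference frame, z = 0 (planar bases).
# name -> (x, y) in Angstrom.
BASE_ATOMS: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498),
        "C8": (0.024, 4.897),
        "N7": (0.877, 3.902),
        "C5": (0.071, 2.771),
        "C6": (0.369, 1.398),
        "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532),
        "C2": (-2.002, 1.021),
        "N3": (-2.342, 2.275),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "N9": (-1.289, 4.551),
        "C8": (0.023, 4.962),
        "N7": (0.870, 3.969),
        "C5": (0.071, 2.833),
        "C6": (0.424, 1.460),
        "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641),
        "C2": (-1.999, 1.087),
        "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364),
        "C4": (-1.265, 3.177),
    },
    "C": {
        "N1": (-1.285, 4.542),
        "C2": (-1.472, 3.158),
        "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344),
        "C4": (0.837, 2.868),
        "N4": (1.875, 2.027),
        "C5": (1.056, 4.275),
        "C6": (-0.023, 5.068),
    },
    "T": {
        "N1": (-1.284, 4.500),
        "C2": (-1.462, 3.135),
        "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407),
        "C4": (0.994, 2.897),
        "O4": (1.944, 2.119),
        "C5": (1.106, 4.338),
        "C7": (2.466, 4.961),
        "C6": (-0.024, 5.057),
    },
}

#: Ring atoms per base type, in outline (perimeter) order.  For purines the
#: nine-atom fused-ring perimeter is used as a single polygon.
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T"})

#: Watson-Crick complement (mC complements as C).
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Glycosidic nitrogen per base type.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}

# Schematic deoxyribose/phosphate backbone, standard frame coordinates.
# C1' is the anchor shared by purines and pyrimidines in this convention.
BACKBONE_ATOMS: dict[str, tuple[float, float, float]] = {
    "C1'": (-2.477, 5.399, 0.000),
    "O4'": (-3.700, 4.770, 0.550),
    "C2'": (-2.730, 6.300, -1.200),
    "C3'": (-4.150, 6.050, -1.600),
    "O3'": (-4.510, 7.230, -2.300),
    "C4'": (-4.600, 5.130, -0.500),
    "C5'": (-5.500, 4.330, 0.350),
    "O5'": (-6.000, 4.130, 1.650),
    "P": (-6.400, 3.230, 2.850),
    "OP1": (-7.700, 2.630, 3.150),
    "OP2": (-5.800, 2.730, 4.100),
}

#: 5'-terminal residues are written without the leading phosphate group.
PHOSPHATE_GROUP = ("P", "OP1", "OP2")

#: Length of the C5-methyl bond added to 5-methylcytosine, Angstrom.
METHYL_BOND_LENGTH = 1.50


def base_template(base: str) -> dict[str, np.ndarray]:
    """Return heavy-atom coordinates of ``base`` ('A','C','G','T') as 3-vectors."""
    if base not in BASE_ATOMS:
        raise KeyError(f"no template for base {base!r}")
    return {
        name: np.array([x, y, 0.0]) for name, (x, y) in BASE_ATOMS[base].items()
    }


def ring_template(base: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Ring atom names (outline order) and their template coordinates (n, 3)."""
    names = RING_ATOMS[base]
    tmpl = base_template(base)
    return names, np.array([tmpl[n] for n in names])


def methyl_position(c5: np.ndarray, c4: np.ndarray, c6: np.ndarray) -> np.ndarray:
    """Ideal in-plane position for a 5-methyl carbon off C5.

    The methyl points away from the ring along the external bisector at C5.
    """
    v = c5 - 0.5 * (c4 + c6)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate C4/C5/C6 geometry")
    return c5 + METHYL_BOND_LENGTH * v / n
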