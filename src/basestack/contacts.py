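"""Protein-DNA contact geometry: hydrogen bonds, water bridges, targeted
distances, rigid-body superposition, and ensemble distance distributions.

All criteria are heavy-atom only — crystal inputs carry no hydrogens — so
a hydrogen bond is a donor/acceptor N-or-O pair within a distance cutoff
(default 3.5 A) with no angle term, and a water bridge is a water oxygen
within the cutoff of polar atoms on both sides.

Atom selections use ``chain/residue-number/atom-name`` triplets with ``*``
wildcards, e.g. ``A/461/NZ`` or ``D/*/O6``; residue numbers are author
numbering, matching published residue labels such as K461 and H472.
"""

from __future__ import annotations

import dataclasses
import fnmatch
import math

import numpy as np

from .config import DEFAULT, Config
from .dna_geometry import kabsch
from .structure_io import Atom, Residue, Structure

# ---------------------------------------------------------------------------
# selections


@dataclasses.dataclass(frozen=True)
class Selection:
    """chain/resnum/atom triplet, '*' wildcards allowed in each field."""

    chain: str = "*"
    resnum: str = "*"
    atom: str = "*"

    @classmethod
    def parse(cls, text: str) -> "Selection":
        parts = text.split("/")
        if len(parts) != 3:
            raise ValueError(
                f"selection {text!r}: expected chain/resnum/atom")
        return cls(*[p if p else "*" for p in parts])

    def matches(self, res: Residue, atom: Atom) -> bool:
        return (fnmatch.fnmatchcase(res.chain_id, self.chain)
                and fnmatch.fnmatchcase(str(res.seq_num), self.resnum)
                and fnmatch.fnmatchcase(atom.name, self.atom))


def _as_selection(sel: "Selection | str") -> Selection:
    return Selection.parse(sel) if isinstance(sel, str) else sel


def select_atoms(s: Structure, sel: Selection | str) -> list[tuple[Residue, Atom]]:
    sel = _as_selection(sel)
    return [(res, a) for res in s.residues() for a in res.atoms
            if sel.matches(res, a)]


def select_one(s: Structure, sel: Selection | str) -> tuple[Residue, Atom]:
    hits = select_atoms(s, sel)
    if len(hits) != 1:
        desc = ", ".join(f"{r.label()}:{a.name}" for r, a in hits[:8]) or "none"
        raise ValueError(f"selection must resolve to exactly one atom, "
                         f"got {len(hits)} ({desc})")
    return hits[0]


# ---------------------------------------------------------------------------
# donor / acceptor typing (heavy atoms)

# residue name -> atom name -> 'd' donor, 'a' acceptor, 'b' both
_POLAR: dict[str, dict[str, str]] = {
    # nucleotides (Watson-Crick and groove-facing atoms)
    "DA": {"N6": "d", "N1": "a", "N3": "a", "N7": "a"},
    "DG": {"N1": "d", "N2": "d", "O6": "a", "N3": "a", "N7": "a"},
    "DC": {"N4": "d", "N3": "a", "O2": "a"},
    "DT": {"N3": "d", "O2": "a", "O4": "a"},
    # protein side chains that matter for the interfaces studied here
    "LYS": {"NZ": "d"},
    "ARG": {"NE": "d", "NH1": "d", "NH2": "d"},
    "HIS": {"ND1": "b", "NE2": "b"},
    "SER": {"OG": "b"},
    "THR": {"OG1": "b"},
    "TYR": {"OH": "b"},
    "ASN": {"ND2": "d", "OD1": "a"},
    "GLN": {"NE2": "d", "OE1": "a"},
    "ASP": {"OD1": "a", "OD2": "a"},
    "GLU": {"OE1": "a", "OE2": "a"},
    "TRP": {"NE1": "d"},
    "HOH": {"O": "b"},
}
_ALIASES = {"A": "DA", "G": "DG", "C": "DC", "T": "DT", "5CM": "DC",
            "WAT": "HOH"}
# phosphate/backbone oxygens and main-chain N/O
_BACKBONE = {"OP1": "a", "OP2": "a", "O3'": "a", "O5'": "a", "O4'": "a",
             "N": "d", "O": "a", "OXT": "a"}


def polar_role(res: Residue, atom: Atom) -> str | None:
    """'d', 'a', 'b' or None for a heavy atom; unknown N/O default to 'b'."""
    name = _ALIASES.get(res.name, res.name)
    table = _POLAR.get(name, {})
    if atom.name in table:
        return table[atom.name]
    if atom.name in _BACKBONE and res.name != "HOH":
        return _BACKBONE[atom.name]
    if atom.element in ("N", "O"):
        return "b"
    return None


# ---------------------------------------------------------------------------
# hydrogen bonds and water bridges


@dataclasses.dataclass
class HBond:
    donor_res: Residue
    donor_atom: Atom
    acceptor_res: Residue
    acceptor_atom: Atom
    distance: float
    bridged_by: Atom | None = None
    leg_a: float | None = None  # donor-side leg when bridged
    leg_b: float | None = None

    def row(self) -> dict:
        return {
            "donor": f"{self.donor_res.label()}:{self.donor_atom.name}",
            "acceptor": f"{self.acceptor_res.label()}:{self.acceptor_atom.name}",
            "distance": self.distance,
            "water_bridge": self.bridged_by is not None,
        }


def _compatible(role_1: str, role_2: str) -> bool:
    """One side must be able to donate while the other accepts."""
    return (role_1 in ("d", "b") and role_2 in ("a", "b")) or \
           (role_2 in ("d", "b") and role_1 in ("a", "b"))


def find_hbonds(s: Structure, selection_a: Selection | str,
                selection_b: Selection | str, d_max: float | None = None,
                cfg: Config = DEFAULT) -> list[HBond]:
    """Heavy-atom hydrogen bonds between two selections, sorted by distance."""
    d_max = cfg.hbond_max if d_max is None else d_max
    side_a = [(r, a, polar_role(r, a)) for r, a in select_atoms(s, selection_a)]
    side_b = [(r, a, polar_role(r, a)) for r, a in select_atoms(s, selection_b)]
    side_a = [t for t in side_a if t[2]]
    side_b = [t for t in side_b if t[2]]
    if not side_a or not side_b:
        raise ValueError("empty (or apolar) selection for hydrogen-bond search")
    bonds = []
    for ra, aa, role_a in side_a:
        for rb, ab, role_b in side_b:
            if aa is ab:
                continue
            d = float(np.linalg.norm(aa.pos - ab.pos))
            if d <= d_max and _compatible(role_a, role_b):
                if role_a in ("d", "b"):
                    bonds.append(HBond(ra, aa, rb, ab, d))
                else:
                    bonds.append(HBond(rb, ab, ra, aa, d))
    return sorted(bonds, key=lambda b: b.distance)


def find_water_bridges(s: Structure, selection_a: Selection | str,
                       selection_b: Selection | str, d_max: float | None = None,
                       cfg: Config = DEFAULT) -> list[HBond]:
    """Water-mediated bridges: a water O within ``d_max`` of polar atoms on
    both sides.  Reported as bridged HBond records (distance = longer leg)."""
    d_max = cfg.hbond_max if d_max is None else d_max
    waters = [(r, a) for r, a in select_atoms(s, Selection())
              if r.name in ("HOH", "WAT") and a.element == "O"]
    side_a = [(r, a) for r, a in select_atoms(s, selection_a)
              if polar_role(r, a) and r.name not in ("HOH", "WAT")]
    side_b = [(r, a) for r, a in select_atoms(s, selection_b)
              if polar_role(r, a) and r.name not in ("HOH", "WAT")]
    bridges = []
    for rw, aw in waters:
        legs_a = [(float(np.linalg.norm(aw.pos - a.pos)), r, a)
                  for r, a in side_a]
        legs_b = [(float(np.linalg.norm(aw.pos - a.pos)), r, a)
                  for r, a in side_b]
        best_a = min((t for t in legs_a if t[0] <= d_max),
                     key=lambda t: t[0], default=None)
        best_b = min((t for t in legs_b if t[0] <= d_max),
                     key=lambda t: t[0], default=None)
        if best_a and best_b and best_a[2] is not best_b[2]:
            da, ra, atom_a = best_a
            db, rb, atom_b = best_b
            bridges.append(HBond(ra, atom_a, rb, atom_b,
                                 distance=max(da, db), bridged_by=aw,
                                 leg_a=da, leg_b=db))
    return sorted(bridges, key=lambda b: b.distance)


# ---------------------------------------------------------------------------
# distances


def min_distance(s: Structure, sel_1: Selection | str,
                 sel_2: Selection | str) -> float:
    """Minimum pairwise distance between two (multi-atom) selections."""
    a = np.array([at.pos for _, at in select_atoms(s, sel_1)])
    b = np.array([at.pos for _, at in select_atoms(s, sel_2)])
    if a.size == 0 or b.size == 0:
        raise ValueError("empty selection in min_distance")
    return float(np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)).min())


def measure_distance(s: Structure, sel_1: Selection | str,
                     sel_2: Selection | str) -> list[float]:
    """Euclidean distance between two single-atom selections, per model."""
    out = []
    for sm in s.models():
        _, a1 = select_one(sm, sel_1)
        _, a2 = select_one(sm, sel_2)
        out.append(float(np.linalg.norm(a1.pos - a2.pos)))
    return out


@dataclasses.dataclass
class DistanceDistribution:
    values: np.ndarray
    bins: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


def distance_distribution(ensemble: Structure, sel_1: Selection | str,
                          sel_2: Selection | str,
                          bin_width: float = 0.1) -> DistanceDistribution:
    """Histogram of a per-model distance over a coordinate ensemble."""
    if ensemble.n_models < 2:
        raise ValueError("distance_distribution needs a multi-model ensemble")
    values = np.array(measure_distance(ensemble, sel_1, sel_2))
    lo = math.floor(values.min())
    hi = math.ceil(values.max())
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges[-1] < values.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return DistanceDistribution(values=values, bins=edges, counts=counts)


# ---------------------------------------------------------------------------
# superposition


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation


def superpose(s_ref: Structure, s_mov: Structure,
              atom_map: list[tuple[Selection | str, Selection | str]]
              ) -> SuperpositionResult:
    """Kabsch fit of ``s_mov`` onto ``s_ref`` over paired single-atom
    selections; RMSD over the mapped atoms after fitting."""
    ref_pts, mov_pts = [], []
    for sel_ref, sel_mov in atom_map:
        _, ar = select_one(s_ref, sel_ref)
        _, am = select_one(s_mov, sel_mov)
        ref_pts.append(ar.pos)
        mov_pts.append(am.pos)
    if len(ref_pts) < 3:
        raise ValueError("atom_map must pair at least 3 atoms")
    rot, t, rmsd = kabsch(np.array(mov_pts), np.array(ref_pts))
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd,
                               n_atoms=len(ref_pts))


def dna_atom_map(s_ref: Structure, s_mov: Structure, chains: list[str],
                 drop_methyl: bool = True
                 ) -> list[tuple[Selection, Selection]]:
    """Pair all DNA heavy atoms of two structures by residue position and
    atom name (the reference convention for duplex-vs-duplex RMSD).

    Residues are matched by order along each chain, so a methylated duplex
    maps onto its unmethylated counterpart; the 5-methyl carbon, absent in
    the unmethylated partner, is dropped when ``drop_methyl`` is set.
    """
    pairs = []
    for cid in chains:
        ref_res = [r for r in s_ref.chain(cid) if r.is_nucleotide]
        mov_res = [r for r in s_mov.chain(cid) if r.is_nucleotide]
        if len(ref_res) != len(mov_res):
            raise ValueError(f"chain {cid}: {len(ref_res)} vs {len(mov_res)} "
                             "nucleotides; cannot pair by position")
        for rr, rm in zip(ref_res, mov_res):
            mov_names = {a.name for a in rm.atoms}
            for a in rr.atoms:
                if drop_methyl and a.name == "C5M":
                    continue
                if a.name in mov_names:
                    pairs.append((
                        Selection(rr.chain_id, str(rr.seq_num), a.name),
                        Selection(rm.chain_id, str(rm.seq_num), a.name)))
    return pairs
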