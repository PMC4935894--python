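"""Macromolecular structure I/O and normalisation of modified bases.

Parsing and writing of PDB/mmCIF is delegated to gemmi; this module wraps
the result in a light hierarchical container tailored to the pipeline:
per-residue base codes (A/C/G/T/mC or none), explicit methylation flags,
and multi-model coordinate sets sharing one topology (crystal structures
read as one model, coordinate ensembles as many).

Conventions applied on read:

* hydrogens (and deuterium) are dropped — crystal inputs lack them and all
  geometric operations are heavy-atom only;
* for alternate locations, the highest-occupancy conformer is kept, ties
  broken by the alphabetically first altloc label;
* author residue numbering is preserved verbatim.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

from .config import DEFAULT, Config, log
from . import templates

_STD_NUCLEOTIDES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "none", "DU": "none",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}


@dataclasses.dataclass
class Atom:
    """A heavy atom: name, element symbol, position (Angstrom)."""

    name: str
    element: str
    pos: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    name: str
    base_code: str  # one of A, C, G, T, mC, none
    is_methylated: bool
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_nucleotide(self) -> bool:
        return self.base_code != "none"

    @property
    def ring_base(self) -> str:
        """Base type used for ring geometry (mC uses the cytosine ring)."""
        return "C" if self.base_code == "mC" else self.base_code

    def label(self) -> str:
        return f"{self.chain_id}/{self.seq_num}{self.icode.strip()}/{self.name}"


class Structure:
    """Hierarchical coordinate container with shared-topology models.

    ``chains`` maps chain id to an ordered residue list; the residues hold
    the coordinates of the first model.  Additional models are stored as
    flat ``(n_atoms, 3)`` arrays in atom-iteration order.
    """

    def __init__(self, sid: str, chains: dict[str, list[Residue]],
                 extra_models: list[np.ndarray] | None = None):
        if not chains or not any(chains.values()):
            raise ValueError("empty structure")
        self.id = sid
        self.chains = chains
        self.extra_models = [np.asarray(m, dtype=float) for m in (extra_models or [])]
        n = self.n_atoms
        for i, m in enumerate(self.extra_models):
            if m.shape != (n, 3):
                raise ValueError(
                    f"model {i + 2} has {m.shape[0]} atoms, topology has {n}")

    # -- iteration ---------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_models(self) -> int:
        return 1 + len(self.extra_models)

    def coords(self) -> np.ndarray:
        """Coordinates of the first model, atom-iteration order, (n, 3)."""
        return np.array([a.pos for a in self.atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        for a, p in zip(self.atoms(), xyz, strict=True):
            a.pos = p

    def model(self, i: int) -> "Structure":
        """A single-model deep copy holding the coordinates of model ``i``."""
        if not 0 <= i < self.n_models:
            raise IndexError(f"model {i} out of range (n_models={self.n_models})")
        chains = {
            cid: [dataclasses.replace(r, atoms=[dataclasses.replace(a) for a in r.atoms])
                  for r in residues]
            for cid, residues in self.chains.items()
        }
        s = Structure(self.id, chains)
        if i > 0:
            s.set_coords(self.extra_models[i - 1])
        return s

    def models(self) -> Iterator["Structure"]:
        for i in range(self.n_models):
            yield self.model(i)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure {self.id}")
        return self.chains[chain_id]


# ---------------------------------------------------------------------------
# reading


def _pick_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties to first label."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for at in res:
        if at.element.name in ("H", "D"):
            continue
        by_name.setdefault(at.name, []).append(at)
    picked = []
    for name, group in by_name.items():
        best = sorted(group, key=lambda a: (-a.occ, a.altloc or "~"))[0]
        picked.append(best)
    return picked


def _base_code(name: str, cfg: Config) -> tuple[str, bool]:
    if name in cfg.mc_residue_names:
        return "mC", True
    return _STD_NUCLEOTIDES.get(name, "none"), False


def read_structure(path: str | Path, fmt: str = "auto",
                   cfg: Config = DEFAULT) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Multi-MODEL files yield one coordinate set per model (all models must
    share topology).  The highest-occupancy alternate location is retained
    per atom; hydrogens are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models")

    chains: dict[str, list[Residue]] = {}
    order: list[tuple[str, int]] = []  # (chain_id, residue index) per atom-group
    model0 = st[0]
    for ch in model0:
        residues: list[Residue] = []
        for res in ch:
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                     a.altloc or "", a.occ)
                for a in _pick_altloc(res)
            ]
            if not atoms:
                continue
            code, methylated = _base_code(res.name, cfg)
            residues.append(Residue(ch.name, res.seqid.num, res.seqid.icode or "",
                                    res.name, code, methylated, atoms))
        if residues:
            chains[ch.name] = chains.get(ch.name, []) + residues
    if not chains or not any(chains.values()):
        raise ValueError(f"{path}: structure contains no atoms")

    s = Structure(st.name or path.stem, chains)
    n = s.n_atoms
    extra = []
    for mi in range(1, len(st)):
        xyz = []
        for ch in st[mi]:
            for res in ch:
                for a in _pick_altloc(res):
                    xyz.append([a.pos.x, a.pos.y, a.pos.z])
        if len(xyz) != n:
            raise ValueError(
                f"{path}: model {mi + 1} has {len(xyz)} atoms, model 1 has {n}")
        extra.append(np.array(xyz))
    s.extra_models = extra
    return normalize_modified_bases(s, cfg)


# ---------------------------------------------------------------------------
# modified-base normalisation


def normalize_modified_bases(s: Structure, cfg: Config = DEFAULT) -> Structure:
    """Flag 5-methylcytosines and map their atom names onto cytosine names.

    Residues whose name is in the configured synonym list get
    ``base_code='mC'`` and ``is_methylated=True``; their methyl-carbon
    synonyms are renamed to the canonical label.  A flagged residue missing
    a cytosine ring atom is demoted to ``base_code='none'`` with a logged
    warning so it cannot poison downstream geometry.
    """
    ring = templates.RING_ATOMS["C"]
    for res in s.residues():
        if res.name in cfg.mc_residue_names or (res.is_methylated and res.base_code == "mC"):
            res.base_code = "mC"
            res.is_methylated = True
            for a in res.atoms:
                if a.name in cfg.mc_methyl_names:
                    a.name = cfg.mc_methyl_canonical
            missing = [n for n in ring if res.atom(n) is None]
            if missing:
                log.warning(
                    "residue %s flagged 5mC but missing ring atoms %s; "
                    "excluded from geometry", res.label(), ",".join(missing))
                res.base_code = "none"
    return s


# ---------------------------------------------------------------------------
# writing


_ELEMENT_FIX = {"C5M": "C"}


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB (MODEL records for multi-model input)."""
    st = gemmi.Structure()
    st.name = s.id
    for mi in range(s.n_models):
        sm = s.model(mi) if mi > 0 else s
        model = gemmi.Model(mi + 1)
        for cid, residues in sm.chains.items():
            ch = gemmi.Chain(cid)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element or _ELEMENT_FIX.get(a.name, a.name[0]))
                    ga.pos = gemmi.Position(*a.pos)
                    ga.occ = a.occupancy
                    gres.add_atom(ga)
                ch.add_residue(gres)
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# tabular reports


def write_report(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write records as a TSV with header; floats at 4 decimals."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def nucleotide_chains(s: Structure, min_length: int = 2) -> list[str]:
    """Chain ids holding at least ``min_length`` nucleotides (duplex strands)."""
    return [cid for cid, residues in s.chains.items()
            if sum(r.is_nucleotide for r in residues) >= min_length]


def duplex_sequence(s: Structure, chain_id: str) -> str:
    """Annotated 5'->3' sequence of a chain (mC written as 'mC')."""
    out = []
    for res in s.chain(chain_id):
        if res.is_nucleotide:
            out.append("mC" if res.base_code == "mC" else res.base_code)
    return "".join(out)
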