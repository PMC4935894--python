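"""Synthetic inputs for the pipeline: idealized B-DNA duplexes (with
optional 5-methylcytosine and per-step geometric perturbations),
multi-model coordinate ensembles, and censored exponential dwell times.

The duplex builder places standard planar base templates on successive
frames generated by fiber-like step parameters (twist 36 deg, rise 3.4 A
by default); the complementary strand follows from the pairing flip of the
standard reference frame and a schematic sugar-phosphate backbone is
attached in each base frame.  mC positions carry a C5-methyl carbon and
residue name 5CM.  There is no energy model: the product is exact,
reproducible geometry for testing frame fitting, pairing, stacking
overlap and contacts.

Every stochastic generator takes an explicit seed and is bit-reproducible.

Study conditions (module constants): the response-element sequences used
throughout — GRE AGAACATCATGTTCT with its side- (smGRE, four mCH across
the two half-sites) and middle-methylated (mmGRE, one mCH in the spacer)
variants, ERE AGGTCACAGTGACCT, E-box CACGTG — and default single-molecule
rates k_off = 0.30 / 0.10 / 0.20 1/s with K_D = 30 / 10 / 20 nM for
GRE / smGRE / mmGRE, i.e. ~3-fold and ~1.5-fold stabilisation by
methylation at constant k_on = 1e7 1/(M s).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import templates
from .config import DEFAULT, Config
from .dna_geometry import FLIP_X, _parse_annotated
from .kinetics import DwellTimeSet
from .structure_io import Atom, Residue, Structure

# ---------------------------------------------------------------------------
# study conditions

GRE = "AGAACATCATGTTCT"
#: side-methylated GRE: the mCA/mCT cytosines of both half-sites, both strands
SMGRE = "AGAAmCATCATGTTmCT"
#: complement-strand methylation of smGRE (positions on the Crick strand 5'->3')
SMGRE_CRICK_MC = (5, 14)
#: middle-methylated GRE: the single spacer cytosine
MMGRE = "AGAACATmCATGTTCT"
ERE = "AGGTCACAGTGACCT"
EBOX = "CACGTG"

#: default dissociation rates (1/s) and K_D (M) per construct
KOFF_DEFAULTS = {"GRE": 0.30, "smGRE": 0.10, "mmGRE": 0.20}
KD_DEFAULTS = {"GRE": 30e-9, "smGRE": 10e-9, "mmGRE": 20e-9}

#: extra slide (A) applied at A-mC steps to emulate the methylation-coupled
#: conformational change seen in methylated complexes; the sign is chosen so
#: the stacking overlap of the affected step increases, the direction
#: observed for the 5'-AC-3' context on methylation
METHYLATION_SLIDE = -0.5


@dataclasses.dataclass
class FiberParams:
    """Per-step helical parameters (degrees and Angstrom)."""

    twist: float = 36.0
    rise: float = 3.4
    roll: float = 0.0
    tilt: float = 0.0
    slide: float = 0.0
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _step_frames(n: int, fiber: FiberParams,
                 step_params: dict[int, FiberParams] | None
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Frames (rotation, origin) for n base pairs along the helix.

    Step i (0-based) transforms frame i into frame i+1: the origin advances
    by (shift, slide, rise) expressed in frame i, the orientation by
    Rx(tilt) Ry(roll) Rz(twist).  A simplified local-step convention, exact
    for the default straight fiber.
    """
    frames = [(np.eye(3), np.zeros(3))]
    for i in range(n - 1):
        p = (step_params or {}).get(i, fiber)
        rot_i, org_i = frames[-1]
        org = org_i + rot_i @ np.array([p.shift, p.slide, p.rise])
        rot = rot_i @ _rot_x(p.tilt) @ _rot_y(p.roll) @ _rot_z(p.twist)
        frames.append((rot, org))
    return frames


def _residue_atoms(base: str, methylated: bool, rot: np.ndarray,
                   org: np.ndarray, flip: bool, first: bool) -> list[Atom]:
    """Place base + schematic backbone (template coords -> lab frame)."""
    placement = rot @ (FLIP_X if flip else np.eye(3))
    tmpl = templates.base_template(base)
    atoms = []
    for name, pos in tmpl.items():
        atoms.append(Atom(name, name[0], placement @ pos + org))
    if methylated:
        mpos = templates.methyl_position(tmpl["C5"], tmpl["C4"], tmpl["C6"])
        atoms.append(Atom("C5M", "C", placement @ mpos + org))
    for name, xyz in templates.BACKBONE_ATOMS.items():
        if first and name in templates.PHOSPHATE_GROUP:
            continue
        atoms.append(Atom(name, name[0], placement @ np.array(xyz) + org))
    return atoms


def parse_annotated_sequence(seq: str) -> list[tuple[str, bool]]:
    """'AGAAmCA...' -> [(base, methylated), ...]; mC must precede A/T/C or G."""
    out = []
    for sym in _parse_annotated(seq):
        if sym == "mC":
            out.append(("C", True))
        else:
            out.append((sym, False))
    return out


def build_bdna(sequence: str, fiber: FiberParams | None = None,
               step_params: dict[int, FiberParams] | None = None,
               crick_methylations: tuple[int, ...] = (),
               structure_id: str = "bdna",
               cfg: Config = DEFAULT) -> Structure:
    """Build an idealized all-heavy-atom B-form duplex.

    ``sequence`` is the Watson strand 5'->3' with mC marks (e.g.
    ``AGAACATmCATGTTCT``); ``crick_methylations`` lists 1-based positions
    of additional mCs counted 5'->3' along the *complementary* strand.
    ``step_params`` overrides the fiber parameters of individual 0-based
    steps (used e.g. for the documented methylation-coupled slide).
    """
    bases = parse_annotated_sequence(sequence)
    n = len(bases)
    if n < 2:
        raise ValueError("sequence must be at least 2 bases")
    fiber = fiber or FiberParams()
    frames = _step_frames(n, fiber, step_params)

    crick_bases = []  # 5'->3' along the Crick strand
    for i, (b, _m) in enumerate(reversed(bases)):
        comp = templates.COMPLEMENT[b]
        pos = i + 1
        meth = pos in crick_methylations
        if meth and comp != "C":
            raise ValueError(
                f"crick methylation at position {pos} is {comp}, not C")
        crick_bases.append((comp, meth))

    def make_residue(chain: str, num: int, base: str, meth: bool,
                     rot: np.ndarray, org: np.ndarray, flip: bool,
                     first: bool) -> Residue:
        name = "5CM" if meth else f"D{base}"
        return Residue(chain, num, "", name, "mC" if meth else base, meth,
                       _residue_atoms(base, meth, rot, org, flip, first))

    chain_a = [
        make_residue("A", i + 1, b, m, frames[i][0], frames[i][1],
                     flip=False, first=(i == 0))
        for i, (b, m) in enumerate(bases)
    ]
    chain_b = []
    for j, (b, m) in enumerate(crick_bases):
        i = n - 1 - j  # paired Watson position
        chain_b.append(make_residue("B", j + 1, b, m, frames[i][0],
                                    frames[i][1], flip=True, first=(j == 0)))
    return Structure(structure_id, {"A": chain_a, "B": chain_b})


def methylation_slide_steps(sequence: str, crick_methylations: tuple[int, ...] = (),
                            slide: float = METHYLATION_SLIDE,
                            fiber: FiberParams | None = None
                            ) -> dict[int, FiberParams]:
    """Step overrides emulating the methylation-coupled conformational change.

    Every A-mC dinucleotide step (on either strand) receives an extra
    ``slide``; all other steps keep the fiber defaults.  This is the
    documented stand-in for the conformational effect of 5mC in complexes,
    where the largest stacking change occurs in the 5'-AC-3' context.
    """
    fiber = fiber or FiberParams()
    bases = parse_annotated_sequence(sequence)
    n = len(bases)
    targets: set[int] = set()
    for i in range(n - 1):  # Watson-strand A-mC at step i
        if bases[i][0] == "A" and bases[i + 1] == ("C", True):
            targets.add(i)
    for pos in crick_methylations:  # Crick-strand A-mC
        # Crick 5'->3' position pos pairs Watson position n+1-pos (1-based);
        # the A 5' of it on the Crick strand pairs Watson position n-pos+2.
        j = pos - 1
        if j >= 1:
            watson_hi = n - 1 - (j - 1)  # 0-based Watson index paired with A
            step = watson_hi - 1
            comp_prev = templates.COMPLEMENT[bases[watson_hi][0]]
            if 0 <= step < n - 1 and comp_prev == "A":
                targets.add(step)
    overrides = {}
    for step in targets:
        overrides[step] = dataclasses.replace(fiber, slide=fiber.slide + slide)
    return overrides


# ---------------------------------------------------------------------------
# ensembles and dwell times


def perturb_structure(s: Structure, sigma: float, n_models: int,
                      seed: int) -> Structure:
    """Multi-model copy with i.i.d. isotropic Gaussian atomic displacement."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    base = s.model(0)
    xyz = base.coords()
    models = [xyz + rng.normal(0.0, sigma, xyz.shape) for _ in range(n_models)]
    out = base
    out.set_coords(models[0])
    out.extra_models = models[1:]
    return out


def simulate_dwell_times(k_off: float, n: int, window: float = math.inf,
                         seed: int = 0) -> DwellTimeSet:
    """n exponential residence times at rate k_off, right-censored at window."""
    if k_off <= 0:
        raise ValueError("k_off must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.exponential(1.0 / k_off, n)
    if math.isfinite(window):
        censored = int(np.sum(draws >= window))
        events = draws[draws < window]
    else:
        censored, events = 0, draws
    return DwellTimeSet(times=events, window=window, n_censored=censored)


def make_distance_ensemble(mean: float, sd: float, n_models: int,
                           seed: int = 0) -> Structure:
    """Two-dummy-atom ensemble whose separation is Normal(mean, sd), > 0.

    Fixture generator for ensemble distance distributions (e.g. the
    arginine-to-C5 separations monitored in simulation trajectories).
    """
    if mean <= 0:
        raise ValueError("mean separation must be positive")
    rng = np.random.default_rng(seed)
    dists = rng.normal(mean, sd, n_models)
    while np.any(dists <= 0):  # truncate at zero by redraw
        bad = dists <= 0
        dists[bad] = rng.normal(mean, sd, int(bad.sum()))
    res1 = Residue("X", 1, "", "DUM", "none", False,
                   [Atom("X1", "C", np.zeros(3))])
    res2 = Residue("Y", 1, "", "DUM", "none", False,
                   [Atom("X2", "C", np.array([dists[0], 0.0, 0.0]))])
    s = Structure("distance-ensemble", {"X": [res1], "Y": [res2]})
    s.extra_models = [np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
                      for d in dists[1:]]
    return s
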