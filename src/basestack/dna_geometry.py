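"""Base reference frames, Watson-Crick pairing, and base-pair steps.

A *base frame* is the orthonormal frame obtained by rigid-body
least-squares (Kabsch) superposition of a standard planar base onto the
observed ring atoms.  A *pair frame* averages the Watson frame with the
Crick frame after flipping the latter 180 degrees about its x-axis (the
standard-reference-frame convention makes the two coincide for an ideal
pair).  A *step* joins two sequence-adjacent pairs; its mid-frame is the
orthonormalised average of the two pair frames and its z-axis serves as
the local helix axis onto which stacking polygons are projected.

Dinucleotide steps are classified into the 10 canonical strand-symmetric
classes (16 raw dinucleotides collapse under reverse complementation);
5-methylcytosine annotations are carried through classification, so an
A-mC step is a different class from A-C.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from . import templates
from .config import DEFAULT, Config
from .structure_io import Residue, Structure

# ---------------------------------------------------------------------------
# rigid-body fitting helpers


def kabsch(moving: np.ndarray, target: np.ndarray,
           min_rank: int = 2) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``moving`` onto ``target``.

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` mapping moving points onto
    the target.  ``min_rank=2`` accepts planar point sets (bases) but
    rejects collinear ones, for which the rotation is not unique.
    """
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    if moving.shape != target.shape or moving.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal shape")
    mc, tc = moving.mean(0), target.mean(0)
    h = (moving - mc).T @ (target - tc)
    u, sv, vt = np.linalg.svd(h)
    scale = sv[0] if sv[0] > 0 else 1.0
    if np.sum(sv > 1e-8 * scale) < min_rank:
        raise ValueError("degenerate (collinear) point set: rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = tc - rot @ mc
    diff = (moving @ rot.T + t) - target
    rmsd = float(np.sqrt((diff ** 2).sum() / len(moving)))
    return rot, t, rmsd


def orthonormalize_mean(*rotations: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (Frobenius) to the mean of rotations."""
    m = np.mean(rotations, axis=0)
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


# 180-degree rotation about x: maps a Crick-base frame onto the pair frame.
FLIP_X = np.diag([1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# domain types


@dataclasses.dataclass
class BaseFrame:
    residue: Residue
    origin: np.ndarray
    axes: np.ndarray  # columns x, y, z; proper orthonormal
    fit_rmsd: float


@dataclasses.dataclass
class BasePair:
    res_w: Residue
    res_c: Residue
    origin: np.ndarray
    axes: np.ndarray
    is_wc: bool
    c1c1_dist: float


@dataclasses.dataclass
class BaseStep:
    pair5: BasePair
    pair3: BasePair
    mid_origin: np.ndarray
    mid_axes: np.ndarray
    helix_axis: np.ndarray
    step_label: str
    class_label: str

    @property
    def index_label(self) -> str:
        return (f"{self.pair5.res_w.chain_id}{self.pair5.res_w.seq_num}-"
                f"{self.pair3.res_w.seq_num}")


# ---------------------------------------------------------------------------
# base frames


def fit_base_frame(res: Residue) -> BaseFrame:
    """Fit the standard base onto the observed ring atoms of ``res``."""
    base = res.ring_base
    if base not in templates.RING_ATOMS:
        raise ValueError(f"residue {res.label()} is not a nucleotide")
    names, tmpl = templates.ring_template(base)
    obs = []
    for n in names:
        a = res.atom(n)
        if a is None:
            raise ValueError(f"residue {res.label()} missing ring atom {n}")
        obs.append(a.pos)
    rot, t, rmsd = kabsch(tmpl, np.array(obs))
    return BaseFrame(res, origin=t, axes=rot, fit_rmsd=rmsd)


# ---------------------------------------------------------------------------
# pairing


def _sequence_complementary(a: str, b: str) -> bool:
    # mC pairs as C
    a = "C" if a == "mC" else a
    b = "C" if b == "mC" else b
    return templates.COMPLEMENT.get(a) == b


def detect_base_pairs(s: Structure, strand_a: str, strand_b: str,
                      cfg: Config = DEFAULT) -> list[BasePair]:
    """Detect Watson-Crick-style pairs between two strands geometrically.

    Criteria: C1'-C1' distance inside the configured window, base-frame
    origins within ``pair_origin_max`` after the pairing flip, and
    antiparallel z-axes.  Each residue joins at most one pair (greedy on
    origin distance); pairs are returned 5'->3' along ``strand_a``.
    """
    def frames(chain_id: str) -> list[BaseFrame]:
        out = []
        for res in s.chain(chain_id):
            if res.is_nucleotide:
                try:
                    out.append(fit_base_frame(res))
                except ValueError:
                    continue
        return out

    fa, fb = frames(strand_a), frames(strand_b)
    if not fa or not fb:
        raise ValueError(f"no usable nucleotides on strands {strand_a}/{strand_b}")

    candidates = []
    for i, fw in enumerate(fa):
        c1w = fw.residue.atom("C1'")
        for j, fc in enumerate(fb):
            c1c = fc.residue.atom("C1'")
            if c1w is None or c1c is None:
                continue
            d_c1 = float(np.linalg.norm(c1w.pos - c1c.pos))
            if not cfg.c1c1_min <= d_c1 <= cfg.c1c1_max:
                continue
            d_origin = float(np.linalg.norm(fw.origin - fc.origin))
            if d_origin > cfg.pair_origin_max:
                continue
            zdot = float(fw.axes[:, 2] @ fc.axes[:, 2])
            if zdot >= cfg.pair_zdot_max:
                continue
            candidates.append((d_origin, i, j, d_c1))

    used_a: set[int] = set()
    used_b: set[int] = set()
    chosen = []
    for d_origin, i, j, d_c1 in sorted(candidates):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        chosen.append((i, j, d_c1))
    if not chosen:
        raise ValueError(f"no base pairs found between {strand_a} and {strand_b}")

    pairs = []
    for i, j, d_c1 in sorted(chosen):  # 5'->3' along strand_a
        fw, fc = fa[i], fb[j]
        axes = orthonormalize_mean(fw.axes, fc.axes @ FLIP_X)
        origin = 0.5 * (fw.origin + fc.origin)
        pairs.append(BasePair(
            res_w=fw.residue, res_c=fc.residue, origin=origin, axes=axes,
            is_wc=_sequence_complementary(fw.residue.base_code,
                                          fc.residue.base_code),
            c1c1_dist=d_c1))
    return pairs


# ---------------------------------------------------------------------------
# step classification

_ANNOTATED = {"A", "C", "G", "T", "mC"}


def _parse_annotated(label: str) -> list[str]:
    """Split an annotated sequence string into base symbols ('mC' kept whole)."""
    out, i = [], 0
    while i < len(label):
        if label[i] == "m":
            if label[i:i + 2] != "mC":
                raise ValueError(f"bad methylation mark in {label!r}")
            out.append("mC")
            i += 2
        elif label[i] in "ACGT":
            out.append(label[i])
            i += 1
        else:
            raise ValueError(f"unknown base symbol {label[i]!r} in {label!r}")
    return out


def _canonical(pairs: list[tuple[str, bool, bool]]) -> str:
    """Canonical class label for a step.

    Each element is ``(base, methylated_on_read_strand,
    methylated_on_complement)`` with ``base`` an unannotated letter.  The
    reading (read strand vs reverse complement) whose plain dinucleotide is
    lexicographically smaller is canonical; methyl marks ride along — 'm'
    prefixes a methylated read-strand cytosine, a trailing apostrophe marks
    a base whose complement carries the methyl (e.g. ``AmC`` vs ``G'T``).
    """
    def render(p):
        base, mw, mc = p
        return ("m" if mw else "") + base + ("'" if mc else "")

    def plain(ps):
        return "".join(p[0] for p in ps)

    rc = [(templates.COMPLEMENT[b], mc, mw) for b, mw, mc in reversed(pairs)]
    a_plain, b_plain = plain(pairs), plain(rc)
    if a_plain < b_plain:
        chosen = pairs
    elif b_plain < a_plain:
        chosen = rc
    else:
        chosen = min(pairs, rc, key=lambda ps: "".join(render(p) for p in ps))
    return "".join(render(p) for p in chosen)


def classify_step(step_label: str) -> str:
    """Canonical strand-symmetric class of an annotated dinucleotide.

    A step and its reverse complement share a class; methylation marks are
    preserved, so ``AmC`` and ``AC`` classify differently while ``AC`` and
    ``GT`` classify identically.
    """
    bases = _parse_annotated(step_label)
    if len(bases) != 2:
        raise ValueError(f"step label must be two bases, got {step_label!r}")
    pairs = [("C", True, False) if b == "mC" else (b, False, False) for b in bases]
    return _canonical(pairs)


def classify_pairs(pair5: BasePair, pair3: BasePair) -> str:
    """Class of an observed step, honouring methylation on either strand."""
    def flags(p: BasePair) -> tuple[str, bool, bool]:
        b = p.res_w.base_code
        return ("C" if b == "mC" else b, p.res_w.base_code == "mC",
                p.res_c.base_code == "mC")
    return _canonical([flags(pair5), flags(pair3)])


def all_unmethylated_classes() -> list[str]:
    """The canonical classes of the 16 plain dinucleotides (10 classes)."""
    labels = {classify_step(a + b) for a, b in
              itertools.product("ACGT", repeat=2)}
    return sorted(labels)


# ---------------------------------------------------------------------------
# steps


def _step_label(pair5: BasePair, pair3: BasePair) -> str:
    def sym(res: Residue) -> str:
        return "mC" if res.base_code == "mC" else res.base_code
    return sym(pair5.res_w) + sym(pair3.res_w)


def build_steps(pairs: list[BasePair], cfg: Config = DEFAULT,
                global_axis: np.ndarray | None = None) -> list[BaseStep]:
    """One step per adjacent pair; mid-frame z is the local helix axis.

    With ``cfg.global_helix_axis`` (or an explicit ``global_axis``), every
    step instead uses the best-fit line through the pair origins — a
    sensitivity switch for strongly bent duplexes.
    """
    if len(pairs) < 2:
        return []
    axis_override = global_axis
    if axis_override is None and cfg.global_helix_axis and len(pairs) >= 2:
        origins = np.array([p.origin for p in pairs])
        centred = origins - origins.mean(0)
        _, _, vt = np.linalg.svd(centred)
        axis_override = vt[0]
        if axis_override @ (origins[-1] - origins[0]) < 0:
            axis_override = -axis_override

    steps = []
    for p5, p3 in zip(pairs[:-1], pairs[1:]):
        axes = orthonormalize_mean(p5.axes, p3.axes)
        origin = 0.5 * (p5.origin + p3.origin)
        axis = axes[:, 2] if axis_override is None else np.asarray(axis_override, float)
        axis = axis / np.linalg.norm(axis)
        steps.append(BaseStep(
            pair5=p5, pair3=p3, mid_origin=origin, mid_axes=axes,
            helix_axis=axis, step_label=_step_label(p5, p3),
            class_label=classify_pairs(p5, p3)))
    return steps
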