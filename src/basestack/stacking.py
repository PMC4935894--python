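"""Stacking-overlap area (S_OA) of base-pair steps.

S_OA quantifies base stacking between two neighbouring base pairs: the
heterocyclic-ring outlines of the four bases are orthogonally projected
onto the plane perpendicular to the local helix axis, and the overlap is
the summed area of intersection between the 5'-side and 3'-side ring
polygons (the four cross-step base combinations — two intra-strand, two
inter-strand).  Van der Waals radii and exocyclic atoms (including the
5-methyl group of mC) are excluded by construction, so methylation can
change S_OA only through the conformation it induces, never directly.

Polygon clipping is done with shapely; tests validate the areas against a
Monte-Carlo point-sampling oracle.
"""

from __future__ import annotations

import dataclasses

from shapely.geometry import Polygon

import numpy as np

from . import templates
from .config import DEFAULT, Config, log
from .dna_geometry import BaseStep, build_steps, detect_base_pairs
from .structure_io import Residue, Structure

# ---------------------------------------------------------------------------
# projection


@dataclasses.dataclass
class RingPolygon:
    residue: Residue
    vertices: np.ndarray  # (n, 2), outline order, Angstrom
    base_type: str  # 'purine' | 'pyrimidine'

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic orthonormal (u, v) basis of the plane normal to axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    seed = np.eye(3)[int(np.argmin(np.abs(axis)))]
    u = np.cross(axis, seed)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def project_ring(res: Residue, axis: np.ndarray, origin: np.ndarray,
                 basis: tuple[np.ndarray, np.ndarray] | None = None) -> RingPolygon:
    """Project the heterocyclic ring of ``res`` onto the plane ``axis``-perp.

    Exocyclic atoms (amino, keto, methyl — including the 5-methyl of mC)
    are excluded; vertices follow the ring outline.
    """
    base = res.ring_base
    if base not in templates.RING_ATOMS:
        raise ValueError(f"residue {res.label()} is not a nucleotide")
    u, v = basis if basis is not None else plane_basis(axis)
    pts = []
    for name in templates.RING_ATOMS[base]:
        a = res.atom(name)
        if a is None:
            raise ValueError(f"residue {res.label()} missing ring atom {name}")
        rel = a.pos - np.asarray(origin, float)
        pts.append((rel @ u, rel @ v))
    return RingPolygon(res, np.array(pts),
                       "purine" if base in templates.PURINES else "pyrimidine")


# ---------------------------------------------------------------------------
# clipping


def _as_polygon(p: RingPolygon, eps: float) -> Polygon | None:
    poly = Polygon(p.vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty or poly.area <= eps:
        return None
    return poly


def polygon_intersection_area(p: RingPolygon, q: RingPolygon,
                              cfg: Config = DEFAULT) -> float:
    """Area of the set intersection of two projected ring polygons (A^2)."""
    a = _as_polygon(p, cfg.clip_eps)
    b = _as_polygon(q, cfg.clip_eps)
    if a is None or b is None:
        log.warning("degenerate projected ring polygon; overlap set to 0")
        return 0.0
    return float(a.intersection(b).area)


# ---------------------------------------------------------------------------
# per-step overlap


@dataclasses.dataclass
class OverlapResult:
    step: BaseStep
    pair_areas: dict[str, float]  # keys: w5w3, w5c3, c5w3, c5c3
    s_oa: float
    class_label: str

    @property
    def intra_strand(self) -> float:
        return self.pair_areas["w5w3"] + self.pair_areas["c5c3"]

    @property
    def inter_strand(self) -> float:
        return self.pair_areas["w5c3"] + self.pair_areas["c5w3"]


def step_overlap(step: BaseStep, cfg: Config = DEFAULT) -> OverlapResult:
    """S_OA of one step: summed ring-overlap across the step mid-plane.

    The four bases are projected onto the plane through the step mid-frame
    origin with normal along the step's helix axis; the 2x2 cross-step
    combinations are intersected (bases within the same pair are never
    intersected with each other).  With ``cfg.union_overlap`` the area of
    (5'-pair union) intersect (3'-pair union) is reported instead of the
    pairwise sum.
    """
    basis = plane_basis(step.helix_axis)
    w5 = project_ring(step.pair5.res_w, step.helix_axis, step.mid_origin, basis)
    c5 = project_ring(step.pair5.res_c, step.helix_axis, step.mid_origin, basis)
    w3 = project_ring(step.pair3.res_w, step.helix_axis, step.mid_origin, basis)
    c3 = project_ring(step.pair3.res_c, step.helix_axis, step.mid_origin, basis)
    areas = {
        "w5w3": polygon_intersection_area(w5, w3, cfg),
        "w5c3": polygon_intersection_area(w5, c3, cfg),
        "c5w3": polygon_intersection_area(c5, w3, cfg),
        "c5c3": polygon_intersection_area(c5, c3, cfg),
    }
    if cfg.union_overlap:
        u5 = _as_polygon(w5, cfg.clip_eps).union(_as_polygon(c5, cfg.clip_eps))
        u3 = _as_polygon(w3, cfg.clip_eps).union(_as_polygon(c3, cfg.clip_eps))
        s_oa = float(u5.intersection(u3).area)
    else:
        s_oa = sum(areas.values())
    return OverlapResult(step=step, pair_areas=areas, s_oa=s_oa,
                         class_label=step.class_label)


def structure_soa_profile(s: Structure, strand_a: str, strand_b: str,
                          cfg: Config = DEFAULT) -> list[list[OverlapResult]]:
    """Per-step S_OA profiles, one list of OverlapResult per model."""
    profiles = []
    for sm in s.models():
        pairs = detect_base_pairs(sm, strand_a, strand_b, cfg)
        steps = build_steps(pairs, cfg)
        profiles.append([step_overlap(st, cfg) for st in steps])
    return profiles


def profile_table(profiles: list[list[OverlapResult]]) -> list[dict]:
    """Flatten profiles into report rows (one row per model and step)."""
    rows = []
    for mi, profile in enumerate(profiles):
        for si, r in enumerate(profile):
            rows.append({
                "model": mi + 1,
                "step_index": si + 1,
                "step_label": r.step.step_label,
                "class_label": r.class_label,
                "area_w5w3": r.pair_areas["w5w3"],
                "area_w5c3": r.pair_areas["w5c3"],
                "area_c5w3": r.pair_areas["c5w3"],
                "area_c5c3": r.pair_areas["c5c3"],
                "s_oa": r.s_oa,
            })
    return rows


# ---------------------------------------------------------------------------
# Monte-Carlo oracle (kept here for reuse by the acceptance pipeline; the
# production path above never calls it)


def points_in_polygon(vertices: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (ray-casting) membership test for a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    v1 = vertices
    v2 = np.roll(vertices, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(v1, v2):
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def monte_carlo_step_overlap(step: BaseStep, n_points: int = 1_000_000,
                             seed: int = 0) -> float:
    """Estimate a step's S_OA by uniform point sampling, no clipping library.

    For each cross-step base combination, points are thrown uniformly on
    the intersection of the two polygons' bounding boxes and membership in
    both rings is tested by the even-odd rule.  Serves as an independent
    check of the clipping route.
    """
    rng = np.random.default_rng(seed)
    basis = plane_basis(step.helix_axis)
    polys = {
        "w5": project_ring(step.pair5.res_w, step.helix_axis, step.mid_origin, basis),
        "c5": project_ring(step.pair5.res_c, step.helix_axis, step.mid_origin, basis),
        "w3": project_ring(step.pair3.res_w, step.helix_axis, step.mid_origin, basis),
        "c3": project_ring(step.pair3.res_c, step.helix_axis, step.mid_origin, basis),
    }
    total = 0.0
    for a, b in (("w5", "w3"), ("w5", "c3"), ("c5", "w3"), ("c5", "c3")):
        va, vb = polys[a].vertices, polys[b].vertices
        lo = np.maximum(va.min(0), vb.min(0))
        hi = np.minimum(va.max(0), vb.max(0))
        if np.any(hi <= lo):
            continue
        pts = rng.uniform(lo, hi, size=(n_points, 2))
        inside = points_in_polygon(va, pts) & points_in_polygon(vb, pts)
        box = float(np.prod(hi - lo))
        total += box * inside.mean()
    return total
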