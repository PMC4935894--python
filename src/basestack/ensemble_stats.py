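"""Aggregation of stacking-overlap values by dinucleotide step class and
comparison of methylated vs unmethylated S_OA profiles.

Box statistics follow the Tukey convention: quartiles by linear
interpolation (numpy type-7, noted in output metadata because box
statistics are convention-sensitive), whiskers at the most extreme
observation within 1.5 x IQR of the box.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stacking import OverlapResult

QUARTILE_CONVENTION = "linear interpolation (type-7)"


@dataclasses.dataclass
class EnsembleSummary:
    class_label: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    def row(self) -> dict:
        return {
            "class_label": self.class_label, "n": self.n,
            "median": self.median, "q1": self.q1, "q3": self.q3,
            "whisker_low": self.whisker_low, "whisker_high": self.whisker_high,
            "n_outliers": len(self.outliers),
            "quartile_convention": QUARTILE_CONVENTION,
        }


def _tukey(values: np.ndarray) -> tuple[float, float, float, float, float, list]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    wlo = float(inside.min()) if inside.size else float(q1)
    whi = float(inside.max()) if inside.size else float(q3)
    outliers = values[(values < lo_fence) | (values > hi_fence)].tolist()
    return float(med), float(q1), float(q3), wlo, whi, outliers


def summarize_by_class(results: list[OverlapResult],
                       per_structure_means: bool = False,
                       structure_ids: list | None = None
                       ) -> list[EnsembleSummary]:
    """Per-class five-number box summaries of pooled S_OA values.

    By default every step of every model contributes one observation.
    ``per_structure_means`` first averages within each structure id
    (sensitivity mode; requires ``structure_ids`` aligned with results).
    """
    if not results:
        raise ValueError("no overlap results to summarise")
    groups: dict[str, list[float]] = {}
    if per_structure_means:
        if structure_ids is None or len(structure_ids) != len(results):
            raise ValueError("per_structure_means requires aligned structure_ids")
        acc: dict[tuple[str, object], list[float]] = {}
        for r, sid in zip(results, structure_ids):
            acc.setdefault((r.class_label, sid), []).append(r.s_oa)
        for (label, _sid), vals in acc.items():
            groups.setdefault(label, []).append(float(np.mean(vals)))
    else:
        for r in results:
            groups.setdefault(r.class_label, []).append(r.s_oa)
    out = []
    for label in sorted(groups):
        vals = np.array(groups[label])
        med, q1, q3, wlo, whi, outliers = _tukey(vals)
        out.append(EnsembleSummary(label, len(vals), med, q1, q3, wlo, whi,
                                   outliers))
    return out


@dataclasses.dataclass
class ProfileDelta:
    step_index: int
    label_ref: str
    label_alt: str
    class_ref: str
    class_alt: str
    delta_soa: float
    methylation_step: bool  # labels differ only by methylation marks

    def row(self) -> dict:
        return dataclasses.asdict(self)


def _strip_methyl(label: str) -> str:
    return label.replace("mC", "C")


def compare_profiles(p_ref: list[OverlapResult],
                     p_alt: list[OverlapResult]) -> list[ProfileDelta]:
    """Per-step S_OA difference (alt - ref) of position-matched profiles.

    Profiles must come from duplexes of the same sequence up to methylation
    marks; steps whose labels differ only by methylation are flagged.
    """
    if len(p_ref) != len(p_alt):
        raise ValueError(f"profile length mismatch: {len(p_ref)} vs {len(p_alt)}")
    deltas = []
    for i, (r, a) in enumerate(zip(p_ref, p_alt)):
        lr, la = r.step.step_label, a.step.step_label
        if _strip_methyl(lr) != _strip_methyl(la):
            raise ValueError(
                f"step {i + 1}: labels {lr!r} vs {la!r} are not position-matched")
        meth = (lr != la) or (r.class_label != a.class_label)
        deltas.append(ProfileDelta(
            step_index=i + 1, label_ref=lr, label_alt=la,
            class_ref=r.class_label, class_alt=a.class_label,
            delta_soa=a.s_oa - r.s_oa, methylation_step=meth))
    return deltas


@dataclasses.dataclass
class ClassRank:
    class_label: str
    mean_abs_delta: float
    mean_delta: float
    n: int


def rank_methylation_sensitive_classes(deltas: list[ProfileDelta]
                                       ) -> list[ClassRank]:
    """Rank step classes by mean |delta S_OA| at methylation-bearing steps.

    Classes are keyed by the unmethylated base class of the alternate
    (methylated) profile so AC and AmC pool together; classes never touched
    by methylation rank at 0.
    """
    if not deltas:
        raise ValueError("no profile deltas supplied")
    groups: dict[str, list[float]] = {}
    for d in deltas:
        base_class = _strip_methyl(d.class_ref).replace("'", "")
        groups.setdefault(base_class, [])
        if d.methylation_step:
            groups[base_class].append(d.delta_soa)
    ranks = []
    for label, vals in groups.items():
        arr = np.array(vals) if vals else np.zeros(0)
        ranks.append(ClassRank(
            label,
            float(np.abs(arr).mean()) if arr.size else 0.0,
            float(arr.mean()) if arr.size else 0.0,
            len(vals)))
    ranks.sort(key=lambda c: (-c.mean_abs_delta, c.class_label))
    return ranks
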