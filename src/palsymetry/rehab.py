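"""Region-based facial-motion evaluation and rehabilitation progress.

The clinical quantity is the per-vertex squared Euclidean displacement between
a neutral-expression mesh ``S0`` and the mesh at the end range of a prescribed
movement ``S1``, aggregated over clinician-defined vertex regions (typically
quadrants or left/right halves, because palsy affects the two sides and the
upper/lower face unequally).  Progress across sessions is the signed
difference of a session's evaluation from the pre-rehabilitation baseline:
a positive value means the region moves more than it did at baseline.

Both meshes must live in model space (the fitter produces pose-free meshes),
so rigid head motion between captures does not contaminate the measure.  A
deliberate diagnostic of this requirement: a pure global translation of S1
inflates every region's mean evaluation by the same squared amount.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DimensionMismatchError,
    RegionConfigError,
    UndefinedAsymmetryError,
)
from .model import FaceMesh, MorphableModel

__all__ = [
    "RegionIndex",
    "RegionStats",
    "Evaluation",
    "RehabSeries",
    "motion_magnitude",
    "rehab_progress",
    "asymmetry_index",
    "attenuation_from_asymmetry",
    "load_regions",
    "quadrant_regions",
]


@dataclass(frozen=True)
class RegionIndex:
    """A named set of model vertex indices (unique, non-empty)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).reshape(-1)
        if idx.size == 0:
            raise RegionConfigError(f"region {self.name!r} is empty")
        if np.unique(idx).size != idx.size:
            raise RegionConfigError(f"region {self.name!r} has duplicate indices")
        if idx.min() < 0:
            raise RegionConfigError(f"region {self.name!r} has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


class RegionStats(NamedTuple):
    e_sum: float   # summed squared displacement, squared model units
    e_mean: float  # mean squared displacement per vertex
    n_vertices: int


@dataclass
class Evaluation:
    """Motion statistics of one session, per region."""

    session_id: str
    stats: dict[str, RegionStats]
    units: str = "model-units^2"
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, st in self.stats.items():
            if st.e_sum < 0 or st.e_mean < 0:
                raise ValueError(f"region {name!r} has negative evaluation")
            if abs(st.e_sum - st.e_mean * st.n_vertices) > 1e-9 * max(1.0, st.e_sum):
                raise ValueError(f"region {name!r}: e_sum != e_mean * n_vertices")

    def region_names(self) -> frozenset[str]:
        return frozenset(self.stats)


@dataclass
class RehabSeries:
    """Ordered evaluations; the first session is the pre-rehab baseline."""

    evaluations: list[Evaluation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.session_id for e in self.evaluations]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate session ids: {ids}")


def motion_magnitude(
    s0: FaceMesh,
    s1: FaceMesh,
    regions: Sequence[RegionIndex],
    session_id: str = "",
    units: str = "model-units^2",
    provenance: str = "",
) -> Evaluation:
    """Per-region squared displacement between neutral and end-range meshes."""
    if s0.vertex_count != s1.vertex_count:
        raise DimensionMismatchError(
            f"S0 has {s0.vertex_count} vertices but S1 has {s1.vertex_count}"
        )
    disp_sq = np.sum((s1.vertices - s0.vertices) ** 2, axis=0)  # (m,)
    m = disp_sq.size
    stats = {}
    for region in regions:
        if region.indices.max() >= m:
            raise IndexError(
                f"region {region.name!r} indexes vertex {region.indices.max()} "
                f"but the mesh has {m} vertices"
            )
        vals = disp_sq[region.indices]
        stats[region.name] = RegionStats(
            e_sum=float(vals.sum()), e_mean=float(vals.mean()), n_vertices=len(region)
        )
    return Evaluation(
        session_id=session_id, stats=stats, units=units, provenance=provenance
    )


def rehab_progress(series: RehabSeries) -> pd.DataFrame:
    """Signed change of each region's mean evaluation from baseline.

    Returns one row per (later session, region) with columns ``session``,
    ``region``, ``e_mean``, ``baseline_e_mean`` and ``progress`` where
    ``progress = e_mean - baseline_e_mean``; positive values indicate a gain
    in motion over the pre-rehabilitation baseline.
    """
    evals = series.evaluations
    if len(evals) < 2:
        raise ValueError("rehab_progress needs a baseline plus at least one session")
    baseline = evals[0]
    names = baseline.region_names()
    rows = []
    for ev in evals[1:]:
        if ev.region_names() != names:
            raise RegionConfigError(
                f"session {ev.session_id!r} regions {sorted(ev.region_names())} "
                f"differ from baseline {sorted(names)}"
            )
        for region in sorted(names):
            e_mean = ev.stats[region].e_mean
            base = baseline.stats[region].e_mean
            rows.append(
                {
                    "session": ev.session_id,
                    "region": region,
                    "e_mean": e_mean,
                    "baseline_e_mean": base,
                    "progress": e_mean - base,
                }
            )
    return pd.DataFrame(
        rows, columns=["session", "region", "e_mean", "baseline_e_mean", "progress"]
    )


def asymmetry_index(
    evaluation: Evaluation, left_region: str = "left", right_region: str = "right"
) -> float:
    """Normalized left/right motion imbalance in [-1, 1].

    Defined as ``(E_right - E_left) / (E_right + E_left)`` on the regions'
    mean evaluations: 0 is symmetric motion, +1 fully right-lateralized,
    -1 fully left-lateralized.  Raises :class:`UndefinedAsymmetryError` when
    both regions show zero motion (0/0 carries no information and silently
    returning 0 would fake perfect symmetry).
    """
    for name in (left_region, right_region):
        if name not in evaluation.stats:
            raise RegionConfigError(f"evaluation has no region {name!r}")
    left = evaluation.stats[left_region].e_mean
    right = evaluation.stats[right_region].e_mean
    if left + right <= 0:
        raise UndefinedAsymmetryError(
            "both regions show zero motion; the asymmetry index is undefined"
        )
    return (right - left) / (right + left)


def attenuation_from_asymmetry(index: float) -> float:
    """Invert the index for a one-sided attenuation model.

    If the affected side's displacements are the healthy side's scaled by
    ``rho``, its evaluation carries ``rho**2`` of the healthy evaluation and
    the magnitude of the index is ``(1 - rho**2) / (1 + rho**2)``; solving
    gives ``rho = sqrt((1 - |a|) / (1 + |a|))``.
    """
    a = abs(float(index))
    if a > 1:
        raise ValueError(f"asymmetry index must lie in [-1, 1], got {index}")
    return float(np.sqrt((1.0 - a) / (1.0 + a)))


# ---------------------------------------------------------------------------
# Region configuration
# ---------------------------------------------------------------------------

_CLAUSE_RE = re.compile(r"^\s*([xyz])\s*([<>])\s*(-?\d+(?:\.\d+)?)\s*$")

#: Exclusion band around a rule threshold, in model units.  Vertices within
#: the band (e.g. exact midline vertices under an ``x < 0`` rule) belong to
#: neither side, which keeps left/right regions strictly disjoint.
RULE_EPS = 1e-9


def _resolve_rule(rule: str, rel: np.ndarray) -> np.ndarray:
    """Boolean vertex mask for a rule like ``"x < 0"`` or ``"x > 0 and y < 0"``.

    Coordinates are taken relative to the mesh centroid.
    """
    mask = np.ones(rel.shape[1], dtype=bool)
    for clause in rule.split("and"):
        match = _CLAUSE_RE.match(clause)
        if not match:
            raise RegionConfigError(f"cannot parse region rule clause {clause!r}")
        axis = "xyz".index(match.group(1))
        threshold = float(match.group(3))
        if match.group(2) == "<":
            mask &= rel[axis] < threshold - RULE_EPS
        else:
            mask &= rel[axis] > threshold + RULE_EPS
    return mask


def load_regions(path: str | Path, model: MorphableModel) -> list[RegionIndex]:
    """Resolve a YAML region config against a model.

    The file maps region names either to explicit vertex index lists or to
    half-plane rules evaluated on centroid-relative mean-shape coordinates::

        regions:
          left:        {rule: "x < 0"}
          upper_right: {rule: "x > 0 and y > 0"}
          custom:      {indices: [0, 1, 2]}

    A region that resolves to no vertices raises :class:`RegionConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "regions" not in raw:
        raise RegionConfigError(f"{path}: expected a top-level 'regions' mapping")
    rel = model.mean_shape - model.mean_shape.mean(axis=1, keepdims=True)
    out = []
    for name, entry in raw["regions"].items():
        if not isinstance(entry, dict):
            raise RegionConfigError(f"{path}: region {name!r} must be a mapping")
        if "indices" in entry:
            idx = np.asarray(entry["indices"], dtype=np.int64)
            if idx.size and idx.max() >= model.vertex_count:
                raise RegionConfigError(
                    f"{path}: region {name!r} indexes beyond the model's "
                    f"{model.vertex_count} vertices"
                )
        elif "rule" in entry:
            idx = np.flatnonzero(_resolve_rule(str(entry["rule"]), rel))
        else:
            raise RegionConfigError(
                f"{path}: region {name!r} needs either 'indices' or 'rule'"
            )
        if idx.size == 0:
            raise RegionConfigError(f"{path}: region {name!r} resolved to no vertices")
        out.append(RegionIndex(name=str(name), indices=idx))
    return out


def quadrant_regions(model: MorphableModel) -> list[RegionIndex]:
    """Left/right halves and the four quadrants, split at the centroid.

    Vertices on a splitting plane (within :data:`RULE_EPS`) are excluded so
    mirrored regions stay strictly disjoint on symmetric meshes.
    """
    rel = model.mean_shape - model.mean_shape.mean(axis=1, keepdims=True)
    rules = {
        "left": "x < 0",
        "right": "x > 0",
        "upper_left": "x < 0 and y > 0",
        "upper_right": "x > 0 and y > 0",
        "lower_left": "x < 0 and y < 0",
        "lower_right": "x > 0 and y < 0",
    }
    out = []
    for name, rule in rules.items():
        idx = np.flatnonzero(_resolve_rule(rule, rel))
        if idx.size == 0:
            raise RegionConfigError(f"quadrant region {name!r} is empty on this model")
        out.append(RegionIndex(name=name, indices=idx))
    return out
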