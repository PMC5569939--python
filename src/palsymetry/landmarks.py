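"""Landmark schemes, .pts I/O, hybrid merging and ocular-scaled evaluation.

The default scheme is the 68-point iBUG convention.  Errors are reported as a
percentage of the interocular distance (IOD) so that faces of different image
sizes are comparable; the IOD is the distance between the two eye-subset
centroids of the ground-truth set.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateGeometryError,
    PtsFormatError,
    SchemeMismatchError,
)

__all__ = [
    "LandmarkScheme",
    "LandmarkSet",
    "ibug_68",
    "load_scheme",
    "merge_hybrid",
    "read_pts",
    "write_pts",
    "interocular_distance",
    "ocular_rmse",
    "per_landmark_error",
    "per_subject_report",
]

_REQUIRED_SUBSETS = ("mouth", "left_eye", "right_eye")


@dataclass(frozen=True, eq=False)
class LandmarkScheme:
    """A named, ordered landmark convention with index subsets.

    ``subsets`` must at minimum define ``mouth``, ``left_eye`` and
    ``right_eye``; the eye subsets must be non-empty and disjoint.
    ``correspondence`` optionally binds each landmark to a model vertex index.
    """

    name: str
    size: int
    subsets: dict[str, np.ndarray] = field(default_factory=dict)
    correspondence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"scheme size must be positive, got {self.size}")
        clean = {}
        for key, idx in self.subsets.items():
            arr = np.asarray(idx, dtype=np.int64).reshape(-1)
            if arr.size and (arr.min() < 0 or arr.max() >= self.size):
                raise ValueError(f"subset {key!r} has indices outside [0, {self.size})")
            clean[key] = arr
        for key in _REQUIRED_SUBSETS:
            if key not in clean or clean[key].size == 0:
                raise ValueError(f"scheme must define a non-empty {key!r} subset")
        if np.intersect1d(clean["left_eye"], clean["right_eye"]).size:
            raise ValueError("left_eye and right_eye subsets must be disjoint")
        object.__setattr__(self, "subsets", clean)
        if self.correspondence is not None:
            corr = np.asarray(self.correspondence, dtype=np.int64).reshape(-1)
            if corr.size != self.size:
                raise ValueError(
                    f"correspondence has {corr.size} entries, scheme size is {self.size}"
                )
            if np.unique(corr).size != corr.size:
                raise ValueError("correspondence indices must be unique")
            object.__setattr__(self, "correspondence", corr)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkScheme):
            return NotImplemented
        if (self.name, self.size) != (other.name, other.size):
            return False
        if set(self.subsets) != set(other.subsets):
            return False
        if any(not np.array_equal(self.subsets[k], other.subsets[k]) for k in self.subsets):
            return False
        if (self.correspondence is None) != (other.correspondence is None):
            return False
        return self.correspondence is None or np.array_equal(
            self.correspondence, other.correspondence
        )

    __hash__ = object.__hash__

    def subset(self, name: str) -> np.ndarray:
        if name not in self.subsets:
            raise KeyError(f"scheme {self.name!r} has no subset {name!r}")
        return self.subsets[name]

    def with_correspondence(self, corr: Sequence[int]) -> "LandmarkScheme":
        return LandmarkScheme(
            name=self.name, size=self.size, subsets=dict(self.subsets),
            correspondence=np.asarray(corr, dtype=np.int64),
        )


@dataclass
class LandmarkSet:
    """Ordered 2D points bound to a scheme.  ``points`` has shape (n, 2)."""

    scheme: LandmarkScheme
    points: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {self.points.shape}")
        if self.points.shape[0] != self.scheme.size:
            raise ValueError(
                f"{self.points.shape[0]} points but scheme {self.scheme.name!r} "
                f"has size {self.scheme.size}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")


def _scheme_from_mapping(raw: dict) -> LandmarkScheme:
    return LandmarkScheme(
        name=str(raw["name"]),
        size=int(raw["size"]),
        subsets={k: np.asarray(v, dtype=np.int64) for k, v in raw.get("subsets", {}).items()},
    )


def ibug_68() -> LandmarkScheme:
    """The packaged 68-point iBUG scheme (mouth 48-67, eyes 36-41 / 42-47)."""
    ref = importlib.resources.files("palsymetry.data").joinpath("ibug68.yaml")
    return _scheme_from_mapping(yaml.safe_load(ref.read_text()))


def load_scheme(path: str | Path) -> LandmarkScheme:
    """Load a scheme definition from a YAML file (same layout as ibug68.yaml)."""
    return _scheme_from_mapping(yaml.safe_load(Path(path).read_text()))


def merge_hybrid(
    primary: LandmarkSet, secondary: LandmarkSet, subset_name: str = "mouth"
) -> LandmarkSet:
    """Combine two fitters' outputs: the named subset (default the mouth) is
    taken from ``secondary``, every other landmark from ``primary``.

    This reflects the common situation where one fitter is more reliable on
    the mouth while another is more accurate elsewhere on the face.
    """
    if primary.scheme is not secondary.scheme and primary.scheme != secondary.scheme:
        raise SchemeMismatchError(
            f"cannot merge landmark sets on schemes "
            f"{primary.scheme.name!r} and {secondary.scheme.name!r}"
        )
    idx = primary.scheme.subset(subset_name)
    points = primary.points.copy()
    points[idx] = secondary.points[idx]
    label = (
        f"hybrid({primary.source_label or 'primary'}+"
        f"{secondary.source_label or 'secondary'}:{subset_name})"
    )
    return LandmarkSet(scheme=primary.scheme, points=points, source_label=label)


# ---------------------------------------------------------------------------
# .pts I/O (iBUG dialect)
# ---------------------------------------------------------------------------

def read_pts(path: str | Path, scheme: LandmarkScheme | None = None) -> LandmarkSet:
    """Read an iBUG-style .pts file.

    Expected dialect: ``version: 1``, ``n_points: N``, then the coordinates
    inside a brace-delimited block.  CRLF line endings and trailing whitespace
    are tolerated.  A declared count that does not match the number of
    coordinate lines raises :class:`PtsFormatError` with the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    n_points = None
    coords: list[tuple[float, float]] = []
    in_block = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("version:"):
            continue
        if line.startswith("n_points:"):
            try:
                n_points = int(line.split(":", 1)[1])
            except ValueError as exc:
                raise PtsFormatError(f"{path}:{lineno}: bad n_points line {line!r}") from exc
            continue
        if line == "{":
            in_block = True
            continue
        if line == "}":
            in_block = False
            continue
        if in_block:
            parts = line.split()
            if len(parts) != 2:
                raise PtsFormatError(
                    f"{path}:{lineno}: expected 'x y' coordinate pair, got {line!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise PtsFormatError(
                    f"{path}:{lineno}: non-numeric coordinates {line!r}"
                ) from exc
    if n_points is None:
        raise PtsFormatError(f"{path}: missing n_points header")
    if len(coords) != n_points:
        raise PtsFormatError(
            f"{path}: header declares n_points: {n_points} but "
            f"{len(coords)} coordinate lines were found"
        )
    if scheme is None:
        if n_points == 68:
            scheme = ibug_68()
        else:
            raise PtsFormatError(
                f"{path}: {n_points} points; pass an explicit scheme for "
                "non-68-point files"
            )
    return LandmarkSet(scheme=scheme, points=np.asarray(coords), source_label=str(path))


def write_pts(landmark_set: LandmarkSet, path: str | Path) -> None:
    """Write a .pts file; coordinates keep 6 decimals (round trip to 1e-6)."""
    lines = ["version: 1", f"n_points: {landmark_set.scheme.size}", "{"]
    for u, v in landmark_set.points:
        lines.append(f"{u:.6f} {v:.6f}")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ocular-scaled evaluation
# ---------------------------------------------------------------------------

def interocular_distance(landmark_set: LandmarkSet) -> float:
    """Distance between the centroids of the two eye subsets, in pixels.

    Centroids (rather than single corner landmarks) keep the normalizer
    robust to noise on any one eye point.
    """
    left = landmark_set.points[landmark_set.scheme.subset("left_eye")].mean(axis=0)
    right = landmark_set.points[landmark_set.scheme.subset("right_eye")].mean(axis=0)
    iod = float(np.linalg.norm(right - left))
    if iod <= 0:
        raise DegenerateGeometryError(
            "eye centroids coincide; interocular distance is undefined"
        )
    return iod


def _check_same_scheme(pred: LandmarkSet, truth: LandmarkSet) -> None:
    if pred.scheme is not truth.scheme and pred.scheme != truth.scheme:
        raise SchemeMismatchError(
            f"prediction uses scheme {pred.scheme.name!r} but ground truth "
            f"uses {truth.scheme.name!r}"
        )


def per_landmark_error(pred: LandmarkSet, truth: LandmarkSet) -> np.ndarray:
    """Per-point Euclidean error as percent of the truth IOD (length n)."""
    _check_same_scheme(pred, truth)
    iod = interocular_distance(truth)
    err = np.linalg.norm(pred.points - truth.points, axis=1)
    return 100.0 * err / iod


def ocular_rmse(
    pred: LandmarkSet,
    truth: LandmarkSet,
    indices: Sequence[int] | None = None,
) -> float:
    """Root-mean-square landmark error as percent of the truth IOD.

    ``indices`` restricts the evaluation to a subset of landmarks (e.g. the
    mouth); by default all landmarks contribute.  Equals the quadratic mean of
    :func:`per_landmark_error` over the selected indices.
    """
    errors = per_landmark_error(pred, truth)
    if indices is not None:
        errors = errors[np.asarray(indices, dtype=np.int64)]
    return float(np.sqrt(np.mean(errors**2)))


def per_subject_report(
    pairs: Iterable[tuple[LandmarkSet, LandmarkSet]],
    subjects: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate ocular RMSE per subject plus a pooled total.

    Parameters
    ----------
    pairs : iterable of (pred, truth)
        One entry per evaluated image.
    subjects : sequence of str, optional
        Subject label per pair; consecutive integers by default.  Pairs that
        share a label are pooled into one row.

    Returns
    -------
    DataFrame with columns ``subject``, ``ocular_rmse`` and ``n_landmarks``.
    The final ``total`` row pools the squared normalized errors of every
    landmark of every image (the headline figure); its ``subject_mean`` column
    carries the unweighted mean of the per-subject values as a secondary
    summary.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("per_subject_report requires at least one (pred, truth) pair")
    if subjects is None:
        subjects = [str(i + 1) for i in range(len(pairs))]
    subjects = [str(s) for s in subjects]
    if len(subjects) != len(pairs):
        raise ValueError("subjects must have one label per pair")

    sq_by_subject: dict[str, list[np.ndarray]] = {}
    for label, (pred, truth) in zip(subjects, pairs):
        errors = per_landmark_error(pred, truth)
        sq_by_subject.setdefault(label, []).append(errors**2)

    rows = []
    all_sq: list[np.ndarray] = []
    for label, chunks in sq_by_subject.items():
        sq = np.concatenate(chunks)
        all_sq.append(sq)
        rows.append(
            {
                "subject": label,
                "ocular_rmse": float(np.sqrt(np.mean(sq))),
                "n_landmarks": int(sq.size),
                "subject_mean": np.nan,
            }
        )
    pooled = np.concatenate(all_sq)
    rows.append(
        {
            "subject": "total",
            "ocular_rmse": float(np.sqrt(np.mean(pooled))),
            "n_landmarks": int(pooled.size),
            "subject_mean": float(np.mean([r["ocular_rmse"] for r in rows])),
        }
    )
    return pd.DataFrame(rows, columns=["subject", "ocular_rmse", "n_landmarks", "subject_mean"])


def read_landmark_csv(path: str | Path, scheme: LandmarkScheme | None = None) -> dict[str, LandmarkSet]:
    """Read a long-format CSV (columns subject, landmark, u, v) into sets."""
    frame = pd.read_csv(path)
    scheme = scheme or ibug_68()
    out = {}
    for subject, grp in frame.groupby("subject", sort=True):
        grp = grp.sort_values("landmark")
        out[str(subject)] = LandmarkSet(
            scheme=scheme,
            points=grp[["u", "v"]].to_numpy(dtype=np.float64),
            source_label=str(path),
        )
    return out


def write_landmark_csv(sets: dict[str, LandmarkSet], path: str | Path) -> None:
    """Write landmark sets to a long-format CSV (subject, landmark, u, v)."""
    rows = []
    for subject, lm in sets.items():
        for i, (u, v) in enumerate(lm.points):
            rows.append({"subject": subject, "landmark": i, "u": u, "v": v})
    pd.DataFrame(rows).to_csv(path, index=False)
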