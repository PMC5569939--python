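"""Fit a morphable model to observed 2D landmarks.

The objective is the squared 2D distance between the observed landmarks and
the projected model landmarks, jointly over pose (scale, rotation, image-plane
translation) and shape coefficients, with a ridge penalty on the coefficients:

    min_{f,R,t,a}  || s_obs - f P R S(a)[corr] - t ||^2
                   + lambda_id ||a_id||^2 + lambda_exp ||a_exp||^2

Because the projection is linear in the coefficients at fixed pose, and the
pose sub-problem has a closed-form scaled-orthographic solution at fixed
shape, the solver alternates the two exact sub-solves (block-coordinate
descent).  Each accepted iterate can only lower the reported residual; if a
floating-point effect would raise it, the previous iterate is kept and the
iteration stops, so the residual trace is non-increasing by construction.

Residuals are reported as ocular-scaled reprojection RMSE (percent of the
observed interocular distance) whenever the observations carry a scheme with
eye subsets, and as plain pixel RMSE otherwise.  The scaling is a constant
factor per fit, so it does not change the trajectory of the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, RankDeficiencyError
from .landmarks import LandmarkSet, interocular_distance
from .model import (
    FaceMesh,
    MorphableModel,
    ShapeCoefficients,
    construct_shape,
)
from .pose import P_ORTHO, Pose, estimate_pose, project

__all__ = [
    "FitConfig",
    "FitResult",
    "validate_correspondence",
    "solve_coefficients",
    "fit",
    "reprojection_rmse",
]


@dataclass(frozen=True)
class FitConfig:
    """Solver settings.

    ``tol`` is the relative change of the residual between iterations below
    which the fit is declared converged.  The ridge weights act on
    standard-deviation-unit coefficients, so their natural magnitude is O(1);
    the defaults apply mild shrinkage that keeps the normal equations well
    conditioned with 68 landmarks and moderately sized bases.
    """

    max_iters: int = 50
    tol: float = 1e-8
    lambda_id: float = 1e-3
    lambda_exp: float = 1e-3
    init_pose: Pose | None = None

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be a positive integer")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.lambda_id < 0 or self.lambda_exp < 0:
            raise ValueError("ridge weights must be non-negative")


@dataclass
class FitResult:
    """Solution of one landmark fit: pose, coefficients and residual history."""

    pose: Pose
    coeffs: ShapeCoefficients
    residual_trace: list[float]
    converged: bool
    n_iters: int
    residual_unit: str = "%IOD"

    @property
    def final_residual(self) -> float:
        return self.residual_trace[-1]

    def to_report(self) -> str:
        """Flat key-value text report (one ``key = value`` pair per line)."""
        lines = [
            f"pose.scale = {self.pose.scale!r}",
            f"pose.pitch = {self.pose.pitch!r}",
            f"pose.yaw = {self.pose.yaw!r}",
            f"pose.roll = {self.pose.roll!r}",
            f"pose.tx = {self.pose.translation[0]!r}",
            f"pose.ty = {self.pose.translation[1]!r}",
            "alpha_id = " + " ".join(repr(v) for v in self.coeffs.alpha_id),
            "alpha_exp = " + " ".join(repr(v) for v in self.coeffs.alpha_exp),
            f"converged = {self.converged}",
            f"n_iters = {self.n_iters}",
            f"residual_unit = {self.residual_unit}",
            "residual_trace = " + " ".join(repr(v) for v in self.residual_trace),
        ]
        return "\n".join(lines) + "\n"

    def write_report(self, path: str | Path) -> None:
        Path(path).write_text(self.to_report())


def validate_correspondence(corr: np.ndarray, vertex_count: int, n_landmarks: int | None = None) -> np.ndarray:
    """Validate a landmark-to-vertex index vector and return it as int64."""
    corr = np.asarray(corr, dtype=np.int64).reshape(-1)
    if n_landmarks is not None and corr.size != n_landmarks:
        raise DimensionMismatchError(
            f"correspondence has {corr.size} entries for {n_landmarks} landmarks"
        )
    if corr.size and (corr.min() < 0 or corr.max() >= vertex_count):
        raise DimensionMismatchError(
            f"correspondence indices outside [0, {vertex_count})"
        )
    if np.unique(corr).size != corr.size:
        raise DimensionMismatchError("correspondence indices must be unique")
    return corr


def _observed_points(observed: LandmarkSet | np.ndarray) -> np.ndarray:
    if isinstance(observed, LandmarkSet):
        return observed.points
    pts = np.asarray(observed, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"observations must have shape (n, 2), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("observations contain non-finite coordinates")
    return pts


def _restricted_basis(model: MorphableModel, corr: np.ndarray) -> np.ndarray:
    """Stacked (3, n, K) basis fields at the corresponded vertices, scaled to
    model units (columns multiplied by their standard deviations)."""
    k_total = model.k_id + model.k_exp
    n = corr.size
    out = np.empty((3, n, k_total))
    for j in range(model.k_id):
        out[:, :, j] = (model.id_scale[j] * model.id_basis[:, j]).reshape(-1, 3).T[:, corr]
    for j in range(model.k_exp):
        out[:, :, model.k_id + j] = (
            model.exp_scale[j] * model.exp_basis[:, j]
        ).reshape(-1, 3).T[:, corr]
    return out


def solve_coefficients(
    model: MorphableModel,
    pose: Pose,
    observed: LandmarkSet | np.ndarray,
    corr: np.ndarray,
    lambda_id: float = 1e-3,
    lambda_exp: float = 1e-3,
) -> ShapeCoefficients:
    """Exact ridge minimizer of the reprojection error at a fixed pose.

    The projected landmark positions are affine in the coefficients, so the
    penalized problem is one linear least-squares system over the concatenated
    (alpha_id, alpha_exp).  With both ridge weights zero a singular system
    raises :class:`RankDeficiencyError` advising a positive lambda.
    """
    obs = _observed_points(observed)
    corr = validate_correspondence(corr, model.vertex_count, obs.shape[0])
    a2 = pose.scale * (P_ORTHO @ pose.rotation())  # (2, 3)

    fields = _restricted_basis(model, corr)  # (3, n, K)
    k_total = fields.shape[2]
    # design[2n, K]: projection of each basis field, landmark-major (u0,v0,u1,...)
    design = np.einsum("ij,jnk->ink", a2, fields).reshape(2 * corr.size, k_total, order="F")
    base = (a2 @ model.mean_shape[:, corr]) + pose.translation[:, None]
    rhs = (obs.T - base).reshape(-1, order="F")

    penalty = np.concatenate(
        [np.full(model.k_id, lambda_id), np.full(model.k_exp, lambda_exp)]
    )
    normal = design.T @ design + np.diag(penalty)
    if lambda_id == 0 and lambda_exp == 0:
        if np.linalg.matrix_rank(design) < k_total:
            raise RankDeficiencyError(
                "coefficient system is singular with zero ridge weights; "
                "use a positive lambda_id/lambda_exp"
            )
    try:
        sol = np.linalg.solve(normal, design.T @ rhs)
    except np.linalg.LinAlgError as exc:
        raise RankDeficiencyError(
            "coefficient system is singular; use a positive lambda"
        ) from exc
    return ShapeCoefficients(sol[: model.k_id], sol[model.k_id :])


def _landmarks3d(model: MorphableModel, coeffs: ShapeCoefficients, corr: np.ndarray) -> np.ndarray:
    return construct_shape(model, coeffs).vertices[:, corr]


def _rms(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((pred - obs) ** 2, axis=1))))


def fit(
    model: MorphableModel,
    observed: LandmarkSet | np.ndarray,
    corr: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Alternating pose/coefficient fit of the model to observed landmarks.

    Initialization is deterministic: coefficients start at zero (the mean
    face) and, unless ``config.init_pose`` is given, the pose starts from the
    closed-form estimate against the mean-face landmarks.  Each iteration
    re-estimates the pose at the current shape, then re-solves the
    coefficients at that pose, and records the residual.

    ``corr`` may be omitted when ``observed`` is a :class:`LandmarkSet` whose
    scheme carries a model correspondence.
    """
    config = config or FitConfig()
    obs = _observed_points(observed)
    if corr is None:
        if isinstance(observed, LandmarkSet) and observed.scheme.correspondence is not None:
            corr = observed.scheme.correspondence
        else:
            raise ValueError("corr is required when the scheme carries no correspondence")
    corr = validate_correspondence(corr, model.vertex_count, obs.shape[0])
    if corr.size < 3:
        raise ValueError("fitting requires at least 3 correspondences")
    k_total = model.k_id + model.k_exp
    if 2 * corr.size <= k_total:
        warnings.warn(
            f"{corr.size} landmarks constrain {k_total} coefficients; "
            "the fit is under-determined and relies on the ridge penalty",
            stacklevel=2,
        )

    if isinstance(observed, LandmarkSet):
        scale_factor = 100.0 / interocular_distance(observed)
        unit = "%IOD"
    else:
        scale_factor = 1.0
        unit = "px"

    coeffs = model.zero_coefficients()
    pose = config.init_pose
    if pose is None:
        pose = estimate_pose(_landmarks3d(model, coeffs, corr), obs).pose

    trace: list[float] = []
    best = float("inf")
    converged = False
    n_iters = 0
    for _ in range(config.max_iters):
        # (a) pose at current shape -- accept only if it does not hurt
        lm3 = _landmarks3d(model, coeffs, corr)
        candidate = estimate_pose(lm3, obs).pose
        if _rms(project(lm3, candidate), obs) <= _rms(project(lm3, pose), obs):
            pose = candidate
        # (b) coefficients at current pose
        new_coeffs = solve_coefficients(
            model, pose, obs, corr, config.lambda_id, config.lambda_exp
        )
        residual = scale_factor * _rms(
            project(_landmarks3d(model, new_coeffs, corr), pose), obs
        )
        if residual > best + 1e-12 * max(1.0, best):
            # floating-point uptick: keep the previous iterate and stop
            converged = True
            break
        coeffs = new_coeffs
        n_iters += 1
        trace.append(residual)
        if best < float("inf") and abs(best - residual) <= config.tol * max(best, 1e-300):
            best = residual
            converged = True
            break
        best = residual
    if not trace:
        # pathological immediate-stop case: report the initial residual
        trace.append(
            scale_factor * _rms(project(_landmarks3d(model, coeffs, corr), pose), obs)
        )
    return FitResult(
        pose=pose,
        coeffs=coeffs,
        residual_trace=trace,
        converged=converged,
        n_iters=n_iters,
        residual_unit=unit,
    )


def fitted_mesh(model: MorphableModel, result: FitResult) -> FaceMesh:
    """Dense mesh implied by a fit (model space, pose-free)."""
    return construct_shape(model, result.coeffs)


def reprojection_rmse(
    model: MorphableModel,
    result: FitResult,
    observed: LandmarkSet | np.ndarray,
    corr: np.ndarray | None = None,
) -> float:
    """Ocular-scaled reprojection RMSE of a fit against its observations.

    Returns percent of the observed interocular distance when ``observed`` is
    a :class:`LandmarkSet`, else plain pixel RMSE.
    """
    obs = _observed_points(observed)
    if corr is None:
        if isinstance(observed, LandmarkSet) and observed.scheme.correspondence is not None:
            corr = observed.scheme.correspondence
        else:
            raise ValueError("corr is required when the scheme carries no correspondence")
    corr = validate_correspondence(corr, model.vertex_count, obs.shape[0])
    pred = project(_landmarks3d(model, result.coeffs, corr), result.pose)
    if isinstance(observed, LandmarkSet):
        from .landmarks import LandmarkSet as _LS, ocular_rmse

        return ocular_rmse(
            _LS(scheme=observed.scheme, points=pred, source_label="reprojection"),
            observed,
        )
    return _rms(pred, obs)
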