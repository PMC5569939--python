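"""Synthetic morphable models, palsy-like motion and landmark observations.

Real pipelines of this kind need a licensed statistical face model and
clinical photographs; neither can ship with a software package.  This module
generates structurally equivalent stand-ins so every other module is testable
offline:

* a small mirror-symmetric morphable model whose first 68 vertices follow the
  iBUG landmark layout (so a 68-point correspondence is trivially available),
* ground-truth identity coefficients and weak-perspective poses,
* a smile-like expression displacement concentrated around the mouth, with a
  one-sided attenuation factor ``rho`` emulating palsy (the affected side
  moves ``rho`` times as far, midline vertices get the average factor),
* noisy 2D landmark observations of the posed meshes,
* a multi-subject, multi-session cohort on disk (.pts files, ground-truth
  meshes, manifest) with a linear recovery schedule of ``rho`` toward 1.

Every generator is a pure function of its configuration and seed.

The expression basis is constructed so that both the symmetric motion field
and its left-masked counterpart lie in its span; a landmark fit can therefore
represent attenuated (asymmetric) motion exactly, which makes closed-loop
recovery experiments meaningful rather than bounded by model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RegionConfigError
from .landmarks import LandmarkScheme, LandmarkSet, ibug_68, write_pts
from .model import (
    FaceMesh,
    MorphableModel,
    ShapeCoefficients,
    construct_shape,
    export_mesh,
    field_to_mesh,
    mesh_to_field,
    save_model,
)
from .pose import Pose, project
from .rehab import RegionIndex, quadrant_regions

__all__ = [
    "SyntheticConfig",
    "SyntheticModel",
    "make_model",
    "sample_face",
    "simulate_movement",
    "observe",
    "make_cohort",
    "MIRROR_68",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a small clinical evaluation setting: a six-subject cohort
    (set at :func:`make_cohort`), a compact model (m = 300 vertices, 8 identity
    and 4 expression modes), manually annotated landmarks treated as exact
    (``noise_sigma = 0``), left-sided palsy with a mid-range attenuation of
    0.5, and an end-range movement amplitude of one expression standard
    deviation.
    """

    m: int = 300
    k_id: int = 8
    k_exp: int = 4
    noise_sigma: float = 0.0
    palsy_side: str = "left"
    attenuation: float = 0.5
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 68:
            raise RegionConfigError(
                f"m = {self.m} cannot host the 68-point correspondence"
            )
        if self.k_id < 1 or self.k_exp < 1:
            raise ValueError("k_id and k_exp must be at least 1")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError(f"attenuation must lie in [0, 1], got {self.attenuation}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.palsy_side not in ("left", "right", "none"):
            raise RegionConfigError(
                f"palsy_side must be 'left', 'right' or 'none', got {self.palsy_side!r}"
            )


@dataclass(frozen=True)
class SyntheticModel:
    """A generated model with its landmark correspondence, regions and the
    mirror permutation (vertex v reflects onto vertex mirror_index[v])."""

    model: MorphableModel
    scheme: LandmarkScheme
    correspondence: np.ndarray
    regions: list[RegionIndex]
    mirror_index: np.ndarray


# ---------------------------------------------------------------------------
# 68-point face template (iBUG layout, model units roughly millimetres;
# x right, y up, z toward the camera, midline at x = 0)
# ---------------------------------------------------------------------------

def _mirror_permutation_68() -> np.ndarray:
    pairs = (
        [(i, 16 - i) for i in range(8)]
        + [(17 + i, 26 - i) for i in range(5)]
        + [(31, 35), (32, 34)]
        + [(36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46)]
        + [(48, 54), (49, 53), (50, 52), (55, 59), (56, 58)]
        + [(60, 64), (61, 63), (65, 67)]
    )
    perm = np.arange(68)
    for a, b in pairs:
        perm[a], perm[b] = b, a
    return perm


MIRROR_68 = _mirror_permutation_68()


def _template_68() -> np.ndarray:
    """Deterministic 3x68 face-like landmark layout, exactly mirror-symmetric."""
    pts = np.zeros((3, 68))
    # jaw: open U from ear level down to the chin
    t = (np.arange(17) - 8) / 8.0
    pts[0, 0:17] = 78.0 * np.sin(1.35 * t)
    pts[1, 0:17] = 70.6 - 160.6 * np.cos(1.25 * t)
    pts[2, 0:17] = -25.0 + 45.0 * np.cos(1.3 * t)
    # brows (17-21 image-left, 22-26 mirrored below via symmetrization)
    pts[0, 17:22] = [-60, -48, -36, -24, -13]
    pts[1, 17:22] = [40, 46, 49, 48, 44]
    pts[2, 17:22] = [18, 22, 25, 26, 25]
    # nose bridge and base
    pts[:, 27:31] = [[0, 0, 0, 0], [38, 26, 14, 2], [30, 34, 38, 43]]
    pts[0, 31:36] = [-14, -7, 0, 7, 14]
    pts[1, 31:36] = [-8, -10, -11, -10, -8]
    pts[2, 31:36] = [30, 34, 36, 34, 30]
    # left eye hexagon
    pts[0, 36:42] = [-48, -41, -31, -24, -31, -41]
    pts[1, 36:42] = [26, 31, 31, 25, 21, 21]
    pts[2, 36:42] = [18, 21, 21, 20, 21, 21]
    # outer mouth
    pts[0, 48:60] = [-26, -16, -6, 0, 6, 16, 26, 16, 6, 0, -6, -16]
    pts[1, 48:60] = [-45, -38, -35, -36, -35, -38, -45, -52, -56, -57, -56, -52]
    pts[2, 48:60] = [22, 28, 31, 32, 31, 28, 22, 26, 29, 30, 29, 26]
    # inner mouth
    pts[0, 60:68] = [-19, -6, 0, 6, 19, 6, 0, -6]
    pts[1, 60:68] = [-45, -43, -43, -43, -45, -48, -49, -48]
    pts[2, 60:68] = [24, 29, 30, 29, 24, 28, 29, 28]
    # symmetrize exactly: average with the mirrored permuted layout
    mirrored = pts[:, MIRROR_68].copy()
    mirrored[0] *= -1.0
    return 0.5 * (pts + mirrored)


_MOUTH_CENTER = np.array([0.0, -46.0, 27.0])
_MOTION_SIGMA = 26.0  # spatial falloff of the expression field, model units


def _filler_vertices(n_fill: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mirror-paired dome points filling the mesh to m vertices.

    Returns the (3, n_fill) coordinates and the local mirror permutation
    (pairs are adjacent; an odd leftover point sits on the midline).
    """
    n_pairs, odd = divmod(n_fill, 2)
    coords = np.zeros((3, n_fill))
    perm = np.arange(n_fill)
    for p in range(n_pairs):
        x = 4.0 + 72.0 * rng.random()
        y = -95.0 + 150.0 * rng.random()
        dome = 1.0 - (x / 85.0) ** 2 - ((y + 15.0) / 95.0) ** 2
        z = 42.0 * np.sqrt(max(dome, 0.0)) - 5.0 + 2.0 * rng.standard_normal()
        coords[:, 2 * p] = (x, y, z)
        coords[:, 2 * p + 1] = (-x, y, z)
        perm[2 * p], perm[2 * p + 1] = 2 * p + 1, 2 * p
    if odd:
        y = -95.0 + 150.0 * rng.random()
        z = 42.0 * np.sqrt(max(1.0 - ((y + 15.0) / 95.0) ** 2, 0.0)) - 5.0
        coords[:, -1] = (0.0, y, z)
    return coords, perm


def _motion_field(mean_shape: np.ndarray) -> np.ndarray:
    """Smile-like symmetric displacement field, flattened to (3m,).

    Each vertex moves in y and z with a Gaussian falloff from the mouth
    centre; the x component is zero so the field is exactly mirror-symmetric.
    """
    d2 = np.sum((mean_shape - _MOUTH_CENTER[:, None]) ** 2, axis=0)
    w = np.exp(-d2 / (2.0 * _MOTION_SIGMA**2))
    m = mean_shape.shape[1]
    fld = np.zeros((3, m))
    fld[1] = 0.8 * w
    fld[2] = 0.6 * w
    return mesh_to_field(fld)


def _side_factors(mean_shape: np.ndarray, side: str, rho: float) -> np.ndarray:
    """Per-vertex attenuation factors: rho on the affected side, 1 on the
    healthy side, the mean (1+rho)/2 on the midline."""
    x = mean_shape[0]
    factors = np.ones(x.size)
    if side == "none":
        return factors
    affected = x < 0 if side == "left" else x > 0
    midline = np.abs(x) < 1e-9
    factors[affected] = rho
    factors[midline] = 0.5 * (1.0 + rho)
    return factors


def make_model(config: SyntheticConfig) -> SyntheticModel:
    """Generate a mirror-symmetric morphable model with eye/mouth structure.

    The first 68 vertices follow the iBUG landmark layout, so the emitted
    correspondence is simply ``0..67``.  Identity basis columns are random
    orthonormal directions; the expression basis spans the smile-like motion
    field and its left-masked counterpart (columns 1 and 2) plus random
    orthonormal completions.  Per-component standard deviations decay
    geometrically with ratio 0.8.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    template = _template_68()
    fill, fill_perm = _filler_vertices(config.m - 68, rng)
    mean_shape = np.concatenate([template, fill], axis=1)
    mirror_index = np.concatenate([MIRROR_68, 68 + fill_perm])

    three_m = 3 * config.m
    id_raw = rng.standard_normal((three_m, config.k_id))
    id_basis, _ = np.linalg.qr(id_raw)

    d_field = _motion_field(mean_shape)
    # Left-masked copy of the motion field (midline at half weight), in the
    # (3v + c) flat layout.  With both the field and this mask in the span,
    # any one-sided attenuation of the motion -- which scales the left part by
    # rho and the midline by (1+rho)/2 -- stays exactly representable.
    x = mean_shape[0]
    left_mask = np.where(x < 0, 1.0, np.where(np.abs(x) < 1e-9, 0.5, 0.0))
    masked = mesh_to_field(field_to_mesh(d_field, config.m) * left_mask)
    seeds = [d_field, masked]
    extra = max(config.k_exp - 2, 0)
    exp_raw = np.column_stack(
        seeds[: config.k_exp] + ([rng.standard_normal((three_m, extra))] if extra else [])
    )
    exp_basis, r_diag = np.linalg.qr(exp_raw)
    # fix signs so the first column points along the motion field
    signs = np.sign(np.diag(r_diag))
    signs[signs == 0] = 1.0
    exp_basis = exp_basis * signs

    id_scale = 5.0 * 0.8 ** np.arange(config.k_id)
    exp_scale = 8.0 * 0.8 ** np.arange(config.k_exp)

    model = MorphableModel(
        mean_shape=mean_shape,
        id_basis=id_basis,
        exp_basis=exp_basis,
        id_scale=id_scale,
        exp_scale=exp_scale,
        name=f"synthetic-m{config.m}-seed{config.seed}",
        units="model-units",
    )
    correspondence = np.arange(68, dtype=np.int64)
    scheme = ibug_68().with_correspondence(correspondence)
    regions = quadrant_regions(model)
    return SyntheticModel(
        model=model,
        scheme=scheme,
        correspondence=correspondence,
        regions=regions,
        mirror_index=mirror_index,
    )


def sample_face(model: MorphableModel, seed: int) -> ShapeCoefficients:
    """Draw i.i.d. standard-normal coefficients (sd units), deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return ShapeCoefficients(
        alpha_id=rng.standard_normal(model.k_id),
        alpha_exp=rng.standard_normal(model.k_exp),
    )


def simulate_movement(
    synth: SyntheticModel,
    coeffs: ShapeCoefficients,
    amplitude: float,
    side: str = "left",
    attenuation: float = 1.0,
) -> tuple[FaceMesh, FaceMesh]:
    """Neutral and end-range meshes for one prescribed movement.

    ``S0`` is the identity at a neutral expression (expression coefficients
    zeroed).  ``S1`` adds ``amplitude`` standard deviations of the first
    expression mode, with every displacement on the affected side scaled by
    ``attenuation`` (midline vertices get the mean factor).  ``attenuation=1``
    or ``side='none'`` gives perfectly symmetric motion; ``amplitude=0`` gives
    ``S1 == S0``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError(f"attenuation must lie in [0, 1], got {attenuation}")
    if side not in ("left", "right", "none"):
        raise RegionConfigError(f"unknown side label {side!r}")
    model = synth.model
    neutral = ShapeCoefficients(coeffs.alpha_id, np.zeros(model.k_exp))
    s0 = construct_shape(model, neutral)
    base_disp = field_to_mesh(
        amplitude * model.exp_scale[0] * model.exp_basis[:, 0], model.vertex_count
    )
    factors = _side_factors(model.mean_shape, side, attenuation)
    s1 = FaceMesh(
        vertices=s0.vertices + base_disp * factors,
        triangulation=model.triangulation,
    )
    return s0, s1


def observe(
    mesh: FaceMesh,
    pose: Pose,
    corr: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    scheme: LandmarkScheme | None = None,
) -> LandmarkSet:
    """Project corresponded vertices and add i.i.d. Gaussian pixel noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    corr = np.asarray(corr, dtype=np.int64)
    pts = project(mesh.vertices[:, corr], pose)
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        pts = pts + noise_sigma * rng.standard_normal(pts.shape)
    if scheme is None:
        scheme = ibug_68().with_correspondence(corr) if corr.size == 68 else None
    if scheme is None:
        raise ValueError("pass a scheme for non-68-point correspondences")
    return LandmarkSet(scheme=scheme, points=pts, source_label="synthetic-observation")


def _capture_pose(rng: np.random.Generator) -> Pose:
    """A plausible near-frontal capture: modest rotation, VGA-ish framing."""
    return Pose(
        scale=float(2.0 + rng.random()),
        pitch=float(rng.uniform(-0.15, 0.15)),
        yaw=float(rng.uniform(-0.2, 0.2)),
        roll=float(rng.uniform(-0.1, 0.1)),
        translation=np.array([rng.uniform(220, 280), rng.uniform(240, 300)]),
    )


def _session_attenuations(rho0: float, n_sessions: int) -> np.ndarray:
    """Linear recovery schedule from rho0 at session 1 to 1.0 at the last."""
    if n_sessions == 1:
        return np.array([rho0])
    return rho0 + (1.0 - rho0) * np.arange(n_sessions) / (n_sessions - 1)


def make_cohort(
    config: SyntheticConfig,
    n_subjects: int = 6,
    n_sessions: int = 3,
    out_dir: str | Path = "cohort",
) -> pd.DataFrame:
    """Write a fully synthetic rehabilitation cohort to disk.

    Layout::

        out_dir/
          model.3dmm            # morphable model container
          regions.yaml          # left/right + quadrant rules
          correspondence.csv    # landmark -> model vertex
          manifest.csv
          subject_01/session_1/{neutral.pts, endrange.pts,
                                neutral_truth.obj, endrange_truth.obj}
          ...

    Each subject keeps one identity across sessions; the attenuation of the
    affected side increases linearly from ``config.attenuation`` at session 1
    to 1.0 at the last session (simulated recovery).  Head pose differs
    between captures, exercising the pose-invariance of the downstream
    model-space motion measure.  Returns the manifest as a DataFrame.
    """
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("n_subjects and n_sessions must be at least 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    synth = make_model(config)
    save_model(synth.model, out_dir / "model.3dmm")
    (out_dir / "regions.yaml").write_text(
        "# Half-plane regions resolved against the model's mean shape.\n"
        "regions:\n"
        "  left:        {rule: \"x < 0\"}\n"
        "  right:       {rule: \"x > 0\"}\n"
        "  upper_left:  {rule: \"x < 0 and y > 0\"}\n"
        "  upper_right: {rule: \"x > 0 and y > 0\"}\n"
        "  lower_left:  {rule: \"x < 0 and y < 0\"}\n"
        "  lower_right: {rule: \"x > 0 and y < 0\"}\n"
    )
    pd.DataFrame(
        {"landmark": np.arange(68), "vertex": synth.correspondence}
    ).to_csv(out_dir / "correspondence.csv", index=False)

    schedule = _session_attenuations(config.attenuation, n_sessions)
    rows = []
    for s in range(1, n_subjects + 1):
        identity_seed = np.random.SeedSequence(config.seed, spawn_key=(s, 0))
        coeffs = ShapeCoefficients(
            alpha_id=np.random.default_rng(identity_seed).standard_normal(config.k_id),
            alpha_exp=np.zeros(config.k_exp),
        )
        for k in range(1, n_sessions + 1):
            rho = float(schedule[k - 1])
            sdir = out_dir / f"subject_{s:02d}" / f"session_{k}"
            sdir.mkdir(parents=True, exist_ok=True)
            s0, s1 = simulate_movement(
                synth, coeffs, config.amplitude, config.palsy_side, rho
            )
            rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(s, k)))
            pose_n = _capture_pose(rng)
            pose_e = _capture_pose(rng)
            noise_seed_n = int(rng.integers(2**31))
            noise_seed_e = int(rng.integers(2**31))
            obs_n = observe(s0, pose_n, synth.correspondence, config.noise_sigma,
                            noise_seed_n, synth.scheme)
            obs_e = observe(s1, pose_e, synth.correspondence, config.noise_sigma,
                            noise_seed_e, synth.scheme)
            write_pts(obs_n, sdir / "neutral.pts")
            write_pts(obs_e, sdir / "endrange.pts")
            export_mesh(s0, sdir / "neutral_truth.obj")
            export_mesh(s1, sdir / "endrange_truth.obj")
            rows.append(
                {
                    "subject": s,
                    "session": k,
                    "side": config.palsy_side,
                    "attenuation": rho,
                    "amplitude": config.amplitude,
                    "noise_sigma": config.noise_sigma,
                    "neutral_pts": str(sdir / "neutral.pts"),
                    "endrange_pts": str(sdir / "endrange.pts"),
                    "neutral_truth": str(sdir / "neutral_truth.obj"),
                    "endrange_truth": str(sdir / "endrange_truth.obj"),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
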