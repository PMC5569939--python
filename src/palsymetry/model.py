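"""Linear 3D morphable face model (3DMM).

A 3DMM represents a dense 3D face as a mean shape plus linear combinations of
identity and expression principal axes:

    S = S_mean + A_id (alpha_id * sigma_id) + A_exp (alpha_exp * sigma_exp)

Coefficients are kept in standard-deviation units: each basis column is unit
norm and the per-component standard deviations ``id_scale`` / ``exp_scale``
are applied inside :func:`construct_shape`.  This makes ridge penalties in the
fitter scale-free and coefficient magnitudes directly interpretable (a value
of 2.0 means two standard deviations along that mode).

Flattening convention
---------------------
Basis matrices have shape ``(3*m, k)``.  Row ``3*v + c`` of a basis column is
the displacement of vertex ``v`` along coordinate ``c`` (0=x, 1=y, 2=z).  The
helpers :func:`field_to_mesh` / :func:`mesh_to_field` implement the mapping
between a flat ``(3m,)`` field and the ``(3, m)`` vertex array and are the only
place the convention appears.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionMismatchError, ModelFormatError

FORMAT_VERSION = 1

__all__ = [
    "MorphableModel",
    "ShapeCoefficients",
    "FaceMesh",
    "construct_shape",
    "save_model",
    "load_model",
    "export_mesh",
    "field_to_mesh",
    "mesh_to_field",
]


def field_to_mesh(vec: np.ndarray, m: int) -> np.ndarray:
    """Reshape a flat ``(3m,)`` displacement field into a ``(3, m)`` array."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.size != 3 * m:
        raise DimensionMismatchError(
            f"field has {vec.size} entries, expected 3*m = {3 * m}"
        )
    return vec.reshape(m, 3).T


def mesh_to_field(vertices: np.ndarray) -> np.ndarray:
    """Flatten a ``(3, m)`` vertex array into the ``(3m,)`` field layout."""
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[0] != 3:
        raise DimensionMismatchError(
            f"vertices must have shape (3, m), got {vertices.shape}"
        )
    return vertices.T.reshape(-1)


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise DimensionMismatchError(f"{name} contains non-finite entries")


@dataclass
class MorphableModel:
    """Mean shape plus identity/expression linear bases.

    Parameters
    ----------
    mean_shape : ndarray, shape (3, m)
        Mean face vertices in model units.
    id_basis : ndarray, shape (3m, k_id)
        Identity principal axes (unit columns).
    exp_basis : ndarray, shape (3m, k_exp)
        Expression principal axes (unit columns).
    id_scale, exp_scale : ndarray
        Strictly positive per-component standard deviations, in model units.
    triangulation : ndarray of int, shape (n_tri, 3), optional
        Triangle vertex indices; required only for surface export.
    name, units : str
        Free-text metadata carried through reports.
    """

    mean_shape: np.ndarray
    id_basis: np.ndarray
    exp_basis: np.ndarray
    id_scale: np.ndarray
    exp_scale: np.ndarray
    triangulation: np.ndarray | None = None
    name: str = "unnamed"
    units: str = "model-units"

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=np.float64)
        self.id_basis = np.asarray(self.id_basis, dtype=np.float64)
        self.exp_basis = np.asarray(self.exp_basis, dtype=np.float64)
        self.id_scale = np.asarray(self.id_scale, dtype=np.float64).reshape(-1)
        self.exp_scale = np.asarray(self.exp_scale, dtype=np.float64).reshape(-1)
        if self.mean_shape.ndim != 2 or self.mean_shape.shape[0] != 3:
            raise DimensionMismatchError(
                f"mean_shape must have shape (3, m), got {self.mean_shape.shape}"
            )
        m = self.mean_shape.shape[1]
        for label, basis, scale in (
            ("id", self.id_basis, self.id_scale),
            ("exp", self.exp_basis, self.exp_scale),
        ):
            if basis.ndim != 2 or basis.shape[0] != 3 * m:
                raise DimensionMismatchError(
                    f"{label}_basis must have shape (3m, k) = ({3 * m}, k), "
                    f"got {basis.shape}"
                )
            if basis.shape[1] != scale.size:
                raise DimensionMismatchError(
                    f"{label}_basis has {basis.shape[1]} columns but "
                    f"{label}_scale has {scale.size} entries"
                )
            if scale.size and not np.all(scale > 0):
                raise DimensionMismatchError(f"{label}_scale must be strictly positive")
            _check_finite(f"{label}_basis", basis)
            _check_finite(f"{label}_scale", scale)
        _check_finite("mean_shape", self.mean_shape)
        if self.triangulation is not None:
            tri = np.asarray(self.triangulation, dtype=np.int64)
            if tri.ndim != 2 or tri.shape[1] != 3:
                raise DimensionMismatchError(
                    f"triangulation must have shape (n_tri, 3), got {tri.shape}"
                )
            if tri.size and (tri.min() < 0 or tri.max() >= m):
                raise DimensionMismatchError(
                    "triangulation indices fall outside [0, m)"
                )
            self.triangulation = tri

    @property
    def vertex_count(self) -> int:
        return self.mean_shape.shape[1]

    @property
    def k_id(self) -> int:
        return self.id_basis.shape[1]

    @property
    def k_exp(self) -> int:
        return self.exp_basis.shape[1]

    def zero_coefficients(self) -> "ShapeCoefficients":
        return ShapeCoefficients(np.zeros(self.k_id), np.zeros(self.k_exp))


@dataclass
class ShapeCoefficients:
    """Identity and expression coefficients in standard-deviation units."""

    alpha_id: np.ndarray
    alpha_exp: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_id = np.asarray(self.alpha_id, dtype=np.float64).reshape(-1)
        self.alpha_exp = np.asarray(self.alpha_exp, dtype=np.float64).reshape(-1)
        _check_finite("alpha_id", self.alpha_id)
        _check_finite("alpha_exp", self.alpha_exp)


@dataclass
class FaceMesh:
    """A concrete 3D face: ``(3, m)`` vertices plus optional triangulation."""

    vertices: np.ndarray
    triangulation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[0] != 3:
            raise DimensionMismatchError(
                f"vertices must have shape (3, m), got {self.vertices.shape}"
            )
        _check_finite("vertices", self.vertices)

    @property
    def vertex_count(self) -> int:
        return self.vertices.shape[1]


def construct_shape(model: MorphableModel, coeffs: ShapeCoefficients) -> FaceMesh:
    """Evaluate the linear shape model at the given coefficients.

    Returns the mesh ``S = S_mean + A_id (a_id * s_id) + A_exp (a_exp * s_exp)``
    where ``*`` is elementwise multiplication by the per-component standard
    deviations.  The map is affine in the coefficients, which downstream code
    relies on (closed-form ridge solves, superposition tests).
    """
    if coeffs.alpha_id.size != model.k_id:
        raise DimensionMismatchError(
            f"alpha_id has {coeffs.alpha_id.size} entries, model expects {model.k_id}"
        )
    if coeffs.alpha_exp.size != model.k_exp:
        raise DimensionMismatchError(
            f"alpha_exp has {coeffs.alpha_exp.size} entries, model expects {model.k_exp}"
        )
    m = model.vertex_count
    offset = np.zeros(3 * m)
    if model.k_id:
        offset += model.id_basis @ (coeffs.alpha_id * model.id_scale)
    if model.k_exp:
        offset += model.exp_basis @ (coeffs.alpha_exp * model.exp_scale)
    vertices = model.mean_shape + field_to_mesh(offset, m)
    return FaceMesh(vertices=vertices, triangulation=model.triangulation)


# ---------------------------------------------------------------------------
# Serialization: a deterministic single-file zip archive of named .npy members
# plus a JSON header.  Member timestamps are pinned so that saving the same
# model twice yields byte-identical files.
# ---------------------------------------------------------------------------

_ARRAY_MEMBERS = ("mean_shape", "id_basis", "exp_basis", "id_scale", "exp_scale")


def _write_member(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
    info.compress_type = zipfile.ZIP_STORED
    info.external_attr = 0o644 << 16
    zf.writestr(info, data)


def _array_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr), allow_pickle=False)
    return buf.getvalue()


def save_model(model: MorphableModel, path: str | Path) -> None:
    """Write a model container; two saves of the same model are byte-identical."""
    header = {
        "format_version": FORMAT_VERSION,
        "name": model.name,
        "units": model.units,
        "vertex_count": model.vertex_count,
        "k_id": model.k_id,
        "k_exp": model.k_exp,
        "has_triangulation": model.triangulation is not None,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        _write_member(
            zf, "header.json", json.dumps(header, sort_keys=True, indent=0).encode()
        )
        for member in _ARRAY_MEMBERS:
            _write_member(zf, member + ".npy", _array_bytes(getattr(model, member)))
        if model.triangulation is not None:
            _write_member(zf, "triangulation.npy", _array_bytes(model.triangulation))


def load_model(path: str | Path) -> MorphableModel:
    """Load a model container written by :func:`save_model`.

    Raises :class:`ModelFormatError` on missing, truncated or malformed files
    and on format-version mismatch; never returns a partial model.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    try:
        with zipfile.ZipFile(path, "r") as zf:
            try:
                header = json.loads(zf.read("header.json"))
            except KeyError as exc:
                raise ModelFormatError(f"{path}: missing header.json") from exc
            version = header.get("format_version")
            if version != FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: format version {version!r}, expected {FORMAT_VERSION}"
                )
            arrays = {}
            for member in _ARRAY_MEMBERS:
                try:
                    raw = zf.read(member + ".npy")
                except KeyError as exc:
                    raise ModelFormatError(f"{path}: missing member {member}") from exc
                arrays[member] = np.lib.format.read_array(
                    io.BytesIO(raw), allow_pickle=False
                )
            tri = None
            if header.get("has_triangulation"):
                try:
                    raw = zf.read("triangulation.npy")
                except KeyError as exc:
                    raise ModelFormatError(
                        f"{path}: header promises triangulation but member is absent"
                    ) from exc
                tri = np.lib.format.read_array(io.BytesIO(raw), allow_pickle=False)
    except zipfile.BadZipFile as exc:
        raise ModelFormatError(f"{path}: not a valid model container ({exc})") from exc
    try:
        return MorphableModel(
            triangulation=tri,
            name=header.get("name", "unnamed"),
            units=header.get("units", "model-units"),
            **arrays,
        )
    except DimensionMismatchError as exc:
        raise ModelFormatError(f"{path}: inconsistent arrays ({exc})") from exc


def export_mesh(mesh: FaceMesh, path: str | Path) -> None:
    """Write a mesh as Wavefront OBJ, preserving vertex order.

    Meshes without a triangulation are exported as vertex records only, which
    is sufficient for point-cloud inspection.  Coordinates are printed with 8
    decimals, so a re-parse recovers them to ~1e-8 model units.
    """
    path = Path(path)
    lines = []
    for x, y, z in mesh.vertices.T:
        lines.append(f"v {x:.8f} {y:.8f} {z:.8f}")
    if mesh.triangulation is not None:
        for a, b, c in mesh.triangulation:
            lines.append(f"f {a + 1} {b + 1} {c + 1}")  # OBJ is 1-based
    path.write_text("\n".join(lines) + "\n")


def import_mesh(path: str | Path) -> FaceMesh:
    """Read back an OBJ written by :func:`export_mesh` (v and f records only)."""
    verts: list[list[float]] = []
    tris: list[list[int]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(p) for p in parts[1:4]])
        elif parts[0] == "f":
            tris.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    tri = np.asarray(tris, dtype=np.int64) if tris else None
    return FaceMesh(vertices=np.asarray(verts, dtype=np.float64).T, triangulation=tri)
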