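"""Parametric synthetic vertebra and FSU generator with full ground truth.

Clinical CT data for this problem are restricted, so every downstream stage
(part segmentation, shape-model fitting, FE assembly, ROM simulation) is
exercised on generated anatomy for which the truth is known exactly: semantic
part labels, landmarks, endplate and facet-cartilage patches, ligament
attachment sites, and — for populations — the true low-rank shape modes.

A vertebra is a star-shaped surface: a fixed icosphere template whose radius
along each vertex direction is an elliptical body radius plus smooth angular
bumps for the posterior processes (left/right transverse, spinous, paired
superior/inferior articular).  Anatomical fidelity is deliberately limited to
the topological features the pipeline consumes; the pipeline itself is
geometry-generic.

Default body/process sizes put the overall left-right extent near 86 mm and
anterior-posterior extent near 88 mm, the average healthy lumbar dimensions
the downstream models are built for.

Coordinates: +x left-to-right, +y posterior-to-anterior, +z
inferior-to-superior, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy import ndimage

from .mesh import (
    LabelVolume,
    TriangleMesh,
    closest_point_on_surface,
    icosphere,
    mesh_to_mask,
    new_mesh,
    vertex_areas,
)

__all__ = [
    "DEFAULT_MODE_SCALES",
    "LIGAMENT_SITES",
    "VertebraParams",
    "FSUSpec",
    "GroundTruth",
    "FSU",
    "generate_vertebra",
    "generate_population",
    "generate_fsu",
    "rasterize_labels",
]

# semantic classes
BODY, LEFT, RIGHT, POSTERIOR = 0, 1, 2, 3
CLASS_NAMES = {
    BODY: "vertebral_body",
    LEFT: "left_processes",
    RIGHT: "right_processes",
    POSTERIOR: "spinous_lamina",
}

LIGAMENT_SITES = ("ALL", "PLL", "SSL", "ISL", "LF", "ITL_left", "ITL_right")

# Default population mode scales (mm, in the 3N-embedding norm of the
# orthonormal fields).  For the default template (642 vertices) these give
# per-vertex RMS displacements of roughly 2.4 / 1.6 / 1.0 mm — a realistic
# magnitude of inter-subject lumbar shape variation.
DEFAULT_MODE_SCALES = (60.0, 40.0, 25.0)


@dataclass(frozen=True)
class VertebraParams:
    """Size and shape parameters of one synthetic vertebra (mm)."""

    body_width: float = 42.0
    body_depth: float = 34.0
    body_height: float = 28.0
    pedicle_size: float = 8.0
    transverse_length: float = 25.0
    spinous_length: float = 42.0
    articular_length: float = 12.0
    asymmetry: float = 0.0
    noise: float = 0.0
    seed: int = 0
    subdivisions: int = 3

    def __post_init__(self) -> None:
        for name in (
            "body_width", "body_depth", "body_height",
            "pedicle_size", "transverse_length", "spinous_length",
            "articular_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.asymmetry < 0 or self.noise < 0:
            raise ValueError("asymmetry and noise must be non-negative")


@dataclass(frozen=True)
class FSUSpec:
    """Two stacked vertebrae plus disc/facet clearances and a Pfirrmann grade."""

    upper: VertebraParams = field(default_factory=VertebraParams)
    lower: VertebraParams = field(default_factory=VertebraParams)
    disc_height: float = 10.0
    facet_gap: float = 1.0  # cartilage joint space, mm
    pfirrmann_grade: Literal["healthy", 4, 5] = "healthy"
    weishaupt_grade: int = 0  # annotation only; no geometric effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_height <= 0:
            raise ValueError("disc_height must be positive")
        if self.facet_gap < 0:
            raise ValueError("facet_gap must be non-negative")
        if self.pfirrmann_grade not in ("healthy", 4, 5):
            raise ValueError("pfirrmann_grade must be 'healthy', 4 or 5")
        if self.weishaupt_grade not in (0, 1, 2, 3):
            raise ValueError("weishaupt_grade must be in 0..3")


@dataclass
class GroundTruth:
    """Per-vertex truth attached to a generated vertebra."""

    labels: np.ndarray  # (N,) int, semantic class per vertex
    landmarks: dict[str, np.ndarray]  # class name -> xyz on the surface
    endplates: dict[str, np.ndarray]  # 'superior'/'inferior' -> vertex indices
    facets: dict[str, np.ndarray]  # e.g. 'superior_left' -> vertex indices
    ligament_sites: dict[str, int]  # site name -> template vertex index
    corresponded: bool = True

    def facet_side(self, side: str) -> np.ndarray:
        """Union of superior+inferior facet patches on one side."""
        return np.union1d(self.facets[f"superior_{side}"], self.facets[f"inferior_{side}"])


# ---------------------------------------------------------------------------
# radius model

# bump definitions: (name, direction, amplitude attr, angular width rad, side).
# The superior articular processes sit lateral with medial-facing facet
# surfaces; the inferior ones sit medial with lateral-facing surfaces, so
# that adjacent vertebrae interlock on near-vertical articulating flanks.
_BUMPS = (
    ("transverse_left", (-0.94, -0.34, 0.0), "transverse_length", 0.30, "L"),
    ("transverse_right", (0.94, -0.34, 0.0), "transverse_length", 0.30, "R"),
    ("spinous", (0.0, -0.99, -0.14), "spinous_length", 0.35, None),
    ("arch", (0.0, -1.0, 0.0), "pedicle_size", 0.55, None),
    ("sup_articular_left", (-0.60, -0.55, 0.58), "articular_length", 0.30, "L"),
    ("sup_articular_right", (0.60, -0.55, 0.58), "articular_length", 0.30, "R"),
    ("inf_articular_left", (-0.32, -0.72, -0.61), "articular_length", 0.30, "L"),
    ("inf_articular_right", (0.32, -0.72, -0.61), "articular_length", 0.30, "R"),
)


def _bump_angles(u: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for name, d, _, _, _ in _BUMPS:
        d = np.asarray(d) / np.linalg.norm(d)
        out[name] = np.arccos(np.clip(u @ d, -1.0, 1.0))
    return out


def _radius(u: np.ndarray, p: VertebraParams) -> np.ndarray:
    # superellipsoid body (exponent 6): near-flat endplates and steep walls,
    # like a real vertebral body, while staying star-shaped
    a, b, c = p.body_width / 2, p.body_depth / 2, p.body_height / 2
    r = (
        (np.abs(u[:, 0]) / a) ** 6
        + (np.abs(u[:, 1]) / b) ** 6
        + (np.abs(u[:, 2]) / c) ** 6
    ) ** (-1.0 / 6.0)
    ang = _bump_angles(u)
    for name, _, attr, sigma, side in _BUMPS:
        amp = getattr(p, attr)
        if side == "L":
            amp *= 1.0 + p.asymmetry
        elif side == "R":
            amp *= 1.0 - p.asymmetry
        r = r + amp * np.exp(-((ang[name] / sigma) ** 2))
    return r


def _semantic_labels(u: np.ndarray) -> np.ndarray:
    labels = np.full(len(u), BODY, dtype=np.int64)
    posterior = u[:, 1] < -0.30
    labels[posterior & (u[:, 0] < -0.22)] = LEFT
    labels[posterior & (u[:, 0] > 0.22)] = RIGHT
    labels[posterior & (np.abs(u[:, 0]) <= 0.22)] = POSTERIOR
    return labels


def _nearest_direction_vertex(u: np.ndarray, d, midline: bool = False) -> int:
    """Template vertex index closest to a direction; midline sites are
    restricted to sagittal-plane vertices so the anatomy stays exactly
    bilaterally symmetric."""
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    score = u @ d
    if midline:
        score = np.where(np.abs(u[:, 0]) < 1e-9, score, -np.inf)
    return int(np.argmax(score))


def generate_vertebra(params: VertebraParams) -> tuple[TriangleMesh, GroundTruth]:
    """Generate one closed, outward-oriented synthetic vertebra plus truth.

    All meshes generated at the same template resolution share vertex count
    and connectivity (point-to-point correspondence); with ``asymmetry = 0``
    and ``noise = 0`` the surface is exactly bilaterally symmetric.
    """
    sphere = icosphere(params.subdivisions)
    u = np.asarray(sphere.vertices)
    r = _radius(u, params)
    if params.noise > 0:
        rng = np.random.default_rng(params.seed)
        r = r + rng.normal(0.0, params.noise, size=len(r))
    if np.any(r <= 0.5):
        raise ValueError(
            "degenerate parameter combination: surface radius collapses "
            "(processes/noise too large relative to body size)"
        )
    verts = u * r[:, None]
    mesh = new_mesh(verts, sphere.faces)

    labels = _semantic_labels(u)
    ang = _bump_angles(u)

    # endplates cover the body's near-flat top/bottom caps (the full disc
    # footprint), staying clear of the articular processes and the spinous
    # process flank
    clear_sup = (
        (ang["sup_articular_left"] > 0.40) & (ang["sup_articular_right"] > 0.40)
    )
    clear_inf = (
        (ang["inf_articular_left"] > 0.40)
        & (ang["inf_articular_right"] > 0.40)
        & (ang["spinous"] > 0.50)
    )
    endplates = {
        "superior": np.where((u[:, 2] > 0.60) & clear_sup)[0],
        "inferior": np.where((u[:, 2] < -0.60) & clear_inf)[0],
    }
    # facet cartilage patches: the articulating flank of each articular
    # process — medial flank of the superior processes (facing the next
    # vertebra's inferior processes), lateral flank of the inferior ones
    normals = np.asarray(mesh.vertex_normals)
    facets = {}
    for key, bump, sign in (
        ("superior_left", "sup_articular_left", +1.0),
        ("superior_right", "sup_articular_right", -1.0),
        ("inferior_left", "inf_articular_left", -1.0),
        ("inferior_right", "inf_articular_right", +1.0),
    ):
        in_bump = ang[bump] < 0.38
        for thr in (0.15, 0.0):
            sel = in_bump & (sign * normals[:, 0] > thr)
            if sel.any():
                break
        facets[key] = np.where(sel)[0]

    ligament_sites = {
        "ALL": _nearest_direction_vertex(u, (0, 1, 0), midline=True),
        "PLL": _nearest_direction_vertex(u, (0, -0.75, 0.62), midline=True),
        "SSL": _nearest_direction_vertex(u, (0, -0.99, -0.14), midline=True),
        "ISL": _nearest_direction_vertex(u, (0, -0.99, 0.14), midline=True),
        "LF": _nearest_direction_vertex(u, (0, -0.87, 0.42), midline=True),
        "ITL_left": _nearest_direction_vertex(u, (-0.94, -0.34, 0)),
        "ITL_right": _nearest_direction_vertex(u, (0.94, -0.34, 0)),
    }

    landmarks = _class_landmarks(mesh, labels)
    gt = GroundTruth(
        labels=labels,
        landmarks=landmarks,
        endplates=endplates,
        facets=facets,
        ligament_sites=ligament_sites,
    )
    _validate(mesh, gt)
    return mesh, gt


def _class_landmarks(mesh: TriangleMesh, labels: np.ndarray) -> dict[str, np.ndarray]:
    w = vertex_areas(mesh)
    out = {}
    for cls, name in CLASS_NAMES.items():
        idx = labels == cls
        com = np.average(mesh.vertices[idx], axis=0, weights=w[idx])
        out[name] = closest_point_on_surface(com[None], mesh)[0][0]
    return out


def _validate(mesh: TriangleMesh, gt: GroundTruth) -> None:
    if not mesh.is_watertight:
        raise ValueError("generated mesh is not watertight")
    for cls in CLASS_NAMES:
        if not (gt.labels == cls).any():
            raise ValueError(f"semantic class {cls} is empty")
    for key in ("superior", "inferior"):
        if len(gt.endplates[key]) == 0:
            raise ValueError(f"{key} endplate patch is empty")
    for key, idx in gt.facets.items():
        if len(idx) == 0:
            raise ValueError(f"facet patch {key} is empty")
        if np.intersect1d(idx, gt.endplates["superior"]).size:
            raise ValueError("facet and endplate patches overlap")
        if np.intersect1d(idx, gt.endplates["inferior"]).size:
            raise ValueError("facet and endplate patches overlap")


# ---------------------------------------------------------------------------
# populations with known shape modes


def _smooth_mode_fields(base: TriangleMesh, n_modes: int) -> np.ndarray:
    """Orthonormal smooth displacement fields (3N x K), rigid-motion free.

    Low-order polynomial fields of the template direction are projected off
    the six rigid-body generators and orthonormalized, so a Procrustes+PCA
    on a generated population can recover the spanned subspace exactly.
    """
    v = np.asarray(base.vertices)
    n = len(v)
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    ux, uy, uz = u.T
    radial = u
    scalars = [
        uz, ux * uy, uz**2 - 1 / 3, ux**2 - uy**2, ux * uz, uy * uz,
        ux**2 * uz, uy, ux, uy**2 - uz**2,
    ]
    fields = []
    for k in range(n_modes):
        f = scalars[k % len(scalars)]
        direction = radial if (k // len(scalars)) % 2 == 0 else np.tile(
            np.eye(3)[k % 3], (n, 1)
        )
        fields.append((f[:, None] * direction).ravel())
    basis = np.column_stack(fields)  # (3N, K)

    # rigid-body generators: 3 translations + 3 linearized rotations
    rig = [np.tile(np.eye(3)[i], (n, 1)).ravel() for i in range(3)]
    for axis in np.eye(3):
        rig.append(np.cross(np.tile(axis, (n, 1)), v).ravel())
    R = np.column_stack(rig)
    Q, _ = np.linalg.qr(R)
    basis = basis - Q @ (Q.T @ basis)
    modes, rr = np.linalg.qr(basis)
    if np.any(np.abs(np.diag(rr)) < 1e-8):
        raise ValueError("mode construction produced a rank-deficient basis")
    # fix signs for reproducibility
    signs = np.sign(modes[np.argmax(np.abs(modes), axis=0), np.arange(n_modes)])
    return modes * signs


def generate_population(
    base: VertebraParams,
    n: int,
    n_modes: int,
    mode_scales,
    seed: int = 0,
) -> tuple[list[tuple[TriangleMesh, GroundTruth]], np.ndarray, np.ndarray]:
    """Population of corresponded vertebrae with known low-rank variation.

    Each mesh is the base vertebra displaced by a linear combination of
    ``n_modes`` smooth orthonormal fields with zero-mean normal coefficients
    of the stated scales (mm).  Returns ``(samples, coefficients, modes)``
    where ``coefficients`` is (n, n_modes) and ``modes`` is (3N, n_modes).
    """
    if n < n_modes + 1:
        raise ValueError("need n >= n_modes + 1 shapes")
    base_mesh, base_gt = generate_vertebra(base)
    nv = len(base_mesh.vertices)
    if n_modes > nv // 10:
        raise ValueError("n_modes too large for the template vertex count")
    mode_scales = np.broadcast_to(np.asarray(mode_scales, dtype=float), (n_modes,))
    modes = _smooth_mode_fields(base_mesh, n_modes)
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(0.0, 1.0, size=(n, n_modes)) * mode_scales
    samples = []
    base_flat = np.asarray(base_mesh.vertices).ravel()
    for i in range(n):
        verts = (base_flat + modes @ coeffs[i]).reshape(-1, 3)
        m = new_mesh(verts, base_mesh.faces)
        gt = GroundTruth(
            labels=base_gt.labels.copy(),
            landmarks=_class_landmarks(m, base_gt.labels),
            endplates={k: v.copy() for k, v in base_gt.endplates.items()},
            facets={k: v.copy() for k, v in base_gt.facets.items()},
            ligament_sites=dict(base_gt.ligament_sites),
        )
        samples.append((m, gt))
    return samples, coeffs, modes


# ---------------------------------------------------------------------------
# FSU assembly


@dataclass
class FSU:
    """A generated functional spine unit: two vertebrae plus disc metadata."""

    upper_mesh: TriangleMesh
    upper_gt: GroundTruth
    lower_mesh: TriangleMesh
    lower_gt: GroundTruth
    spec: FSUSpec
    disc_region: dict

    @property
    def meshes(self) -> tuple[TriangleMesh, TriangleMesh]:
        return self.upper_mesh, self.lower_mesh


def _mean_set_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean over points of a of the distance to the closest point of b."""
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def _min_set_distance(a: np.ndarray, b: np.ndarray) -> float:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def generate_fsu(spec: FSUSpec) -> FSU:
    """Stack two vertebrae into an FSU with prescribed disc height and facet gap.

    The upper vertebra is translated along +z until the mean closest-point
    distance between the opposing labelled endplates equals ``disc_height``;
    facet clearance below ``facet_gap`` is then resolved by locally lifting
    the upper vertebra's inferior facet patches (facet vertices only).
    """
    lower_mesh, lower_gt = generate_vertebra(replace(spec.lower, seed=spec.seed * 2 + 1))
    upper_mesh, upper_gt = generate_vertebra(replace(spec.upper, seed=spec.seed * 2 + 2))

    lo_ep = np.asarray(lower_mesh.vertices)[lower_gt.endplates["superior"]]
    up_ep0 = np.asarray(upper_mesh.vertices)[upper_gt.endplates["inferior"]]

    def gap(tz: float) -> float:
        return _mean_set_distance(lo_ep, up_ep0 + [0, 0, tz]) - spec.disc_height

    z0 = lo_ep[:, 2].max() - up_ep0[:, 2].min()
    tz = brentq(gap, z0, z0 + 4 * spec.disc_height, xtol=1e-10)
    uv = np.asarray(upper_mesh.vertices) + [0.0, 0.0, tz]
    upper_mesh = new_mesh(uv, upper_mesh.faces)

    # enforce signed facet clearance by lifting only the upper inferior
    # facet patches (the automatic facet-joint gap creation)
    from .mesh import signed_region_clearance

    for side in ("left", "right"):
        lo_idx = lower_gt.facets[f"superior_{side}"]
        up_idx = upper_gt.facets[f"inferior_{side}"]
        total = 0.0
        for _ in range(12):
            clearance = signed_region_clearance(upper_mesh, up_idx, lower_mesh, lo_idx)
            if clearance >= spec.facet_gap - 1e-9:
                break
            lift = spec.facet_gap - clearance
            total += lift
            if total > 8.0:
                raise ValueError("negative facet clearance too large to resolve")
            uv = np.asarray(upper_mesh.vertices).copy()
            direction = uv[up_idx].mean(axis=0) - np.asarray(
                lower_mesh.vertices)[lo_idx].mean(axis=0)
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            uv[up_idx] += lift * direction
            upper_mesh = new_mesh(uv, upper_mesh.faces)

    # refresh landmarks for the posed upper vertebra
    upper_gt.landmarks = _class_landmarks(upper_mesh, upper_gt.labels)

    lo_top = lo_ep[:, 2].mean()
    disc_region = {
        "axis": np.array([0.0, 0.0, 1.0]),
        "center": np.append(lo_ep[:, :2].mean(axis=0), lo_top + spec.disc_height / 2),
        "height": spec.disc_height,
    }
    fsu = FSU(upper_mesh, upper_gt, lower_mesh, lower_gt, spec, disc_region)
    # no interpenetration: upper mesh must stay above the lower endplate plane
    if _min_set_distance(
        np.asarray(upper_mesh.vertices)[upper_gt.endplates["inferior"]], lo_ep
    ) <= 0:
        raise ValueError("vertebrae interpenetrate after posing")
    return fsu


# ---------------------------------------------------------------------------
# rasterization


def rasterize_labels(
    fsu: FSU,
    spacing=(0.39, 0.39, 0.5),
    boundary_noise: float = 0.0,
    seed: int | None = None,
) -> LabelVolume:
    """Rasterize an FSU to an integer label grid (1 = lower, 2 = upper).

    ``boundary_noise`` perturbs each label boundary by a smooth random field
    of the given standard deviation in voxel units, emulating imperfect
    automated segmentation.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    lo, up = fsu.lower_mesh, fsu.upper_mesh
    bmin = np.minimum(lo.bounds[0], up.bounds[0]) - 3 * spacing
    bmax = np.maximum(lo.bounds[1], up.bounds[1]) + 3 * spacing
    shape = tuple(int(np.ceil((bmax[k] - bmin[k]) / spacing[k])) + 1 for k in range(3))
    data = np.zeros(shape, dtype=np.int16)
    rng = np.random.default_rng(fsu.spec.seed if seed is None else seed)
    for label, mesh in ((1, lo), (2, up)):
        mask = mesh_to_mask(mesh, bmin, spacing, shape)
        if boundary_noise > 0:
            sdf = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(~mask)
            noise = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
            noise *= boundary_noise / max(noise.std(), 1e-12)
            mask = (sdf + noise) > 0.5
        if not mask.any():
            raise ValueError(f"vertebra {label} vanished at this voxel spacing")
        data[mask & (data == 0)] = label
    return LabelVolume(data, spacing, bmin)
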