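"""Assembly of FSU finite-element models and FEBio export.

Input: two fitted, annotated vertebral surface meshes (template topology, so
facet / endplate patches and ligament attachment sites transfer by vertex
index).  Output: an :class:`FSUModel` holding

* volumetric bone meshes (tetrahedra on a voxel lattice, split into a
  cortical shell and trabecular core, with endplate element tags),
* a structured hexahedral intervertebral disc spanning the endplate gap,
  nucleus/annulus element sets and two criss-cross fiber direction fields
  on the annulus,
* seven nonlinear tension-only ligaments (ALL, PLL, SSL, ISL, LF and the
  left/right intertransverse representatives),
* left/right facet sliding-contact pairs,
* boundary conditions (inferior endplate fully fixed; superior endplate of
  the upper vertebra rigid, carrying the pure-moment load), and
* the grade-dependent material set.

``write_febio`` serializes the model to the FEBio 2.5 XML input dialect
(geometry in mm, moments in N mm — the 7.5 N m protocol peak becomes 7500);
``read_febio`` parses those files back for lossless round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .materials import MaterialSet, materials_for_grade
from .mesh import (
    TriangleMesh,
    closest_point_on_surface,
    mesh_to_mask,
    new_mesh,
    ray_surface_first_hit,
)
from .mesh import patch_faces as _patch_faces
from .mesh import signed_region_clearance as _signed_patch_clearance
from .synthetic import LIGAMENT_SITES, GroundTruth

__all__ = [
    "LoadCase",
    "BoneMesh",
    "DiscMesh",
    "Ligament",
    "FEConfig",
    "FSUModel",
    "transfer_template_annotations",
    "enforce_facet_gap",
    "tetrahedralize_with_shell",
    "build_disc_mesh",
    "attach_ligaments",
    "assemble_fsu_model",
    "write_febio",
    "read_febio",
    "DEFAULT_LIGAMENT_CURVES",
    "LOAD_DIRECTIONS",
]


# moment axes (unit vectors) per load direction, package coordinates
LOAD_DIRECTIONS = {
    "flexion": np.array([-1.0, 0.0, 0.0]),
    "extension": np.array([1.0, 0.0, 0.0]),
    "lateral_bending_right": np.array([0.0, 1.0, 0.0]),
    "lateral_bending_left": np.array([0.0, -1.0, 0.0]),
    "axial_rotation_left": np.array([0.0, 0.0, 1.0]),
    "axial_rotation_right": np.array([0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class LoadCase:
    """Pure-moment load: direction name, peak magnitude (N m), increments."""

    direction: str
    peak_moment: float = 7.5
    increments: int = 15

    def __post_init__(self) -> None:
        if self.direction not in LOAD_DIRECTIONS:
            raise ValueError(f"unknown load direction {self.direction!r}")
        if self.peak_moment <= 0:
            raise ValueError("peak moment must be positive")
        if self.increments < 1:
            raise ValueError("need at least 1 increment")

    @property
    def axis(self) -> np.ndarray:
        return LOAD_DIRECTIONS[self.direction]


# ---------------------------------------------------------------------------
# annotation transfer and facet clearance


def transfer_template_annotations(model, fitted_mesh: TriangleMesh) -> GroundTruth:
    """Map template annotations onto a fitted mesh by vertex correspondence.

    The fitted mesh must keep the template topology; patches and ligament
    sites transfer by index, landmarks are recomputed as the projected
    region centroids of the fitted geometry.
    """
    ann = model.annotations
    if len(fitted_mesh.vertices) != len(model.mean_vertices) or not np.array_equal(
        np.asarray(fitted_mesh.faces), np.asarray(model.faces)
    ):
        raise ValueError("fitted mesh does not share the template topology")
    from .parts import landmarks_from_parts

    return GroundTruth(
        labels=ann.labels.copy(),
        landmarks=landmarks_from_parts(fitted_mesh, ann.labels),
        endplates={k: v.copy() for k, v in ann.endplates.items()},
        facets={k: v.copy() for k, v in ann.facets.items()},
        ligament_sites=dict(ann.ligament_sites),
    )


def enforce_facet_gap(
    upper_mesh: TriangleMesh,
    lower_mesh: TriangleMesh,
    upper_ann: GroundTruth,
    lower_ann: GroundTruth,
    min_gap: float = 0.25,
    max_adjustment: float = 2.0,
) -> tuple[TriangleMesh, TriangleMesh]:
    """Guarantee facet-joint clearance by fine local mesh adjustment.

    Where the opposing facet-cartilage patches of the fitted meshes are
    closer than ``min_gap`` (or interpenetrate, as segmentation errors in
    the facet region can cause), the upper vertebra's inferior facet patch
    is displaced along the patch separation direction just enough to restore
    the gap.  Only facet-region vertices move; the lower mesh is returned
    unchanged.
    """
    for side in ("left", "right"):
        up_idx = upper_ann.facets[f"inferior_{side}"]
        lo_idx = lower_ann.facets[f"superior_{side}"]
        total = 0.0
        for _ in range(12):
            clearance = _signed_patch_clearance(upper_mesh, up_idx, lower_mesh, lo_idx)
            if clearance >= min_gap - 1e-9:
                break
            shift = min_gap - clearance
            total += shift
            if total > max_adjustment + min_gap:
                raise ValueError(
                    f"facet penetration on the {side} side requires a "
                    f"{total:.2f} mm adjustment, above the {max_adjustment} mm cap"
                )
            uv = np.asarray(upper_mesh.vertices).copy()
            lo_pts = np.asarray(lower_mesh.vertices)[lo_idx]
            direction = uv[up_idx].mean(axis=0) - lo_pts.mean(axis=0)
            direction /= max(np.linalg.norm(direction), 1e-12)
            uv[up_idx] += shift * direction
            upper_mesh = new_mesh(uv, upper_mesh.faces)
    return upper_mesh, lower_mesh


# ---------------------------------------------------------------------------
# bone tetrahedralization (voxel lattice, Kuhn 6-tet split)

# the six path-permutations of the Kuhn/Freudenthal cube decomposition
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


@dataclass
class BoneMesh:
    """Volumetric bone mesh: tets with cortical/trabecular and endplate tags."""

    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) 0-based
    is_cortical: np.ndarray  # (m,) bool
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())


def tetrahedralize_with_shell(
    surface: TriangleMesh,
    shell_thickness: float = 1.0,
    voxel_pitch: float | None = None,
    endplate_sets: dict[str, np.ndarray] | None = None,
) -> BoneMesh:
    """Fill a closed surface with tetrahedra and tag a cortical shell.

    The interior is sampled on a voxel lattice (pitch defaults to 1/24 of
    the largest extent) and each interior voxel is split into six conforming
    tetrahedra (Kuhn decomposition), guaranteeing positive Jacobians.
    Elements whose centroid lies within ``shell_thickness`` of the surface
    are tagged cortical, the rest trabecular.  If ``endplate_sets`` maps
    names to surface vertex indices, a one-element-deep endplate element set
    is derived for each.
    """
    if not surface.is_watertight:
        raise ValueError("tetrahedralization requires a closed surface")
    if shell_thickness <= 0:
        raise ValueError("shell thickness must be positive")
    if voxel_pitch is None:
        voxel_pitch = float(surface.extents.max()) / 24.0
    origin = surface.bounds[0] - 1.5 * voxel_pitch
    spacing = np.full(3, voxel_pitch)
    shape = tuple(
        int(np.ceil((surface.bounds[1][k] - origin[k]) / voxel_pitch)) + 2
        for k in range(3)
    )
    mask = mesh_to_mask(surface, origin, spacing, shape)
    vox = np.argwhere(mask)
    if len(vox) == 0:
        raise ValueError("voxel pitch too coarse: no interior voxels")

    # voxel corner grid -> compact node array
    corners = (
        vox[:, None, :]
        + np.array(
            [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        )[None]
    )  # (V, 8, 3), corner order: binary (i, j, k)
    flat = (
        corners[..., 0] * (shape[1] + 1) * (shape[2] + 1)
        + corners[..., 1] * (shape[2] + 1)
        + corners[..., 2]
    )
    uniq, inv = np.unique(flat, return_inverse=True)
    inv = inv.reshape(len(vox), 8)
    gi = uniq // ((shape[1] + 1) * (shape[2] + 1))
    gj = (uniq // (shape[2] + 1)) % (shape[1] + 1)
    gk = uniq % (shape[2] + 1)
    # corners sit half a voxel off the center lattice
    nodes = origin + (np.column_stack([gi, gj, gk]) - 0.5) * voxel_pitch

    def corner(offsets) -> int:
        i, j, k = offsets
        return i * 4 + j * 2 + k

    tets = []
    for perm in _KUHN_PERMS:
        path = [np.zeros(3, dtype=int)]
        for axis in perm:
            step = path[-1].copy()
            step[axis] += 1
            path.append(step)
        tet = [corner(p) for p in path]
        tets.append(tet)
    tets = np.array(tets)  # (6, 4) corner indices
    elements = inv[:, tets].reshape(-1, 4)

    # enforce positive volumes
    x = nodes[elements]
    vol = np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0
    flip = vol < 0
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]

    centroids = nodes[elements].mean(axis=1)
    cp, dist, tid = closest_point_on_surface(centroids, surface, candidates=8)
    is_cortical = dist <= shell_thickness

    element_sets: dict[str, np.ndarray] = {}
    if endplate_sets:
        faces = np.asarray(surface.faces)
        for name, vidx in endplate_sets.items():
            member = np.zeros(len(surface.vertices), dtype=bool)
            member[vidx] = True
            face_in = member[faces].sum(axis=1) >= 2
            near = face_in[tid] & (dist <= voxel_pitch)
            element_sets[f"endplate_{name}"] = np.where(near)[0]

    bone = BoneMesh(nodes, elements, is_cortical, element_sets)
    if np.any(bone.tet_volumes() <= 0):
        raise ValueError("tetrahedralization produced inverted elements")
    return bone


# ---------------------------------------------------------------------------
# intervertebral disc hex mesh


@dataclass
class DiscMesh:
    """Structured hexahedral IVD mesh tied to the endplates.

    Bottom boundary nodes lie on the lower vertebra's superior endplate,
    top boundary nodes on the upper vertebra's inferior endplate (both
    within 1e-6 mm by ray projection); annulus elements carry two unit
    fiber directions at +/- the fiber angle to the transverse plane.
    """

    nodes: np.ndarray  # (n, 3)
    hexes: np.ndarray  # (m, 8) 0-based
    nucleus_elements: np.ndarray
    annulus_elements: np.ndarray
    fiber_directions: np.ndarray  # (m, 2, 3); zero rows for nucleus elements
    bottom_nodes: np.ndarray
    top_nodes: np.ndarray
    height: float

    def hex_volumes(self) -> np.ndarray:
        """Exact trilinear hex volumes via 2x2x2 Gauss quadrature."""
        from .simulate import hex_shape_gradients

        _, wdet = hex_shape_gradients(self.nodes, self.hexes)
        return wdet.sum(axis=1)

    def corner_jacobians(self) -> np.ndarray:
        from .simulate import hex_shape_gradients

        _, wdet = hex_shape_gradients(self.nodes, self.hexes)
        return wdet

    def total_volume(self) -> float:
        return float(self.hex_volumes().sum())


def _square_to_disk(s: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # elliptical square-to-disk map: non-degenerate all-quad parameterization
    return s * np.sqrt(1.0 - 0.5 * t**2), t * np.sqrt(1.0 - 0.5 * s**2)


def build_disc_mesh(
    lower_mesh: TriangleMesh,
    lower_endplate: np.ndarray,
    upper_mesh: TriangleMesh,
    upper_endplate: np.ndarray,
    n_side: int = 6,
    n_axial: int = 3,
    nucleus_fraction: float = 0.44,
    fiber_angle_deg: float = 30.0,
    footprint_scale: float = 0.9,
) -> DiscMesh:
    """Structured IVD hex mesh spanning the endplate gap.

    An elliptical footprint is fitted to the opposing endplate patches and a
    (n_side x n_side x n_axial) hex grid is stretched between the two
    surfaces by vertical ray projection, so the disc height equals the mean
    endplate distance by construction.  The central elements closest to
    ``nucleus_fraction`` of the total volume are tagged nucleus, the rest
    annulus with criss-cross fiber directions.
    """
    lo_pts = np.asarray(lower_mesh.vertices)[lower_endplate]
    up_pts = np.asarray(upper_mesh.vertices)[upper_endplate]

    n_lo = np.asarray(lower_mesh.vertex_normals)[lower_endplate].mean(axis=0)
    n_up = np.asarray(upper_mesh.vertex_normals)[upper_endplate].mean(axis=0)
    n_lo /= np.linalg.norm(n_lo)
    n_up /= np.linalg.norm(n_up)
    if np.degrees(np.arccos(np.clip(-n_lo @ n_up, -1, 1))) > 45.0:
        raise ValueError("endplates are not opposing (normal angle > 45 deg)")

    # footprint: largest ellipse in the xy intersection box of both patches
    x0 = max(lo_pts[:, 0].min(), up_pts[:, 0].min())
    x1 = min(lo_pts[:, 0].max(), up_pts[:, 0].max())
    y0 = max(lo_pts[:, 1].min(), up_pts[:, 1].min())
    y1 = min(lo_pts[:, 1].max(), up_pts[:, 1].max())
    cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    a = footprint_scale * 0.5 * (x1 - x0)
    b = footprint_scale * 0.5 * (y1 - y0)
    if a <= 0 or b <= 0:
        raise ValueError("degenerate endplate footprint")

    n1 = n_side + 1
    s, t = np.meshgrid(np.linspace(-1, 1, n1), np.linspace(-1, 1, n1), indexing="ij")
    ds, dt = _square_to_disk(s.ravel(), t.ravel())
    px = cx + a * ds
    py = cy + b * dt

    z_hi = lo_pts[:, 2].max() + 1.0
    origins_dn = np.column_stack([px, py, np.full(px.shape, z_hi)])
    t_dn, hit_dn = ray_surface_first_hit(
        origins_dn, np.tile([0.0, 0.0, -1.0], (len(px), 1)), lower_mesh
    )
    z_lo_start = up_pts[:, 2].min() - 1.0
    origins_up = np.column_stack([px, py, np.full(px.shape, z_lo_start)])
    t_up, hit_up = ray_surface_first_hit(
        origins_up, np.tile([0.0, 0.0, 1.0], (len(px), 1)), upper_mesh
    )
    if not (hit_dn.all() and hit_up.all()):
        raise ValueError("disc footprint extends beyond an endplate; reduce it")
    z_bot = z_hi - t_dn
    z_top = z_lo_start + t_up
    if np.any(z_top <= z_bot):
        raise ValueError("endplates cross within the disc footprint")

    nz = n_axial + 1
    nodes = np.empty((n1 * n1 * nz, 3))
    for layer in range(nz):
        f = layer / n_axial
        zl = (1 - f) * z_bot + f * z_top
        nodes[layer * n1 * n1 : (layer + 1) * n1 * n1] = np.column_stack([px, py, zl])

    def nid(i: int, j: int, layer: int) -> int:
        return layer * n1 * n1 + i * n1 + j

    hexes = []
    for layer in range(n_axial):
        for i in range(n_side):
            for j in range(n_side):
                hexes.append(
                    [
                        nid(i, j, layer), nid(i + 1, j, layer),
                        nid(i + 1, j + 1, layer), nid(i, j + 1, layer),
                        nid(i, j, layer + 1), nid(i + 1, j, layer + 1),
                        nid(i + 1, j + 1, layer + 1), nid(i, j + 1, layer + 1),
                    ]
                )
    hexes = np.asarray(hexes, dtype=np.int64)

    from .simulate import hex_shape_gradients

    _, wdet = hex_shape_gradients(nodes, hexes)
    if np.any(wdet <= 0):
        raise ValueError("disc mesh has non-positive Jacobians")
    vols = wdet.sum(axis=1)

    # nucleus = central prefix of elements (by footprint radius) whose
    # cumulative volume is closest to the requested fraction
    cent = nodes[hexes].mean(axis=1)
    rho = np.sqrt(((cent[:, 0] - cx) / a) ** 2 + ((cent[:, 1] - cy) / b) ** 2)
    # cut between distinct radius levels (never splitting a symmetric ring)
    # at the level whose cumulative volume is closest to the target fraction
    levels = np.unique(np.round(rho, 9))
    cuts = [(np.abs(vols[rho <= lv + 1e-9].sum() / vols.sum() - nucleus_fraction), lv)
            for lv in levels[:-1]]
    if cuts:
        _, best = min(cuts)
        nucleus = np.where(rho <= best + 1e-9)[0]
        annulus = np.where(rho > best + 1e-9)[0]
    else:
        # too coarse to separate a core: model the whole disc as annulus
        nucleus = np.array([], dtype=np.int64)
        annulus = np.arange(len(hexes))

    theta = np.radians(fiber_angle_deg)
    fibers = np.zeros((len(hexes), 2, 3))
    zhat = np.array([0.0, 0.0, 1.0])
    for e in annulus:
        radial = np.array([cent[e, 0] - cx, cent[e, 1] - cy, 0.0])
        radial /= max(np.linalg.norm(radial), 1e-9)
        circ = np.cross(zhat, radial)
        fibers[e, 0] = np.cos(theta) * circ + np.sin(theta) * zhat
        fibers[e, 1] = np.cos(theta) * circ - np.sin(theta) * zhat

    bottom = np.arange(n1 * n1)
    top = np.arange((nz - 1) * n1 * n1, nz * n1 * n1)
    height = float((z_top - z_bot).mean())
    return DiscMesh(nodes, hexes, nucleus, annulus, fibers, bottom, top, height)


# ---------------------------------------------------------------------------
# ligaments


# piecewise-linear force-strain curves (strain, force N): a compliant toe
# region followed by a stiffer linear branch; library defaults are
# literature-shaped and fully configurable
DEFAULT_LIGAMENT_CURVES: dict[str, tuple[tuple[float, float], ...]] = {
    "ALL": ((0.0, 0.0), (0.10, 20.0), (0.45, 500.0)),
    "PLL": ((0.0, 0.0), (0.10, 15.0), (0.45, 350.0)),
    "SSL": ((0.0, 0.0), (0.12, 10.0), (0.50, 180.0)),
    "ISL": ((0.0, 0.0), (0.10, 8.0), (0.45, 140.0)),
    "LF": ((0.0, 0.0), (0.08, 20.0), (0.40, 320.0)),
    "ITL_left": ((0.0, 0.0), (0.08, 10.0), (0.40, 180.0)),
    "ITL_right": ((0.0, 0.0), (0.08, 10.0), (0.40, 180.0)),
}


@dataclass
class Ligament:
    """One tension-only nonlinear ligament element between two vertebrae."""

    name: str
    upper_point: np.ndarray
    lower_point: np.ndarray
    rest_length: float
    curve: np.ndarray  # (k, 2): strain, force (N); strictly increasing strain

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if np.any(np.diff(self.curve[:, 0]) <= 0):
            raise ValueError(f"ligament {self.name}: curve strains must increase")
        if self.rest_length <= 0:
            raise ValueError(f"ligament {self.name}: rest length must be positive")


def attach_ligaments(
    upper_mesh: TriangleMesh,
    upper_ann: GroundTruth,
    lower_mesh: TriangleMesh,
    lower_ann: GroundTruth,
    curves: dict | None = None,
) -> list[Ligament]:
    """Create the seven named ligaments between corresponding attachment sites."""
    curves = {**DEFAULT_LIGAMENT_CURVES, **(curves or {})}
    missing = [s for s in LIGAMENT_SITES if s not in upper_ann.ligament_sites
               or s not in lower_ann.ligament_sites]
    if missing:
        raise ValueError(f"missing ligament attachment sites: {missing}")
    out = []
    for name in LIGAMENT_SITES:
        pu = np.asarray(upper_mesh.vertices)[upper_ann.ligament_sites[name]]
        pl = np.asarray(lower_mesh.vertices)[lower_ann.ligament_sites[name]]
        rest = float(np.linalg.norm(pu - pl))
        out.append(Ligament(name, pu.copy(), pl.copy(), rest, np.array(curves[name])))
    return out


# ---------------------------------------------------------------------------
# full model


@dataclass
class FEConfig:
    """Geometric discretization choices for the FE assembly."""

    shell_thickness: float = 1.0  # mm, cortical shell depth
    voxel_pitch: float | None = None  # mm, bone tet lattice (None = auto)
    disc_n_side: int = 6
    disc_n_axial: int = 3
    nucleus_fraction: float = 0.44
    fiber_angle_deg: float = 30.0
    facet_min_gap: float = 0.25  # mm, clearance restored when violated
    facet_plane_angle_deg: float = 45.0  # joint plane orientation vs sagittal
    contact_stiffness: float = 200.0  # N/mm per unit reference area
    build_bone_volumes: bool = True


@dataclass
class FSUModel:
    """Complete FSU FE model ready for simulation and FEBio export."""

    upper_surface: TriangleMesh
    lower_surface: TriangleMesh
    upper_ann: GroundTruth
    lower_ann: GroundTruth
    upper_bone: BoneMesh | None
    lower_bone: BoneMesh | None
    disc: DiscMesh
    ligaments: list[Ligament]
    materials: MaterialSet
    load_cases: list[LoadCase]
    config: FEConfig

    @property
    def facet_pairs(self) -> list[dict]:
        """Left/right sliding contact pairs: upper (moving) vertex sets
        against lower (fixed) facet patches."""
        pairs = []
        for side in ("left", "right"):
            pairs.append(
                {
                    "side": side,
                    "upper_vertices": self.upper_ann.facets[f"inferior_{side}"],
                    "lower_faces": _patch_faces(
                        self.lower_surface, self.lower_ann.facets[f"superior_{side}"]
                    ),
                }
            )
        return pairs

    @property
    def fixed_node_set(self) -> np.ndarray:
        """Inferior endplate vertices of the lower vertebra (all DOFs fixed)."""
        return self.lower_ann.endplates["inferior"]

    @property
    def loaded_node_set(self) -> np.ndarray:
        """Superior endplate vertices of the upper vertebra (rigid plate)."""
        return self.upper_ann.endplates["superior"]

    def validate(self) -> None:
        """Self-validation of all structural invariants; raises on failure."""
        for bone, which in ((self.upper_bone, "upper"), (self.lower_bone, "lower")):
            if bone is not None and np.any(bone.tet_volumes() <= 0):
                raise ValueError(f"{which} bone mesh has non-positive tet volumes")
        if np.any(self.disc.corner_jacobians() <= 0):
            raise ValueError("disc mesh has non-positive Jacobians")
        for idx, mesh, which in (
            (self.disc.bottom_nodes, self.lower_surface, "bottom"),
            (self.disc.top_nodes, self.upper_surface, "top"),
        ):
            d = closest_point_on_surface(self.disc.nodes[idx], mesh, candidates=16)[1]
            if d.max() > 1e-6:
                raise ValueError(
                    f"disc {which} nodes are not tied to the endplate "
                    f"(max gap {d.max():.2e} mm)"
                )
        if len(self.ligaments) != len(LIGAMENT_SITES):
            raise ValueError("expected 7 ligaments")
        for side in ("left", "right"):
            c = _signed_patch_clearance(
                self.upper_surface,
                self.upper_ann.facets[f"inferior_{side}"],
                self.lower_surface,
                self.lower_ann.facets[f"superior_{side}"],
            )
            if c < 0:
                raise ValueError(f"{side} facet surfaces interpenetrate ({c:.3f} mm)")
        if len(self.fixed_node_set) == 0 or len(self.loaded_node_set) == 0:
            raise ValueError("boundary-condition node sets must be non-empty")


def assemble_fsu_model(
    upper_mesh: TriangleMesh,
    lower_mesh: TriangleMesh,
    upper_ann: GroundTruth,
    lower_ann: GroundTruth,
    grade="healthy",
    config: FEConfig | None = None,
    load_cases: list[LoadCase] | None = None,
) -> FSUModel:
    """Assemble the complete FSU FE model from two annotated surfaces.

    Runs the full chain — facet clearance adjustment, bone meshing, disc
    meshing, ligament attachment, material selection, boundary conditions —
    and validates every structural invariant before returning.
    """
    cfg = config or FEConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"FSU assembly failed at stage '{name}': {exc}") from exc

    upper_mesh, lower_mesh = _stage(
        "facet gap", enforce_facet_gap, upper_mesh, lower_mesh, upper_ann,
        lower_ann, cfg.facet_min_gap,
    )
    upper_bone = lower_bone = None
    if cfg.build_bone_volumes:
        upper_bone = _stage(
            "upper bone meshing", tetrahedralize_with_shell, upper_mesh,
            cfg.shell_thickness, cfg.voxel_pitch,
            {k: v for k, v in upper_ann.endplates.items()},
        )
        lower_bone = _stage(
            "lower bone meshing", tetrahedralize_with_shell, lower_mesh,
            cfg.shell_thickness, cfg.voxel_pitch,
            {k: v for k, v in lower_ann.endplates.items()},
        )
    disc = _stage(
        "disc meshing", build_disc_mesh, lower_mesh,
        lower_ann.endplates["superior"], upper_mesh,
        upper_ann.endplates["inferior"], cfg.disc_n_side, cfg.disc_n_axial,
        cfg.nucleus_fraction, cfg.fiber_angle_deg,
    )
    ligaments = _stage(
        "ligaments", attach_ligaments, upper_mesh, upper_ann, lower_mesh, lower_ann
    )
    materials = _stage("materials", materials_for_grade, grade)
    if load_cases is None:
        load_cases = [LoadCase(d) for d in LOAD_DIRECTIONS]
    model = FSUModel(
        upper_surface=upper_mesh,
        lower_surface=lower_mesh,
        upper_ann=upper_ann,
        lower_ann=lower_ann,
        upper_bone=upper_bone,
        lower_bone=lower_bone,
        disc=disc,
        ligaments=ligaments,
        materials=materials,
        load_cases=list(load_cases),
        config=cfg,
    )
    _stage("validation", model.validate)
    return model


# ---------------------------------------------------------------------------
# FEBio 2.5 export / import


def _mat_elem(parent, mid, name, mtype, params: dict):
    m = etree.SubElement(parent, "material", id=str(mid), name=name, type=mtype)
    for k, v in params.items():
        etree.SubElement(m, k).text = f"{v:.9g}"
    return m


def write_febio(model: FSUModel, path: str | Path, load_case: LoadCase | None = None) -> None:
    """Write the model as a FEBio 2.5 XML input file.

    Geometry in mm; the pure moment is written in N mm (1 N m = 1000 N mm)
    on the rigid loading plate, ramped by a linear load curve.  Node and
    element ids are 1-based and contiguous.  Files round-trip losslessly
    through :func:`read_febio`.
    """
    model.validate()
    lc = load_case or model.load_cases[0]
    mats = model.materials

    root = etree.Element("febio_spec", version="2.5")
    etree.SubElement(root, "Module", type="solid")

    mat = etree.SubElement(root, "Material")
    c = mats.cortical
    _mat_elem(mat, 1, "cortical bone", "orthotropic elastic", {
        "E1": c.E1, "E2": c.E2, "E3": c.E3,
        "v12": c.nu12, "v23": c.nu23, "v31": c.nu31,
        "G12": c.G12, "G23": c.G23, "G31": c.G31,
    })
    _mat_elem(mat, 2, "trabecular bone", "neo-Hookean",
              {"E": mats.trabecular.E, "v": mats.trabecular.nu})
    _mat_elem(mat, 3, "vertebral endplate", "neo-Hookean",
              {"E": mats.endplate.E, "v": mats.endplate.nu})
    _mat_elem(mat, 4, "nucleus pulposus", "neo-Hookean",
              {"E": mats.nucleus.E, "v": mats.nucleus.nu})
    ann_mat = etree.SubElement(mat, "material", id="5", name="annulus",
                               type="solid mixture")
    solid = etree.SubElement(ann_mat, "solid", type="Holmes-Mow")
    for k, v in (("E", mats.annulus.E), ("v", mats.annulus.nu),
                 ("beta", mats.annulus.beta)):
        etree.SubElement(solid, k).text = f"{v:.9g}"
    for sign, angle in (("+", model.config.fiber_angle_deg),
                        ("-", -model.config.fiber_angle_deg)):
        fib = etree.SubElement(ann_mat, "solid", type="fiber-exp-pow")
        for k, v in (("ksi", mats.fiber.xi), ("alpha", mats.fiber.alpha),
                     ("beta", mats.fiber.beta), ("theta", angle), ("phi", 90.0)):
            etree.SubElement(fib, k).text = f"{v:.9g}"
    _mat_elem(mat, 6, "facet cartilage", "neo-Hookean",
              {"E": mats.facet_cartilage.E, "v": mats.facet_cartilage.nu})
    rigid = etree.SubElement(mat, "material", id="7", name="loading plate",
                             type="rigid body")
    com = np.asarray(model.upper_surface.vertices)[model.loaded_node_set].mean(axis=0)
    etree.SubElement(rigid, "center_of_mass").text = ",".join(f"{x:.9g}" for x in com)

    # geometry: concatenate node blocks with global 1-based ids
    geo = etree.SubElement(root, "Geometry")
    blocks = []  # (name, nodes array)
    blocks.append(("lower_surface", np.asarray(model.lower_surface.vertices)))
    blocks.append(("upper_surface", np.asarray(model.upper_surface.vertices)))
    if model.lower_bone is not None:
        blocks.append(("lower_bone", model.lower_bone.nodes))
        blocks.append(("upper_bone", model.upper_bone.nodes))
    blocks.append(("disc", model.disc.nodes))
    offsets = {}
    off = 0
    nodes_el = etree.SubElement(geo, "Nodes", name="all")
    for name, arr in blocks:
        offsets[name] = off
        for i, p in enumerate(arr):
            n = etree.SubElement(nodes_el, "node", id=str(off + i + 1))
            n.text = ",".join(f"{x:.12g}" for x in p)
        off += len(arr)

    def elem_block(name, etype, matid, conn, offset):
        el = etree.SubElement(geo, "Elements", type=etype, mat=str(matid), name=name)
        base = elem_block.counter
        for i, row in enumerate(conn):
            e = etree.SubElement(el, "elem", id=str(base + i + 1))
            e.text = ",".join(str(offset + int(v) + 1) for v in row)
        elem_block.counter += len(conn)

    elem_block.counter = 0
    if model.lower_bone is not None:
        for bone, name in ((model.lower_bone, "lower"), (model.upper_bone, "upper")):
            o = offsets[f"{name}_bone"]
            elem_block(f"{name}_cortical", "tet4", 1, bone.tets[bone.is_cortical], o)
            elem_block(f"{name}_trabecular", "tet4", 2, bone.tets[~bone.is_cortical], o)
    od = offsets["disc"]
    elem_block("nucleus", "hex8", 4, model.disc.hexes[model.disc.nucleus_elements], od)
    elem_block("annulus", "hex8", 5, model.disc.hexes[model.disc.annulus_elements], od)
    # facet cartilage patches as tri3 shells on the surface meshes
    for pair in model.facet_pairs:
        lf = pair["lower_faces"]
        elem_block(f"facet_lower_{pair['side']}", "tri3", 6, lf, offsets["lower_surface"])
        uf = _patch_faces(model.upper_surface, pair["upper_vertices"])
        elem_block(f"facet_upper_{pair['side']}", "tri3", 6, uf, offsets["upper_surface"])
    # rigid loading plate: superior endplate triangles of the upper vertebra
    plate_faces = _patch_faces(model.upper_surface, model.loaded_node_set)
    elem_block("loading_plate", "tri3", 7, plate_faces, offsets["upper_surface"])

    # node sets
    fixed = etree.SubElement(geo, "NodeSet", name="fixed_inferior_endplate")
    for v in model.fixed_node_set:
        etree.SubElement(fixed, "node", id=str(offsets["lower_surface"] + int(v) + 1))
    dbot = etree.SubElement(geo, "NodeSet", name="disc_bottom")
    for v in model.disc.bottom_nodes:
        etree.SubElement(dbot, "node", id=str(offsets["disc"] + int(v) + 1))
    dtop = etree.SubElement(geo, "NodeSet", name="disc_top")
    for v in model.disc.top_nodes:
        etree.SubElement(dtop, "node", id=str(offsets["disc"] + int(v) + 1))

    # boundary conditions
    bnd = etree.SubElement(root, "Boundary")
    fix = etree.SubElement(bnd, "fix", bc="x,y,z", node_set="fixed_inferior_endplate")  # noqa: F841

    # contact: tied disc-endplate interfaces and sliding facet joints
    contact_root = etree.SubElement(root, "Contact")
    for nset, which in (("disc_bottom", "lower"), ("disc_top", "upper")):
        tied = etree.SubElement(contact_root, "contact", type="tied-node-on-facet",
                                name=f"tied_{nset}")
        etree.SubElement(tied, "primary").text = nset
        etree.SubElement(tied, "secondary").text = f"{which}_surface"
    for pair in model.facet_pairs:
        sl = etree.SubElement(contact_root, "contact", type="sliding-node-on-facet",
                              name=f"facet_{pair['side']}")
        etree.SubElement(sl, "penalty").text = f"{model.config.contact_stiffness:.9g}"
        etree.SubElement(sl, "primary").text = f"facet_upper_{pair['side']}"
        etree.SubElement(sl, "secondary").text = f"facet_lower_{pair['side']}"

    # ligaments as nonlinear tension-only discrete elements
    disc_el = etree.SubElement(root, "Discrete")
    for li, lig in enumerate(model.ligaments):
        dm = etree.SubElement(disc_el, "discrete_material", id=str(li + 1),
                              name=lig.name, type="nonlinear spring")
        etree.SubElement(dm, "tension_only").text = "1"
        etree.SubElement(dm, "rest_length").text = f"{lig.rest_length:.12g}"
        curve = etree.SubElement(dm, "force_strain_curve")
        for strain, force in lig.curve:
            etree.SubElement(curve, "point").text = f"{strain:.9g},{force:.9g}"
        de = etree.SubElement(disc_el, "delem", dmat=str(li + 1))
        etree.SubElement(de, "upper").text = ",".join(f"{x:.12g}" for x in lig.upper_point)
        etree.SubElement(de, "lower").text = ",".join(f"{x:.12g}" for x in lig.lower_point)

    # load: ramped pure moment on the rigid plate (N mm)
    loaddata = etree.SubElement(root, "LoadData")
    curve = etree.SubElement(loaddata, "loadcurve", id="1", type="linear")
    etree.SubElement(curve, "point").text = "0,0"
    etree.SubElement(curve, "point").text = "1,1"
    loads = etree.SubElement(root, "Loads")
    rb = etree.SubElement(loads, "rigid_body", mat="7")
    axis = lc.axis * lc.peak_moment * 1000.0  # N m -> N mm
    for bc, val in zip(("Ru", "Rv", "Rw"), axis):
        if val != 0.0:
            f = etree.SubElement(rb, "force", bc=bc, lc="1")
            f.text = f"{val:.9g}"

    steps = etree.SubElement(root, "Step")
    ctrl = etree.SubElement(steps, "Control")
    etree.SubElement(ctrl, "time_steps").text = str(lc.increments)
    etree.SubElement(ctrl, "step_size").text = f"{1.0 / lc.increments:.9g}"

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_febio(path: str | Path) -> dict:
    """Parse a FEBio file written by :func:`write_febio`.

    Returns a dict with nodes, element blocks, materials, contacts,
    ligaments, node sets and the rigid-body load — everything needed to
    verify a lossless round-trip.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    out: dict = {"version": root.get("version")}

    nodes = []
    ids = []
    for n in root.findall(".//Geometry/Nodes/node"):
        ids.append(int(n.get("id")))
        nodes.append([float(x) for x in n.text.split(",")])
    out["node_ids"] = np.array(ids)
    out["nodes"] = np.array(nodes)

    out["elements"] = {}
    for block in root.findall(".//Geometry/Elements"):
        conn = []
        eids = []
        for e in block.findall("elem"):
            eids.append(int(e.get("id")))
            conn.append([int(v) for v in e.text.split(",")])
        out["elements"][block.get("name")] = {
            "type": block.get("type"),
            "mat": int(block.get("mat")),
            "ids": np.array(eids),
            "conn": np.array(conn),
        }

    out["materials"] = {}
    for m in root.findall(".//Material/material"):
        entry = {"type": m.get("type"), "name": m.get("name")}
        for child in m:
            if child.tag == "solid":
                entry.setdefault("solids", []).append(
                    {"type": child.get("type"),
                     **{c.tag: float(c.text) for c in child}}
                )
            elif child.tag != "center_of_mass":
                entry[child.tag] = float(child.text)
        out["materials"][int(m.get("id"))] = entry

    out["node_sets"] = {}
    for ns in root.findall(".//Geometry/NodeSet"):
        out["node_sets"][ns.get("name")] = np.array(
            [int(n.get("id")) for n in ns.findall("node")]
        )

    out["contacts"] = [
        {"type": c.get("type"), "name": c.get("name")}
        for c in root.findall(".//Contact/contact")
    ]
    out["ligaments"] = []
    for dm in root.findall(".//Discrete/discrete_material"):
        pts = [
            tuple(float(x) for x in p.text.split(","))
            for p in dm.findall("force_strain_curve/point")
        ]
        out["ligaments"].append(
            {"name": dm.get("name"),
             "rest_length": float(dm.findtext("rest_length")),
             "curve": np.array(pts)}
        )
    loads = []
    for f in root.findall(".//Loads/rigid_body/force"):
        loads.append({"bc": f.get("bc"), "value": float(f.text)})
    out["rigid_loads"] = loads
    fixes = root.find(".//Boundary/fix")
    out["fixed_node_set"] = fixes.get("node_set") if fixes is not None else None
    return out
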