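"""Statistical shape models of vertebrae and landmark-constrained fitting.

A :class:`ShapeModel` is built per vertebral level from a population of
corresponded surface meshes: generalized Procrustes alignment brings the
shapes into a common frame, PCA of the aligned vertex coordinates yields an
orthonormal mode matrix, and the template annotations (four landmarks,
endplate / facet-cartilage patches, ligament attachment vertices) ride along
by vertex index.

Fitting to a target surface follows the registration chain used for
patient-specific model generation: rigid initialization from the four
landmarks, ICP refinement, alternating pose / mode-coefficient optimization
penalized toward the mean, and a final projection of the template vertices
along their normals onto the target surface.  The fitted mesh always keeps
the template topology — the correspondence contract the FE builder relies
on.

Model / results split: ``ShapeModel.fit(target, ...)`` returns a
:class:`FitResult` carrying the coefficients (in units of per-mode standard
deviation), the final rigid transform, fitted and projected meshes, residual
distances and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh, closest_point_on_surface, new_mesh, ray_surface_first_hit
from .synthetic import GroundTruth

__all__ = [
    "RigidTransform",
    "ShapeModel",
    "FitResult",
    "generalized_procrustes",
    "build_shape_model",
    "rigid_from_landmarks",
    "icp_refine",
    "fit_model",
    "project_normals",
]


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid (optionally scaled) transform ``x -> scale * R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points) @ self.rotation.T) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * (self.rotation @ other.translation) + self.translation,
            self.scale * other.scale,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            Rinv, -(Rinv @ self.translation) / self.scale, 1.0 / self.scale
        )


def _kabsch(source: np.ndarray, target: np.ndarray, scale: bool = False) -> RigidTransform:
    """Least-squares rigid (optionally similarity) alignment source -> target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    A = (target - tc).T @ (source - sc)
    Usvd, svals, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(Usvd @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = Usvd @ D @ Vt
    s = 1.0
    if scale:
        var = ((source - sc) ** 2).sum()
        s = float((svals * np.diag(D)).sum() / var)
    t = tc - s * (R @ sc)
    return RigidTransform(R, t, s)


def rigid_from_landmarks(source, target) -> RigidTransform:
    """Optimal rigid transform mapping source landmarks onto target landmarks.

    Accepts (n, 3) arrays or name -> point dicts (matched by key).
    """
    if isinstance(source, dict):
        keys = sorted(source)
        if not isinstance(target, dict) or sorted(target) != keys:
            raise ValueError("landmark dictionaries must share the same names")
        source = np.array([source[k] for k in keys])
        target = np.array([target[k] for k in keys])
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.shape[0] < 3:
        raise ValueError("need at least 3 paired landmarks")
    sv = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("landmarks are collinear or degenerate")
    return _kabsch(source, target)


# ---------------------------------------------------------------------------
# Procrustes + PCA


def generalized_procrustes(
    meshes: list[TriangleMesh],
    scale: bool = False,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[list[TriangleMesh], TriangleMesh]:
    """Iterative rigid alignment of corresponded meshes to their evolving mean.

    Rotation + translation only by default (scale excluded: global size is a
    shape difference the PCA modes should carry).  Stops when the mean shape
    moves less than ``tol`` (mm, RMS).
    """
    faces = np.asarray(meshes[0].faces)
    pts = []
    for m in meshes:
        if np.asarray(m.faces).shape != faces.shape or not np.array_equal(m.faces, faces):
            raise ValueError("all meshes must share identical topology")
        pts.append(np.asarray(m.vertices, dtype=float).copy())
    mean = pts[0] - pts[0].mean(axis=0)
    for _ in range(max_iter):
        aligned = [_kabsch(p, mean, scale=scale).apply(p) for p in pts]
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        shift = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        pts = aligned
        if shift < tol:
            break
    return [new_mesh(p, faces) for p in pts], new_mesh(mean, faces)


@dataclass
class ShapeModel:
    """Mean shape + orthonormal PCA modes + template annotations.

    ``modes`` is (3N, K) with orthonormal columns, ``variances`` the
    corresponding non-increasing PCA variances (mm^2); coefficients are
    expressed in units of per-mode standard deviation throughout.
    """

    mean_vertices: np.ndarray
    faces: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    annotations: GroundTruth

    def __post_init__(self) -> None:
        k = self.modes.shape[1]
        if k:
            gram = self.modes.T @ self.modes
            if not np.allclose(gram, np.eye(k), atol=1e-8):
                raise ValueError("mode columns must be orthonormal")
            if np.any(np.diff(self.variances) > 1e-12):
                raise ValueError("variances must be non-increasing")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def stddevs(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.variances, 0.0))

    @property
    def mean_mesh(self) -> TriangleMesh:
        return new_mesh(self.mean_vertices, self.faces)

    def shape_at(self, b: np.ndarray) -> TriangleMesh:
        """Instance of the model at coefficients ``b`` (sd units)."""
        b = np.zeros(self.n_modes) if b is None else np.asarray(b, dtype=float)
        disp = self.modes @ (b * self.stddevs)
        return new_mesh(self.mean_vertices + disp.reshape(-1, 3), self.faces)

    def template_landmarks(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, dtype=float) for k, v in self.annotations.landmarks.items()}

    def fit(self, target: TriangleMesh, target_landmarks=None, **kwargs) -> "FitResult":
        return fit_model(self, target, target_landmarks, **kwargs)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        ann = self.annotations
        meta = {
            "landmarks": {k: list(map(float, v)) for k, v in ann.landmarks.items()},
            "ligament_sites": {k: int(v) for k, v in ann.ligament_sites.items()},
        }
        np.savez(
            path,
            mean_vertices=self.mean_vertices,
            faces=self.faces,
            modes=self.modes,
            variances=self.variances,
            labels=ann.labels,
            ep_superior=ann.endplates["superior"],
            ep_inferior=ann.endplates["inferior"],
            fc_superior_left=ann.facets["superior_left"],
            fc_superior_right=ann.facets["superior_right"],
            fc_inferior_left=ann.facets["inferior_left"],
            fc_inferior_right=ann.facets["inferior_right"],
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModel":
        with np.load(path) as d:
            meta = json.loads(bytes(d["meta"]).decode())
            ann = GroundTruth(
                labels=d["labels"].copy(),
                landmarks={k: np.array(v) for k, v in meta["landmarks"].items()},
                endplates={"superior": d["ep_superior"].copy(), "inferior": d["ep_inferior"].copy()},
                facets={
                    k: d[f"fc_{k}"].copy()
                    for k in ("superior_left", "superior_right", "inferior_left", "inferior_right")
                },
                ligament_sites=meta["ligament_sites"],
            )
            return cls(
                d["mean_vertices"].copy(), d["faces"].copy(), d["modes"].copy(),
                d["variances"].copy(), ann,
            )


def build_shape_model(
    aligned: list[TriangleMesh],
    n_modes: int,
    annotations: GroundTruth,
) -> ShapeModel:
    """PCA shape model from Procrustes-aligned corresponded meshes."""
    n = len(aligned)
    if n < n_modes + 1:
        raise ValueError("need at least n_modes + 1 aligned shapes")
    X = np.stack([np.asarray(m.vertices).ravel() for m in aligned])  # (n, 3N)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((svals > 1e-9 * max(svals[0], 1.0)).sum())
    if n_modes > rank:
        raise ValueError(f"requested {n_modes} modes but data rank is {rank}")
    modes = Vt[:n_modes].T  # (3N, K)
    variances = (svals[:n_modes] ** 2) / (n - 1)
    mean_vertices = mean.reshape(-1, 3)
    ann = GroundTruth(
        labels=annotations.labels.copy(),
        landmarks={},  # recomputed on the mean below
        endplates={k: v.copy() for k, v in annotations.endplates.items()},
        facets={k: v.copy() for k, v in annotations.facets.items()},
        ligament_sites=dict(annotations.ligament_sites),
    )
    mean_mesh = new_mesh(mean_vertices, aligned[0].faces)
    from .parts import landmarks_from_parts

    ann.landmarks = landmarks_from_parts(mean_mesh, ann.labels)
    return ShapeModel(mean_vertices, np.asarray(aligned[0].faces), modes,
                      variances, ann)


# ---------------------------------------------------------------------------
# ICP


def icp_refine(
    moving: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> RigidTransform:
    """Iterative closest point rigid refinement (vertex correspondences).

    The closest-point RMSD is non-increasing across iterations (alternating
    minimization); stops when its decrease drops below ``tol``.
    """
    if len(moving.vertices) == 0 or len(target.vertices) == 0:
        raise ValueError("icp_refine requires non-empty meshes")
    T = init or RigidTransform.identity()
    src = np.asarray(moving.vertices, dtype=float)
    tree = cKDTree(np.asarray(target.vertices, dtype=float))
    prev = np.inf
    for _ in range(max_iter):
        cur = T.apply(src)
        dist, idx = tree.query(cur)
        rmsd = float(np.sqrt((dist**2).mean()))
        if prev - rmsd < tol:
            break
        prev = rmsd
        T = _kabsch(src, np.asarray(target.vertices)[idx])
    return T


# ---------------------------------------------------------------------------
# constrained non-rigid fit


@dataclass
class FitResult:
    """Result of fitting a ShapeModel to a target surface.

    ``coefficients`` are in per-mode standard deviations; ``fitted_mesh`` is
    the model instance posed in target space before normal projection,
    ``projected_mesh`` after.  ``msd``/``hd`` are vertex-sampled residual
    distances of the projected mesh against the target surface.
    """

    coefficients: np.ndarray
    transform: RigidTransform
    fitted_mesh: TriangleMesh
    projected_mesh: TriangleMesh
    msd: float
    hd: float
    converged: bool
    n_iterations: int
    model: ShapeModel = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Shape model fit",
            "=" * 46,
            f"modes used            : {len(self.coefficients)}",
            f"iterations            : {self.n_iterations}"
            + ("" if self.converged else "  (not converged)"),
            f"residual MSD [mm]     : {self.msd:.4f}",
            f"residual HD  [mm]     : {self.hd:.4f}",
            "coefficients [sd units]:",
        ]
        lines += [
            f"  b{k:<3d} {c:+8.3f}" for k, c in enumerate(self.coefficients)
        ]
        return "\n".join(lines)


def fit_model(
    model: ShapeModel,
    target: TriangleMesh,
    target_landmarks=None,
    regularization: float = 0.1,
    iterations: int = 30,
    landmark_weight: float = 1.0,
    coefficient_cap: float = 3.0,
    tol: float = 1e-6,
    do_projection: bool = True,
    surface_iterations: int = 10,
) -> FitResult:
    """Landmark-constrained non-rigid registration of the model to a target.

    Alternating scheme: rigid pose from current correspondences (closest
    target vertices), then regularized linear least squares for the mode
    coefficients with the four landmark correspondences as additional
    weighted rows and an L2 penalty ``regularization * sum(b^2)`` pulling
    toward the mean shape.  Coefficients are clipped to
    ``|b_k| <= coefficient_cap`` standard deviations.  Early iterations use
    fast closest-vertex correspondences with the landmark term active
    (coarse, landmark-constrained phase); the last ``surface_iterations``
    switch to closest-point-on-surface correspondences without the landmark
    rows (the derived landmarks are centroids-of-regions and carry a small
    definition bias, so the fine phase is purely surface-driven).  A final
    normal projection snaps the posed template onto the target surface.
    """
    tmpl_lm = model.template_landmarks()
    names = sorted(tmpl_lm)
    if target_landmarks is not None:
        missing = [k for k in names if k not in target_landmarks]
        if missing:
            raise ValueError(f"target landmark set incomplete: missing {missing}")
        tgt_lm = {k: np.asarray(target_landmarks[k], dtype=float) for k in names}
        T = rigid_from_landmarks(
            np.array([tmpl_lm[k] for k in names]),
            np.array([tgt_lm[k] for k in names]),
        )
    else:
        tgt_lm = None
        T = RigidTransform.identity()
    T = icp_refine(model.mean_mesh, target, init=T)

    tree = cKDTree(np.asarray(target.vertices, dtype=float))
    sds = model.stddevs
    cols = model.modes * sds  # (3N, K): mode columns in mm per sd unit
    K = model.n_modes
    b = np.zeros(K)
    mean_flat = model.mean_vertices.ravel()

    # landmark rows: template landmark points expressed at their nearest
    # template vertices (landmarks lie on the surface; nearest vertex is an
    # adequate linearization for the constraint rows)
    lm_vidx = None
    if tgt_lm is not None:
        vtree = cKDTree(model.mean_vertices)
        lm_vidx = vtree.query(np.array([tmpl_lm[k] for k in names]))[1]
        tgt_lm_arr = np.array([tgt_lm[k] for k in names])

    converged = False
    n_done = 0

    # -- coarse phase: alternating closest-vertex / landmark-constrained LLS
    prev_obj = np.inf
    for _ in range(iterations):
        n_done += 1
        shape = (mean_flat + cols @ b).reshape(-1, 3)
        posed = T.apply(shape)
        _, idx = tree.query(posed)
        corr = np.asarray(target.vertices)[idx]
        T = _kabsch(shape, corr)
        y = T.inverse().apply(corr).ravel() - mean_flat
        ATA = cols.T @ cols + regularization * np.eye(K)
        ATy = cols.T @ y
        if lm_vidx is not None and landmark_weight > 0:
            ylm = T.inverse().apply(tgt_lm_arr) - model.mean_vertices[lm_vidx]
            Alm = np.zeros((3 * len(lm_vidx), K))
            for k in range(3):
                Alm[k::3] = cols.reshape(-1, 3, K)[lm_vidx][:, k, :]
            ATA += landmark_weight * (Alm.T @ Alm)
            ATy += landmark_weight * (Alm.T @ ylm.reshape(-1))
        b = np.clip(np.linalg.solve(ATA, ATy), -coefficient_cap, coefficient_cap)
        obj = float(((posed - corr) ** 2).sum()) + regularization * float(b @ b)
        if abs(prev_obj - obj) < tol * max(1.0, prev_obj):
            break
        prev_obj = obj

    # -- fine phase: joint point-to-plane Gauss-Newton over pose and b
    from scipy.spatial.transform import Rotation as _Rot

    face_normals = np.asarray(target.face_normals)
    mode_fields = cols.reshape(-1, 3, K)  # per-vertex 3-vectors per mode
    for _ in range(surface_iterations):
        n_done += 1
        shape = (mean_flat + cols @ b).reshape(-1, 3)
        posed = T.apply(shape)
        cp, _, tid = closest_point_on_surface(posed, target, candidates=16)
        nrm = face_normals[tid]
        r = np.einsum("ij,ij->i", posed - cp, nrm)
        J = np.empty((len(r), 6 + K))
        J[:, 0:3] = np.cross(posed, nrm)  # d/d(rotation increment)
        J[:, 3:6] = nrm
        J[:, 6:] = np.einsum("ij,ijk->ik", nrm @ T.rotation, mode_fields)
        H = J.T @ J
        g = J.T @ r
        H[6:, 6:] += regularization * np.eye(K)
        g[6:] += regularization * b
        H += 1e-9 * np.trace(H) / (6 + K) * np.eye(6 + K)
        delta = -np.linalg.solve(H, g)
        Rinc = _Rot.from_rotvec(delta[0:3]).as_matrix()
        T = RigidTransform(Rinc @ T.rotation, Rinc @ T.translation + delta[3:6])
        b = np.clip(b + delta[6:], -coefficient_cap, coefficient_cap)
        if np.linalg.norm(delta) < 1e-6:
            converged = True
            break

    if not converged:
        import warnings

        warnings.warn("shape model fit did not converge; returning best result",
                      RuntimeWarning, stacklevel=2)
    fitted = new_mesh(T.apply((mean_flat + cols @ b).reshape(-1, 3)), model.faces)
    projected = project_normals(fitted, target) if do_projection else fitted
    dists = closest_point_on_surface(np.asarray(projected.vertices), target)[1]
    return FitResult(
        coefficients=b,
        transform=T,
        fitted_mesh=fitted,
        projected_mesh=projected,
        msd=float(dists.mean()),
        hd=float(dists.max()),
        converged=converged,
        n_iterations=n_done,
        model=model,
    )


def project_normals(
    fitted: TriangleMesh,
    target: TriangleMesh,
    gate: float = 2.0,
    max_distance: float | None = None,
    max_flipped_fraction: float = 0.0,
) -> TriangleMesh:
    """Move each fitted vertex to the nearest ray-surface hit along +/- normal.

    Vertices whose rays miss within ``max_distance`` stay put.  Vertices of
    triangles that would invert (flipped normals) beyond the allowed
    fraction are reverted, keeping the template topology valid.  Requires
    the fitted mesh to already be close to the target (vertex MSD below
    ``gate`` mm).
    """
    v = np.asarray(fitted.vertices, dtype=float)
    pre = closest_point_on_surface(v, target)[1]
    if float(pre.mean()) > gate:
        raise ValueError(
            f"fitted mesh too far from target (MSD {pre.mean():.3f} mm > gate "
            f"{gate} mm); refine the fit before projecting"
        )
    if max_distance is None:
        max_distance = 3.0 * gate
    normals = np.asarray(fitted.vertex_normals, dtype=float)
    t_fwd, hit_fwd = ray_surface_first_hit(v, normals, target, max_distance)
    t_bwd, hit_bwd = ray_surface_first_hit(v, -normals, target, max_distance)
    t_fwd = np.where(hit_fwd, t_fwd, np.inf)
    t_bwd = np.where(hit_bwd, t_bwd, np.inf)
    use_fwd = t_fwd <= t_bwd
    step = np.where(use_fwd, t_fwd, -t_bwd)
    step = np.where(np.isfinite(step), step, 0.0)
    out = v + normals * step[:, None]

    # revert vertices that invert faces
    faces = np.asarray(fitted.faces)
    ref_n = np.asarray(fitted.face_normals)
    for _ in range(10):
        tri = out[faces]
        cur_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        flipped = np.einsum("ij,ij->i", cur_n, ref_n) <= 0
        if flipped.mean() <= max_flipped_fraction:
            break
        out[np.unique(faces[flipped])] = v[np.unique(faces[flipped])]
    return new_mesh(out, faces)
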