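"""Statistical shape models: Procrustes, PCA, rigid alignment, ICP,
constrained fitting and normal projection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinefsu import mesh as M
from spinefsu import parts as P
from spinefsu import ssm
from spinefsu import synthetic as S


def _rand_rigid(rng, max_deg=180.0):
    R = Rotation.from_rotvec(
        rng.normal(size=3) / np.linalg.norm(rng.normal(size=3))
        * np.radians(rng.uniform(0, max_deg))
    ).as_matrix()
    return ssm.RigidTransform(R, rng.uniform(-20, 20, 3))


# ---------------------------------------------------------------------------
# rigid transforms


def test_rigid_transform_validation_and_composition(rng):
    T1 = _rand_rigid(rng)
    T2 = _rand_rigid(rng)
    pts = rng.normal(size=(10, 3)) * 10
    assert np.allclose(T1.compose(T2).apply(pts), T1.apply(T2.apply(pts)))
    assert np.allclose(T1.inverse().apply(T1.apply(pts)), pts, atol=1e-10)
    with pytest.raises(ValueError):
        ssm.RigidTransform(np.eye(3) * 2.0, np.zeros(3))
    with pytest.raises(ValueError):
        ssm.RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def test_rigid_from_landmarks_exact_recovery():
    src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    tgt = src @ R.T + [1, 2, 3]
    T = ssm.rigid_from_landmarks(src, tgt)
    assert np.abs(T.apply(src) - tgt).max() < 1e-9
    assert np.allclose(T.rotation, R)
    ident = ssm.rigid_from_landmarks(src, src)
    assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(ident.translation, 0.0, atol=1e-12)


def test_rigid_from_landmarks_noisy_matches_grid_oracle(rng):
    """On a 4-point toy with noise, the closed-form solution is at least as
    good as a brute-force search over a fine rotation grid."""
    src = np.array([[0, 0, 0], [10, 0, 0], [0, 8, 0], [2, 3, 9.0]])
    R = Rotation.from_euler("xyz", [10, -20, 30], degrees=True).as_matrix()
    tgt = src @ R.T + [4, 5, 6] + rng.normal(0, 0.5, (4, 3))
    T = ssm.rigid_from_landmarks(src, tgt)
    res = ((T.apply(src) - tgt) ** 2).sum()

    best = np.inf
    grid = np.arange(-180, 180, 20.0)
    for ax in grid:
        for ay in np.arange(-90, 91, 20.0):
            for az in grid:
                Rg = Rotation.from_euler("xyz", [ax, ay, az], degrees=True).as_matrix()
                moved = src @ Rg.T
                t = (tgt - moved).mean(axis=0)
                best = min(best, ((moved + t - tgt) ** 2).sum())
    assert res <= best + 1e-9


def test_rigid_from_landmarks_degenerate_raises():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        ssm.rigid_from_landmarks(line, line + 1.0)


# ---------------------------------------------------------------------------
# generalized Procrustes + PCA


def test_procrustes_aligns_rigid_copies(default_vertebra, rng):
    m, _ = default_vertebra
    v = np.asarray(m.vertices)
    meshes = [M.new_mesh(_rand_rigid(rng, 40).apply(v), m.faces) for _ in range(4)]
    aligned, mean = ssm.generalized_procrustes(meshes)
    ref = np.asarray(aligned[0].vertices)
    for a in aligned[1:]:
        assert np.abs(np.asarray(a.vertices) - ref).max() < 1e-6
    assert np.abs(np.asarray(mean.vertices) - ref).max() < 1e-6


def test_procrustes_already_aligned_is_identity_like(population):
    samples, _, _ = population
    meshes = [s[0] for s in samples[:6]]
    centered = [
        M.new_mesh(np.asarray(m.vertices) - np.asarray(m.vertices).mean(0), m.faces)
        for m in meshes
    ]
    aligned, _ = ssm.generalized_procrustes(centered)
    for orig, al in zip(centered, aligned):
        # alignment of an already centered, common-frame set barely moves them
        assert np.abs(np.asarray(al.vertices) - np.asarray(orig.vertices)).max() < 1.0


def test_procrustes_two_shape_alignment_beats_grid_search(rng):
    """5-vertex toy: GPA residual <= best rigid alignment on a rotation grid."""
    base = rng.normal(size=(5, 3)) * 10
    faces = np.array([[0, 1, 2], [1, 2, 3], [2, 3, 4], [0, 2, 4], [0, 1, 4],
                      [1, 3, 4], [0, 3, 4], [0, 1, 3]])
    other = base + rng.normal(0, 0.5, (5, 3))
    Rr = Rotation.from_euler("xyz", [25, 10, -40], degrees=True).as_matrix()
    m1 = M.new_mesh(base, faces)
    m2 = M.new_mesh(other @ Rr.T + [5, 1, -2], faces)
    aligned, _ = ssm.generalized_procrustes([m1, m2])
    rmsd = np.sqrt(((np.asarray(aligned[0].vertices)
                     - np.asarray(aligned[1].vertices)) ** 2).mean())
    best = np.inf
    for ax in np.arange(-180, 180, 15.0):
        for ay in np.arange(-90, 91, 15.0):
            for az in np.arange(-180, 180, 15.0):
                Rg = Rotation.from_euler("xyz", [ax, ay, az], degrees=True).as_matrix()
                moved = np.asarray(m2.vertices) @ Rg.T
                moved = moved - moved.mean(0) + base.mean(0)
                best = min(best, np.sqrt(((moved - base) ** 2).mean()))
    assert rmsd <= best + 1e-9


def test_pca_recovers_true_subspace(population, shape_model):
    _, _, true_modes = population
    Q1 = np.linalg.qr(true_modes)[0]
    Q2 = np.linalg.qr(shape_model.modes)[0]
    sv = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(sv, -1, 1)))
    assert angles.max() < 5.0
    assert np.all(np.diff(shape_model.variances) <= 1e-12)


def test_k_zero_model_is_mean_only(population):
    samples, _, _ = population
    aligned, _ = ssm.generalized_procrustes([s[0] for s in samples[:5]])
    model = ssm.build_shape_model(aligned, 0, samples[0][1])
    inst = model.shape_at(np.zeros(0))
    assert np.allclose(inst.vertices, model.mean_vertices)


def test_build_model_rejects_excess_modes(population):
    samples, _, _ = population
    aligned, _ = ssm.generalized_procrustes([s[0] for s in samples[:4]])
    with pytest.raises(ValueError):
        ssm.build_shape_model(aligned, 10, samples[0][1])


def test_shape_model_serialization_roundtrip(shape_model, tmp_path):
    shape_model.save(tmp_path / "model.npz")
    back = ssm.ShapeModel.load(tmp_path / "model.npz")
    assert np.allclose(back.mean_vertices, shape_model.mean_vertices)
    assert np.allclose(back.modes, shape_model.modes)
    assert np.allclose(back.variances, shape_model.variances)
    assert set(back.annotations.ligament_sites) == set(
        shape_model.annotations.ligament_sites
    )


# ---------------------------------------------------------------------------
# ICP


def test_icp_recovers_small_perturbation(default_vertebra):
    m, _ = default_vertebra
    R = Rotation.from_euler("y", 5, degrees=True).as_matrix()
    target = M.new_mesh(np.asarray(m.vertices) @ R.T + [2, 0, 1], m.faces)
    T = ssm.icp_refine(m, target)
    moved = M.new_mesh(T.apply(np.asarray(m.vertices)), m.faces)
    msd, _ = M.surface_metrics(moved, target)
    assert msd < 0.1


def test_icp_rmsd_monotone_and_idempotent(default_vertebra):
    m, _ = default_vertebra
    R = Rotation.from_euler("x", 4, degrees=True).as_matrix()
    target = M.new_mesh(np.asarray(m.vertices) @ R.T + [1, 2, 0], m.faces)
    from scipy.spatial import cKDTree

    tree = cKDTree(np.asarray(target.vertices))
    T = ssm.RigidTransform.identity()
    prev = np.inf
    src = np.asarray(m.vertices)
    for _ in range(10):
        T = ssm.icp_refine(m, target, init=T, max_iter=1)
        rmsd = float(np.sqrt((tree.query(T.apply(src))[0] ** 2).mean()))
        assert rmsd <= prev + 1e-9
        prev = rmsd
    # starting from the converged transform changes almost nothing
    T2 = ssm.icp_refine(m, target, init=T, max_iter=5)
    assert np.abs(T2.rotation - T.rotation).max() < 1e-6


# ---------------------------------------------------------------------------
# fitting and projection


def test_fit_recovers_known_coefficients(shape_model, rng):
    for _ in range(3):
        b_true = rng.uniform(-2, 2, 3)
        inst = shape_model.shape_at(b_true)
        T = _rand_rigid(rng, 12.0)
        target = M.new_mesh(T.apply(np.asarray(inst.vertices)), inst.faces)
        lms = P.landmarks_from_parts(target, shape_model.annotations.labels)
        res = shape_model.fit(target, lms, regularization=0.01)
        assert np.abs(res.coefficients - b_true).max() < 0.1
        assert len(res.fitted_mesh.vertices) == len(shape_model.mean_vertices)
        assert "coefficients" in res.summary()


def test_fit_strong_regularization_returns_mean(shape_model, rng):
    inst = shape_model.shape_at(np.array([1.5, -1.0, 0.5]))
    res = ssm.fit_model(shape_model, inst, None, regularization=1e12,
                        iterations=10, surface_iterations=3, do_projection=False)
    assert np.abs(res.coefficients).max() < 1e-3


def test_fit_beats_rigid_only_alignment(shape_model, rng):
    b_true = np.array([1.6, -1.2, 0.8])
    inst = shape_model.shape_at(b_true)
    target = M.new_mesh(np.asarray(inst.vertices) + [3.0, 1.0, -2.0], inst.faces)
    T = ssm.icp_refine(shape_model.mean_mesh, target)
    rigid_only = M.new_mesh(T.apply(shape_model.mean_vertices), shape_model.faces)
    msd_rigid, _ = M.surface_metrics(rigid_only, target)
    res = shape_model.fit(target, None, regularization=0.01, do_projection=False)
    msd_fit, _ = M.surface_metrics(res.fitted_mesh, target)
    assert msd_fit <= msd_rigid


def test_fit_incomplete_landmarks_raise(shape_model):
    target = shape_model.mean_mesh
    with pytest.raises(ValueError, match="incomplete"):
        shape_model.fit(target, {"vertebral_body": np.zeros(3)})


def test_project_normals_identity_and_radial():
    s = M.icosphere(3)
    inner = M.new_mesh(np.asarray(s.vertices) * 10.0, s.faces)
    same = ssm.project_normals(inner, inner)
    assert np.abs(np.asarray(same.vertices) - np.asarray(inner.vertices)).max() < 1e-9
    outer = M.new_mesh(np.asarray(s.vertices) * 11.0, s.faces)
    proj = ssm.project_normals(inner, outer)
    moved = np.linalg.norm(np.asarray(proj.vertices), axis=1)
    assert np.allclose(moved, 11.0, atol=0.15)


def test_project_normals_gate(default_vertebra):
    m, _ = default_vertebra
    far = M.new_mesh(np.asarray(m.vertices) + [30, 0, 0], m.faces)
    with pytest.raises(ValueError, match="gate|MSD"):
        ssm.project_normals(far, m)


def test_projection_reduces_msd(shape_model, rng):
    b = rng.uniform(-1.5, 1.5, 3)
    target = shape_model.shape_at(b)
    res = ssm.fit_model(shape_model, target, None, regularization=0.3,
                        iterations=10, surface_iterations=2)
    pre = M.closest_point_on_surface(
        np.asarray(res.fitted_mesh.vertices), target)[1].mean()
    post = M.closest_point_on_surface(
        np.asarray(res.projected_mesh.vertices), target)[1].mean()
    assert post <= pre + 1e-9


def test_rigid_equivariance_of_alignment_chain(default_vertebra, rng):
    m, gt = default_vertebra
    target = M.new_mesh(np.asarray(m.vertices) @ Rotation.from_euler(
        "z", 7, degrees=True).as_matrix().T + [1, 0, 2], m.faces)
    T0 = ssm.icp_refine(m, target)
    G = _rand_rigid(rng, 90.0)
    m_g = M.new_mesh(G.apply(np.asarray(m.vertices)), m.faces)
    t_g = M.new_mesh(G.apply(np.asarray(target.vertices)), target.faces)
    T1 = ssm.icp_refine(m_g, t_g)
    # equivariance: T1 = G o T0 o G^-1
    expected = G.compose(T0).compose(G.inverse())
    assert np.abs(T1.rotation - expected.rotation).max() < 1e-4
    assert np.abs(T1.translation - expected.translation).max() < 1e-3
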