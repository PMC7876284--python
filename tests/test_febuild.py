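"""FE model assembly: materials, annotation transfer, facet clearance, bone
tetrahedralization, disc hex meshing, ligaments, validation, FEBio I/O."""

import numpy as np
import pytest

from spinefsu import febuild as F
from spinefsu import mesh as M
from spinefsu import synthetic as S
from spinefsu.materials import materials_for_grade


# ---------------------------------------------------------------------------
# materials


def test_healthy_material_set_values():
    m = materials_for_grade("healthy")
    assert (m.cortical.E1, m.cortical.E2, m.cortical.E3) == (8000.0, 8000.0, 12000.0)
    assert (m.cortical.nu12, m.cortical.nu23, m.cortical.nu31) == (0.4, 0.3, 0.35)
    assert (m.trabecular.E, m.trabecular.nu) == (100.0, 0.2)
    assert (m.endplate.E, m.endplate.nu) == (1000.0, 0.3)
    assert (m.nucleus.E, m.nucleus.nu) == (1.0, 0.49)
    assert (m.annulus.E, m.annulus.nu, m.annulus.beta) == (1.0, 0.4, 3.4)
    assert (m.fiber.alpha, m.fiber.beta, m.fiber.xi) == (65.0, 2.0, 0.296)
    assert (m.facet_cartilage.E, m.facet_cartilage.nu) == (30.0, 0.4)


def test_degenerated_material_corrections():
    g4 = materials_for_grade(4)
    assert (g4.nucleus.E, g4.nucleus.nu) == (1.4, 0.42)
    assert g4.annulus.E == 4.5
    g5 = materials_for_grade(5)
    assert (g5.nucleus.E, g5.nucleus.nu) == (2.2, 0.32)
    assert g5.annulus.E == 5.5
    # everything else stays at the healthy values
    h = materials_for_grade("healthy")
    for g in (g4, g5):
        assert g.annulus.beta == h.annulus.beta == 3.4
        assert g.fiber == h.fiber
        assert g.cortical == h.cortical
        assert g.facet_cartilage == h.facet_cartilage
    # stiffening is monotone with degeneration grade
    assert h.nucleus.E < g4.nucleus.E < g5.nucleus.E
    assert h.annulus.E < g4.annulus.E < g5.annulus.E


@pytest.mark.parametrize("bad", [1, 2, 3, "PG2", 6])
def test_unsupported_grades_raise(bad):
    with pytest.raises(ValueError, match="grade"):
        materials_for_grade(bad)


# ---------------------------------------------------------------------------
# annotation transfer


def test_transfer_annotations_identity_and_scaling(shape_model):
    mean = shape_model.mean_mesh
    ann = F.transfer_template_annotations(shape_model, mean)
    assert np.array_equal(ann.labels, shape_model.annotations.labels)
    for k in ann.endplates:
        assert np.array_equal(ann.endplates[k], shape_model.annotations.endplates[k])
    scaled = M.new_mesh(np.asarray(mean.vertices) * 1.5, mean.faces)
    ann_s = F.transfer_template_annotations(shape_model, scaled)
    pf = M.patch_faces(mean, ann.endplates["superior"])
    pf_s = M.patch_faces(scaled, ann_s.endplates["superior"])
    area = M.new_mesh(mean.vertices, pf).area
    area_s = M.new_mesh(scaled.vertices, pf_s).area
    assert area_s == pytest.approx(area * 1.5**2, rel=1e-6)


def test_transfer_annotations_rejects_foreign_topology(shape_model):
    other = M.icosphere(2)
    with pytest.raises(ValueError, match="topology"):
        F.transfer_template_annotations(shape_model, other)


def test_transfer_endplates_overlap_generator_truth(shape_model, default_fsu):
    fsu = default_fsu
    fit = shape_model.fit(fsu.lower_mesh, None, regularization=0.05)
    ann = F.transfer_template_annotations(shape_model, fit.projected_mesh)
    # vertex-set Dice against the generator's endplate patch
    a = set(map(int, ann.endplates["superior"]))
    b = set(map(int, fsu.lower_gt.endplates["superior"]))
    dice = 2 * len(a & b) / (len(a) + len(b))
    assert dice >= 0.8


# ---------------------------------------------------------------------------
# facet clearance


def test_enforce_facet_gap_noop_when_clear(default_fsu):
    fsu = default_fsu
    up, lo = F.enforce_facet_gap(
        fsu.upper_mesh, fsu.lower_mesh, fsu.upper_gt, fsu.lower_gt, min_gap=0.25
    )
    assert np.array_equal(np.asarray(up.vertices), np.asarray(fsu.upper_mesh.vertices))


def test_enforce_facet_gap_fixes_constructed_penetration(default_fsu):
    fsu = default_fsu
    # push the upper facet patches toward the lower ones until the signed
    # clearance is violated (~ -0.3 mm penetration)
    def side_clearance(mesh_u, side):
        return M.signed_region_clearance(
            mesh_u, fsu.upper_gt.facets[f"inferior_{side}"],
            fsu.lower_mesh, fsu.lower_gt.facets[f"superior_{side}"],
        )

    pushed = fsu.upper_mesh
    for _ in range(10):
        clearances = {s: side_clearance(pushed, s) for s in ("left", "right")}
        if max(clearances.values()) < -0.25:
            break
        uv = np.asarray(pushed.vertices).copy()
        for side in ("left", "right"):
            if clearances[side] < -0.25:
                continue  # this side is already penetrating enough
            idx = fsu.upper_gt.facets[f"inferior_{side}"]
            lo_pts = np.asarray(fsu.lower_mesh.vertices)[
                fsu.lower_gt.facets[f"superior_{side}"]
            ]
            d = uv[idx].mean(axis=0) - lo_pts.mean(axis=0)
            uv[idx] -= 0.5 * d / np.linalg.norm(d)
        pushed = M.new_mesh(uv, fsu.upper_mesh.faces)
    uv = np.asarray(pushed.vertices)
    pre = {s: side_clearance(pushed, s) for s in ("left", "right")}
    assert max(pre.values()) < 0.0  # constructed violation on both sides
    up, _ = F.enforce_facet_gap(pushed, fsu.lower_mesh, fsu.upper_gt,
                                fsu.lower_gt, min_gap=0.25)
    for side in ("left", "right"):
        c = side_clearance(up, side)
        # restored to at least the requested gap (within half a percent);
        # iterative correction of a deep lateral penetration can overshoot
        # by up to roughly the penetration itself
        assert 0.2487 <= c <= 2.0 * (-pre[side]) + 0.25 + 0.5
    # locality: non-facet vertices untouched
    facet_all = np.union1d(fsu.upper_gt.facets["inferior_left"],
                           fsu.upper_gt.facets["inferior_right"])
    mask = np.ones(len(uv), dtype=bool)
    mask[facet_all] = False
    assert np.array_equal(np.asarray(up.vertices)[mask], uv[mask])


# ---------------------------------------------------------------------------
# bone tetrahedralization


def test_tet_sphere_shell_fraction_and_volume():
    s = M.icosphere(3)
    sphere = M.new_mesh(np.asarray(s.vertices) * 10.0, s.faces)
    bone = F.tetrahedralize_with_shell(sphere, shell_thickness=1.0, voxel_pitch=0.8)
    vols = bone.tet_volumes()
    assert (vols > 0).all()
    total = vols.sum()
    analytic = 4.0 / 3.0 * np.pi * 1000.0
    assert abs(total - analytic) / analytic < 0.02
    frac = vols[bone.is_cortical].sum() / total
    shell_frac = 1.0 - (9.0 / 10.0) ** 3  # 0.271
    assert abs(frac - shell_frac) / shell_frac < 0.2


def test_tet_thick_shell_all_cortical():
    s = M.icosphere(2)
    sphere = M.new_mesh(np.asarray(s.vertices) * 6.0, s.faces)
    bone = F.tetrahedralize_with_shell(sphere, shell_thickness=10.0, voxel_pitch=1.0)
    assert bone.is_cortical.all()


def test_tet_rejects_open_surface_and_coarse_pitch():
    open_mesh = M.new_mesh([[0, 0, 0], [5, 0, 0], [0, 5, 0]], [[0, 1, 2]])
    with pytest.raises(ValueError):
        F.tetrahedralize_with_shell(open_mesh)
    s = M.icosphere(1)
    tiny = M.new_mesh(np.asarray(s.vertices) * 1.0, s.faces)
    with pytest.raises(ValueError):
        F.tetrahedralize_with_shell(tiny, voxel_pitch=10.0)


# ---------------------------------------------------------------------------
# disc meshing


def _plate_pair(size=30.0, gap=10.0, thickness=4.0):
    import trimesh

    def plate(zc):
        b = trimesh.creation.box(extents=[size, size, thickness])
        return M.new_mesh(np.asarray(b.vertices) + [0, 0, zc], np.asarray(b.faces))

    lower = plate(-thickness / 2)  # top face at z = 0
    upper = plate(gap + thickness / 2)  # bottom face at z = gap
    lo_idx = np.where(np.asarray(lower.vertices)[:, 2] > -1e-9)[0]
    up_idx = np.where(np.asarray(upper.vertices)[:, 2] < gap + 1e-9)[0]
    return lower, lo_idx, upper, up_idx


def test_disc_mesh_parallel_plates_right_prisms():
    lower, lo_idx, upper, up_idx = _plate_pair(gap=10.0)
    disc = F.build_disc_mesh(lower, lo_idx, upper, up_idx, n_side=4, n_axial=2)
    assert disc.height == pytest.approx(10.0, abs=1e-6)
    z = disc.nodes[:, 2]
    assert z.min() == pytest.approx(0.0, abs=1e-9)
    assert z.max() == pytest.approx(10.0, abs=1e-9)
    assert (disc.corner_jacobians() > 0).all()
    # tied contact: boundary nodes on the endplate surfaces
    dlo = M.closest_point_on_surface(disc.nodes[disc.bottom_nodes], lower)[1]
    dup = M.closest_point_on_surface(disc.nodes[disc.top_nodes], upper)[1]
    assert dlo.max() < 1e-6 and dup.max() < 1e-6


def test_disc_nucleus_fraction_and_fibers():
    lower, lo_idx, upper, up_idx = _plate_pair()
    disc = F.build_disc_mesh(lower, lo_idx, upper, up_idx, n_side=6, n_axial=3,
                             nucleus_fraction=0.4)
    vols = disc.hex_volumes()
    frac = vols[disc.nucleus_elements].sum() / vols.sum()
    assert 0.3 <= frac <= 0.5
    fib = disc.fiber_directions[disc.annulus_elements]
    norms = np.linalg.norm(fib, axis=2)
    assert np.allclose(norms, 1.0, atol=1e-9)
    # the two families are mirror images about the transverse plane
    assert np.allclose(fib[:, 0, 2], -fib[:, 1, 2], atol=1e-12)
    assert np.allclose(fib[:, 0, :2], fib[:, 1, :2], atol=1e-12)
    theta = np.degrees(np.arcsin(np.abs(fib[:, 0, 2])))
    assert np.allclose(theta, 30.0, atol=1e-6)


def test_disc_rejects_non_opposing_endplates():
    lower, lo_idx, upper, up_idx = _plate_pair()
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("x", 80, degrees=True).as_matrix()
    tilted = M.new_mesh(np.asarray(upper.vertices) @ R.T + [0, 0, 30], upper.faces)
    with pytest.raises(ValueError, match="opposing|footprint|cross"):
        F.build_disc_mesh(lower, lo_idx, tilted, up_idx)


def test_disc_height_matches_endplate_distance(fe_model, default_fsu):
    fsu = default_fsu
    lo = np.asarray(fe_model.lower_surface.vertices)[
        fe_model.lower_ann.endplates["superior"]
    ]
    up = np.asarray(fe_model.upper_surface.vertices)[
        fe_model.upper_ann.endplates["inferior"]
    ]
    d2 = ((lo[:, None, :] - up[None, :, :]) ** 2).sum(axis=2)
    mean_dist = np.sqrt(d2.min(axis=1)).mean()
    assert abs(fe_model.disc.height - mean_dist) / mean_dist < 0.1


# ---------------------------------------------------------------------------
# ligaments


def test_ligaments_complete_and_rest_lengths(default_fsu):
    fsu = default_fsu
    ligs = F.attach_ligaments(fsu.upper_mesh, fsu.upper_gt,
                              fsu.lower_mesh, fsu.lower_gt)
    assert len(ligs) == 7
    assert {l.name for l in ligs} == set(S.LIGAMENT_SITES)
    for l in ligs:
        assert l.rest_length == pytest.approx(
            np.linalg.norm(l.upper_point - l.lower_point), abs=1e-9
        )
    by_name = {l.name: l for l in ligs}
    assert by_name["ITL_left"].rest_length == pytest.approx(
        by_name["ITL_right"].rest_length, abs=1e-9
    )


def test_ligaments_missing_site_raises(default_fsu):
    fsu = default_fsu
    gt = fsu.upper_gt
    broken = S.GroundTruth(
        labels=gt.labels, landmarks=gt.landmarks, endplates=gt.endplates,
        facets=gt.facets,
        ligament_sites={k: v for k, v in gt.ligament_sites.items() if k != "PLL"},
    )
    with pytest.raises(ValueError, match="PLL"):
        F.attach_ligaments(fsu.upper_mesh, broken, fsu.lower_mesh, fsu.lower_gt)


# ---------------------------------------------------------------------------
# full assembly + FEBio


def test_assembled_model_validates(fe_model):
    fe_model.validate()  # raises on any violated invariant
    assert len(fe_model.facet_pairs) == 2
    assert fe_model.materials.grade == "healthy"


def test_assemble_grade5_materials(default_fsu):
    fsu = default_fsu
    model = F.assemble_fsu_model(
        fsu.upper_mesh, fsu.lower_mesh, fsu.upper_gt, fsu.lower_gt, grade=5,
        config=F.FEConfig(build_bone_volumes=False),
    )
    assert model.materials == materials_for_grade(5)


def test_febio_roundtrip_and_contents(fe_model, tmp_path):
    path = tmp_path / "model.feb"
    F.write_febio(fe_model, path)
    data = F.read_febio(path)
    assert data["version"] == "2.5"
    # node ids 1-based contiguous, coordinates lossless
    assert data["node_ids"][0] == 1
    assert np.array_equal(data["node_ids"], np.arange(1, len(data["nodes"]) + 1))
    n_surf = len(fe_model.lower_surface.vertices)
    assert np.abs(data["nodes"][:n_surf]
                  - np.asarray(fe_model.lower_surface.vertices)).max() < 1e-9
    # element ids 1-based contiguous across blocks
    all_ids = np.sort(np.concatenate([b["ids"] for b in data["elements"].values()]))
    assert np.array_equal(all_ids, np.arange(1, len(all_ids) + 1))
    # annulus material carries the Holmes-Mow beta and fiber xi as printed
    annulus = data["materials"][5]
    solids = {s["type"]: s for s in annulus["solids"]}
    assert solids["Holmes-Mow"]["beta"] == 3.4
    assert solids["fiber-exp-pow"]["ksi"] == 0.296
    assert solids["fiber-exp-pow"]["alpha"] == 65.0
    # the ramped moment is written in N mm
    total = np.linalg.norm([ld["value"] for ld in data["rigid_loads"]])
    assert total == pytest.approx(7500.0)
    assert data["fixed_node_set"] == "fixed_inferior_endplate"
    assert len(data["ligaments"]) == 7
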