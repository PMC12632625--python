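"""Structure I/O, plane/centroid primitives and pose descriptors."""

import math

import numpy as np
import pytest

from hostguest import (
    AtomSite,
    GuestSpec,
    StructureModel,
    centroid,
    fit_plane,
    gen_toy_complex,
    hbond_geometry,
    plane_plane_angle,
    point_plane_distance,
    pose_descriptors,
    read_structure,
    vertex_angle,
    write_structure,
)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestStructureIO:
    def test_orthorhombic_fractional_to_cartesian(self, tmp_path):
        cif = tmp_path / "ortho.cif"
        cif.write_text(
            "data_test\n"
            "_cell_length_a 10.0\n_cell_length_b 20.0\n_cell_length_c 30.0\n"
            "_cell_angle_alpha 90.0\n_cell_angle_beta 90.0\n_cell_angle_gamma 90.0\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "_atom_site_occupancy\n"
            "C1 C 0.5 0.5 0.5 1.0\n"
        )
        model = read_structure(cif, "cif_min")
        assert np.allclose(model.atoms[0].pos, [5.0, 10.0, 15.0], atol=1e-9)

    def test_monoclinic_against_hand_matrix(self, tmp_path):
        a, b, c, beta = 8.0, 11.0, 9.5, 104.0
        frac = np.array([0.21, 0.37, 0.65])
        cif = tmp_path / "mono.cif"
        cif.write_text(
            "data_test\n"
            f"_cell_length_a {a}\n_cell_length_b {b}\n_cell_length_c {c}\n"
            f"_cell_angle_alpha 90.0\n_cell_angle_beta {beta}\n_cell_angle_gamma 90.0\n"
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "_atom_site_occupancy\n"
            f"N1 N {frac[0]} {frac[1]} {frac[2]} 1.0\n"
        )
        model = read_structure(cif, "cif_min")
        # independent oracle: the standard crystallographic matrix for a
        # monoclinic cell (unique axis b)
        cb = math.cos(math.radians(beta))
        m = np.array(
            [[a, 0.0, c * cb],
             [0.0, b, 0.0],
             [0.0, 0.0, c * math.sin(math.radians(beta))]]
        )
        assert np.allclose(model.atoms[0].pos, m @ frac, atol=1e-9)

    def test_labeled_xyz_round_trip(self, tmp_path):
        toy = gen_toy_complex(seed=3)
        path = tmp_path / "toy.xyz"
        write_structure(toy.structure, path, "labeled_xyz")
        back = read_structure(path, "labeled_xyz")
        assert len(back.atoms) == len(toy.structure.atoms)
        for a, b in zip(toy.structure.atoms, back.atoms):
            assert a.label == b.label and a.disorder_group == b.disorder_group
            assert np.array_equal(a.pos, b.pos)
            assert a.occupancy == b.occupancy

    def test_cif_round_trip_preserves_geometry(self, tmp_path):
        toy = gen_toy_complex(seed=3)
        path = tmp_path / "toy.cif"
        write_structure(toy.structure, path, "cif_min")
        back = read_structure(path, "cif_min")
        for a, b in zip(toy.structure.atoms, back.atoms):
            # the writer shifts into a padded box: compare internal distances
            pass
        d_orig = np.linalg.norm(
            toy.structure.atoms[0].pos - toy.structure.atoms[5].pos
        )
        d_back = np.linalg.norm(back.atoms[0].pos - back.atoms[5].pos)
        assert d_back == pytest.approx(d_orig, abs=1e-6)

    def test_malformed_xyz_reports_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nC1 C 0.0 0.0 0.0 1.0 0\nC2 C 1.0\n")
        with pytest.raises(ValueError, match="line 4"):
            read_structure(path, "labeled_xyz")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_structure(tmp_path / "x", "pdb")

    def test_duplicate_label_in_group_rejected(self):
        with pytest.raises(ValueError):
            StructureModel(
                atoms=[
                    AtomSite("C1", "C", np.zeros(3)),
                    AtomSite("C1", "C", np.ones(3)),
                ]
            )


class TestPrimitives:
    def test_centroid_of_square_and_single_point(self):
        square = [np.array(p) for p in
                  [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]]
        assert np.allclose(centroid(square), [0.5, 0.5, 0.0])
        assert np.allclose(centroid([np.array([1.0, 2.0, 3.0])]), [1.0, 2.0, 3.0])

    def test_centroid_of_symmetric_ring(self):
        c = np.array([2.0, -1.0, 4.0])
        pts = [c + 3.0 * np.array([math.cos(t), math.sin(t), 0.0])
               for t in np.linspace(0, 2 * math.pi, 8)[:-1]]
        assert np.allclose(centroid(pts), c, atol=1e-12)

    def test_centroid_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            centroid([])

    def test_plane_through_coplanar_points(self):
        pts = [np.array(p) for p in
               [(0, 0, 1), (2, 0, 1), (0, 3, 1), (5, 5, 1)]]
        plane = fit_plane(pts)
        assert plane.rms == pytest.approx(0.0, abs=1e-12)
        assert abs(plane.normal @ np.array([0, 0, 1.0])) == pytest.approx(1.0)

    def test_plane_of_alternating_displacements(self):
        h = 0.3
        base = [np.array(p, float) for p in
                [(1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0)]]
        pts = [p + np.array([0, 0, h if i % 2 == 0 else -h])
               for i, p in enumerate(base)]
        plane = fit_plane(pts)
        assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)
        assert plane.rms == pytest.approx(h, abs=1e-12)

    def test_collinear_selection_rejected(self):
        pts = [np.array([t, 2 * t, -t]) for t in (0.0, 1.0, 2.0, 3.5)]
        with pytest.raises(ValueError):
            fit_plane(pts)

    def test_plane_matches_brute_force_orientation_grid(self):
        # independent oracle: scan plane normals on a refining spherical
        # grid; for each normal the best offset passes through the centroid
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(10, 3)) * np.array([3.0, 2.0, 0.4])
        centered = pts - pts.mean(axis=0)

        def rms_for(theta, phi):
            n = np.array([
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta),
            ])
            return math.sqrt(np.mean((centered @ n) ** 2))

        t_lo, t_hi, p_lo, p_hi = 0.0, math.pi, 0.0, 2 * math.pi
        best = (0.0, 0.0)
        for _ in range(6):  # coarse-to-fine refinement
            thetas = np.linspace(t_lo, t_hi, 60)
            phis = np.linspace(p_lo, p_hi, 120)
            vals = [(rms_for(t, p), (t, p)) for t in thetas for p in phis]
            _, best = min(vals)
            dt, dp = (t_hi - t_lo) / 10, (p_hi - p_lo) / 10
            t_lo, t_hi = best[0] - dt, best[0] + dt
            p_lo, p_hi = best[1] - dp, best[1] + dp
        brute = rms_for(*best)
        assert fit_plane(pts).rms == pytest.approx(brute, abs=1e-6)

    def test_point_plane_distance_signed_and_unsigned(self):
        pts = [np.array(p, float) for p in [(1, 0, 0), (0, 1, 0), (-1, -1, 0)]]
        plane = fit_plane(pts, orient_toward=np.array([0, 0, 5.0]))
        assert point_plane_distance(np.array([0.3, -0.2, 0.0]), plane) == pytest.approx(0.0, abs=1e-12)
        assert point_plane_distance(np.array([0, 0, 0.74]), plane) == pytest.approx(0.74)
        assert point_plane_distance(np.array([0, 0, -0.5]), plane, signed=True) == pytest.approx(-0.5)

    def test_vertex_angles(self):
        a, b, c = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])
        assert vertex_angle(a, b, c) == pytest.approx(90.0)
        assert vertex_angle(a, b, -a) == pytest.approx(180.0)
        with pytest.raises(ValueError):
            vertex_angle(a, a, c)

    def test_plane_plane_angles(self):
        xy = fit_plane([np.array(p, float) for p in [(1, 0, 0), (0, 1, 0), (-1, -1, 0)]])
        xy2 = fit_plane([np.array(p, float) for p in [(1, 0, 3), (0, 1, 3), (-1, -1, 3)]])
        xz = fit_plane([np.array(p, float) for p in [(1, 0, 0), (0, 0, 1), (-1, 0, -1)]])
        assert plane_plane_angle(xy, xy2) == pytest.approx(0.0, abs=1e-9)
        assert plane_plane_angle(xy, xz) == pytest.approx(90.0)


class TestPoseDescriptors:
    def test_toy_round_trip_closes(self):
        specs = [GuestSpec(0.74, 20.68, 78.66, 1.49), GuestSpec(1.36, 1.00, 78.66, 1.49)]
        toy = gen_toy_complex(guest_spec=specs, occupancies=(0.6, 0.4), seed=9)
        recs = pose_descriptors(toy.structure, toy.selections)
        assert [r.disorder_group for r in recs] == [1, 2]
        for rec, truth in zip(recs, toy.truth):
            assert rec.occupancy == truth.occupancy
            assert rec.d_n_plane1 == pytest.approx(truth.d_n_plane1, abs=1e-6)
            assert rec.angle_cen1_cen2_n == pytest.approx(truth.angle_cen1_cen2_n, abs=1e-6)
            assert rec.angle_phenyl_plane2 == pytest.approx(truth.angle_phenyl_plane2, abs=1e-6)
            assert rec.d_cen1prime_halogen == pytest.approx(truth.d_cen1prime_halogen, abs=1e-6)

    def test_canonical_pose_in_plane_on_axis(self):
        toy = gen_toy_complex(guest_spec=[GuestSpec(0.0, 0.0, 83.13)], seed=0)
        (rec,) = pose_descriptors(toy.structure, toy.selections)
        assert rec.d_n_plane1 == pytest.approx(0.0, abs=1e-9)
        assert rec.angle_cen1_cen2_n == pytest.approx(0.0, abs=1e-9)
        assert rec.angle_phenyl_plane2 == pytest.approx(83.13, abs=1e-9)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(17)
        toy = gen_toy_complex(
            guest_spec=[GuestSpec(0.19, 16.97, 83.13)], seed=2
        )
        base = pose_descriptors(toy.structure, toy.selections)[0]
        for _ in range(5):
            moved = toy.structure.transformed(
                random_rotation(rng), rng.normal(scale=20.0, size=3)
            )
            rec = pose_descriptors(moved, toy.selections)[0]
            assert rec.d_n_plane1 == pytest.approx(base.d_n_plane1, abs=1e-9)
            assert rec.angle_cen1_cen2_n == pytest.approx(base.angle_cen1_cen2_n, abs=1e-9)
            assert rec.angle_phenyl_plane2 == pytest.approx(base.angle_phenyl_plane2, abs=1e-9)

    def test_unresolvable_label_named(self):
        toy = gen_toy_complex(seed=0)
        bad = toy.selections.__class__(
            portal_o=toy.selections.portal_o,
            equatorial_c=toy.selections.equatorial_c,
            n_charged="N99",
            phenyl=toy.selections.phenyl,
        )
        with pytest.raises(KeyError, match="N99"):
            pose_descriptors(toy.structure, bad)

    def test_occupancy_validation(self):
        with pytest.raises(ValueError):
            gen_toy_complex(
                guest_spec=[GuestSpec(), GuestSpec()], occupancies=(0.8, 0.4)
            )


class TestHBondGeometry:
    def test_linear_bond(self):
        atoms = [
            AtomSite("N29", "N", np.array([0.0, 0.0, 0.0])),
            AtomSite("H29", "H", np.array([0.0, 0.0, 1.0])),
            AtomSite("O1", "O", np.array([0.0, 0.0, 3.10])),
        ]
        hb = hbond_geometry(StructureModel(atoms=atoms), "N29", "H29", "O1")
        assert hb.d_da == pytest.approx(3.10)
        assert hb.angle_dha == pytest.approx(180.0)

    def test_random_geometry_matches_dot_product_oracle(self):
        rng = np.random.default_rng(4)
        d, h, a = rng.normal(size=(3, 3)) * 2.0
        atoms = [
            AtomSite("D", "N", d), AtomSite("H", "H", h), AtomSite("A", "O", a)
        ]
        hb = hbond_geometry(StructureModel(atoms=atoms), "D", "H", "A")
        assert hb.d_da == pytest.approx(np.linalg.norm(d - a), abs=1e-12)
        u, v = d - h, a - h
        expected = math.degrees(
            math.acos(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        )
        assert hb.angle_dha == pytest.approx(expected, abs=1e-9)
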