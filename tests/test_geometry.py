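"""Geometry: torsions, chain building, and per-conformer observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prolens.geometry import (
    BackboneGeometry,
    DihedralSpec,
    build_backbone,
    build_chain_coords,
    ca_contact_map,
    classify_isomer,
    cv_series,
    dihedral,
    dihedral_from_points,
    dihedral_correlation,
    end_to_end,
    radius_of_gyration,
)

SEQ = "SKSLTENKYSQLDEEQPMEID"
RNG = np.random.default_rng(1234)


def oracle_torsion(p0, p1, p2, p3):
    """Independent torsion formula: signed angle between the projections of
    the outer bonds onto the plane perpendicular to the central bond."""
    p0, p1, p2, p3 = map(np.asarray, (p0, p1, p2, p3))
    b = p2 - p1
    bhat = b / np.linalg.norm(b)
    u = (p0 - p1) - np.dot(p0 - p1, bhat) * bhat
    w = (p3 - p2) - np.dot(p3 - p2, bhat) * bhat
    x = np.dot(u, w)
    y = np.dot(np.cross(u, w), bhat)
    return np.degrees(np.arctan2(y, x))


class TestDihedral:
    def test_coplanar_syn_is_zero(self):
        assert dihedral_from_points((0, 1, 0), (0, 0, 0),
                                    (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_coplanar_anti_is_180(self):
        assert dihedral_from_points((0, 1, 0), (0, 0, 0),
                                    (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_random_quadruples_match_independent_oracle(self):
        for _ in range(100):
            pts = RNG.normal(size=(4, 3))
            got = dihedral_from_points(*pts)
            want = oracle_torsion(*pts)
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    def test_rigid_transform_invariance(self):
        pts = RNG.normal(size=(4, 3))
        ref = dihedral_from_points(*pts)
        for _ in range(20):
            # random rotation via QR, plus translation
            q, _ = np.linalg.qr(RNG.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = pts @ q.T + RNG.normal(size=3)
            got = dihedral_from_points(*moved)
            assert abs((got - ref + 180) % 360 - 180) < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral_from_points((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_named_spec_on_conformer(self):
        conf = build_backbone("AAA", np.full(3, -120.0), np.full(3, 120.0),
                              np.full(3, 180.0))
        i = [conf.atom_index(1, "N"), conf.atom_index(1, "CA"),
             conf.atom_index(1, "C"), conf.atom_index(2, "N")]
        spec = DihedralSpec("psi", tuple(i))
        assert dihedral(conf, spec) == pytest.approx(120.0, abs=1e-6)

    def test_spec_requires_distinct_indices(self):
        with pytest.raises(ValueError):
            DihedralSpec("bad", (0, 1, 1, 2))


class TestClassifyIsomer:
    @pytest.mark.parametrize("omega,label", [
        (0.0, "cis"), (180.0, "trans"), (-91.0, "trans"), (89.9, "cis"),
        (90.0, "trans"), (-90.0, "trans"), (360.0, "cis"), (269.0, "trans"),
    ])
    def test_boundary_and_wrapping(self, omega, label):
        assert classify_isomer(omega) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_isomer(np.nan)

    def test_construction_label_recovered_on_built_chains(self):
        n = len(SEQ)
        rng = np.random.default_rng(7)
        for target in (0.0, 180.0):
            phi = rng.uniform(-150, -50, n)
            psi = rng.uniform(100, 160, n)
            omega = np.full(n, 180.0)
            omega[16] = target
            conf = build_backbone(SEQ, phi, psi, omega)
            w = dihedral_from_points(conf.position(16, "CA"),
                                     conf.position(16, "C"),
                                     conf.position(17, "N"),
                                     conf.position(17, "CA"))
            want = "cis" if target == 0.0 else "trans"
            assert classify_isomer(w) == want


class TestBuildBackbone:
    def test_bond_length_echo(self):
        geom = BackboneGeometry(r_n_ca=0.1458)
        n = len(SEQ)
        conf = build_backbone(SEQ, np.full(n, -75.0), np.full(n, 150.0),
                              np.full(n, 180.0), geom)
        for i in range(1, n + 1):
            d = np.linalg.norm(conf.position(i, "CA") - conf.position(i, "N"))
            assert d == pytest.approx(0.1458, abs=1e-9)

    def test_all_dihedrals_round_trip(self):
        n = len(SEQ)
        rng = np.random.default_rng(3)
        phi = rng.uniform(-180, 180, n)
        psi = rng.uniform(-180, 180, n)
        omega = rng.uniform(-180, 180, n)
        conf = build_backbone(SEQ, phi, psi, omega)
        for i in range(2, n + 1):
            w = dihedral_from_points(conf.position(i - 1, "CA"),
                                     conf.position(i - 1, "C"),
                                     conf.position(i, "N"),
                                     conf.position(i, "CA"))
            assert abs((w - omega[i - 1] + 180) % 360 - 180) < 1e-4
            ph = dihedral_from_points(conf.position(i - 1, "C"),
                                      conf.position(i, "N"),
                                      conf.position(i, "CA"),
                                      conf.position(i, "C"))
            assert abs((ph - phi[i - 1] + 180) % 360 - 180) < 1e-4

    def test_tripeptide_matches_independent_nerf_oracle(self):
        geom = BackboneGeometry()
        phi = np.array([0.0, -120.0, -120.0])
        psi = np.array([120.0, 120.0, 120.0])
        omega = np.full(3, 180.0)
        conf = build_backbone("AAA", phi, psi, omega, geom)
        oracle = _oracle_chain("AAA", phi, psi, omega, geom)
        d_got = np.linalg.norm(conf.position(3, "CA") - conf.position(1, "CA"))
        d_want = np.linalg.norm(oracle[(3, "CA")] - oracle[(1, "CA")])
        assert d_got == pytest.approx(d_want, abs=1e-6)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            build_backbone("AXA", np.zeros(3), np.zeros(3), np.zeros(3))

    def test_missing_dihedral_names_residue(self):
        bad_psi = np.array([120.0, np.nan, 120.0])
        with pytest.raises(ValueError, match="psi for residue 2"):
            build_backbone("AAA", np.full(3, -120.0), bad_psi, np.full(3, 180.0))

    def test_proline_cd_in_amide_plane(self):
        n = len(SEQ)
        conf = build_backbone(SEQ, np.full(n, -75.0), np.full(n, 150.0),
                              np.full(n, 180.0))
        # CD, N, CA(i), C(i-1) coplanar for a planar amide
        cd = conf.position(17, "CD")
        npos = conf.position(17, "N")
        ca = conf.position(17, "CA")
        c_prev = conf.position(16, "C")
        normal = np.cross(ca - npos, c_prev - npos)
        normal /= np.linalg.norm(normal)
        assert abs(np.dot(cd - npos, normal)) < 1e-9


def _oracle_chain(seq, phi, psi, omega, geom):
    """Second, independent internal-to-Cartesian builder using explicit
    axis-angle rotations (Rodrigues), kept free of the package's NeRF code."""
    def rotate(v, axis, ang_deg):
        axis = axis / np.linalg.norm(axis)
        th = np.radians(ang_deg)
        return (v * np.cos(th) + np.cross(axis, v) * np.sin(th)
                + axis * np.dot(axis, v) * (1 - np.cos(th)))

    def place(a, b, c, bond, angle, torsion):
        d0 = (c - b) / np.linalg.norm(c - b)
        n = np.cross(b - a, d0)
        v = rotate(d0 * bond, n, 180.0 - angle)
        v = rotate(v, d0, -torsion)
        return c + v

    pos = {}
    pos[(1, "N")] = np.zeros(3)
    pos[(1, "CA")] = np.array([geom.r_n_ca, 0, 0])
    th = np.radians(geom.ang_n_ca_c)
    pos[(1, "C")] = pos[(1, "CA")] + geom.r_ca_c * np.array(
        [-np.cos(th), np.sin(th), 0.0])
    for i in range(2, len(seq) + 1):
        pos[(i, "N")] = place(pos[(i - 1, "N")], pos[(i - 1, "CA")],
                              pos[(i - 1, "C")], geom.r_c_n,
                              geom.ang_ca_c_n, psi[i - 2])
        pos[(i, "CA")] = place(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                               pos[(i, "N")], geom.r_n_ca,
                               geom.ang_c_n_ca, omega[i - 1])
        pos[(i, "C")] = place(pos[(i - 1, "C")], pos[(i, "N")],
                              pos[(i, "CA")], geom.r_ca_c,
                              geom.ang_n_ca_c, phi[i - 1])
    return pos


class TestScalarObservables:
    def test_rg_two_equal_atoms(self):
        coords = np.array([[0, 0, 0], [0.2, 0, 0]])
        assert radius_of_gyration(coords) == pytest.approx(0.1)

    def test_rg_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_rg_brute_force_oracle(self):
        coords = RNG.normal(size=(10, 3))
        m = RNG.uniform(1, 20, 10)
        com = (m[:, None] * coords).sum(0) / m.sum()
        want = np.sqrt(sum(mi * np.dot(r - com, r - com)
                           for mi, r in zip(m, coords)) / m.sum())
        assert radius_of_gyration(coords, masses=m) == pytest.approx(
            want, abs=1e-12)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rg_scales_linearly(self, s):
        coords = np.random.default_rng(0).normal(size=(8, 3))
        assert radius_of_gyration(s * coords) == pytest.approx(
            s * radius_of_gyration(coords), rel=1e-12)

    def test_end_to_end_example_and_rigid_invariance(self):
        n = len(SEQ)
        conf = build_backbone(SEQ, np.full(n, -75.0), np.full(n, 150.0),
                              np.full(n, 180.0))
        ref = end_to_end(conf)
        assert ref == pytest.approx(np.linalg.norm(
            conf.position(n, "CA") - conf.position(1, "CA")))
        q, _ = np.linalg.qr(RNG.normal(size=(3, 3)))
        moved = conf.with_coords(conf.coords @ q.T + np.array([1.0, -2.0, 3.0]))
        assert end_to_end(moved) == pytest.approx(ref, abs=1e-12)

    def test_dihcor_equal_psi_gives_n_pairs(self):
        n = 6
        conf = build_backbone("AAAAAA", np.full(n, -120.0), np.full(n, 140.0),
                              np.full(n, 180.0))
        assert dihedral_correlation(conf) == pytest.approx(n - 2, abs=1e-6)

    def test_dihcor_alternating_psi_gives_zero(self):
        psi = np.array([0.0, 180.0, 0.0, 180.0])
        conf = build_backbone("AAAA", np.full(4, -120.0), psi, np.full(4, 180.0))
        assert dihedral_correlation(conf) == pytest.approx(0.0, abs=1e-6)

    def test_dihcor_matches_term_by_term_sum(self):
        n = 7
        rng = np.random.default_rng(5)
        psi = rng.uniform(-180, 180, n)
        conf = build_backbone("A" * n, np.full(n, -100.0), psi, np.full(n, 180.0))
        want = sum(0.5 * (1 + np.cos(np.radians(psi[i] - psi[i + 1])))
                   for i in range(n - 2))
        assert dihedral_correlation(conf) == pytest.approx(want, abs=1e-6)


class TestContactMap:
    def test_symmetric_with_unit_diagonal(self, small_ensemble):
        cmap = ca_contact_map(small_ensemble.ca_coords(),
                              small_ensemble.weights, 0.8)
        assert np.array_equal(cmap, cmap.T)
        assert np.all(np.diag(cmap) == 1.0)

    def test_adjacent_residues_always_in_contact(self, small_ensemble):
        cmap = ca_contact_map(small_ensemble.ca_coords(),
                              small_ensemble.weights, 0.8)
        off = np.diag(cmap, k=1)
        assert off == pytest.approx(1.0)   # consecutive CA ~0.38 nm apart

    def test_monotone_in_cutoff(self, small_ensemble):
        prev = None
        for cut in (0.5, 0.8, 1.2, 2.0):
            cmap = ca_contact_map(small_ensemble.ca_coords(),
                                  small_ensemble.weights, cut)
            if prev is not None:
                assert np.all(cmap >= prev - 1e-12)
            prev = cmap

    def test_five_frame_brute_force(self):
        rng = np.random.default_rng(9)
        ca = rng.normal(scale=0.5, size=(5, 6, 3))
        w = rng.dirichlet(np.ones(5))
        cut = 0.6
        cmap = ca_contact_map(ca, w, cut)
        for i in range(6):
            for j in range(6):
                want = sum(w[f] for f in range(5)
                           if np.linalg.norm(ca[f, i] - ca[f, j]) < cut)
                if i == j:
                    want = 1.0
                assert cmap[i, j] == pytest.approx(want, abs=1e-12)

    def test_nonpositive_cutoff_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            ca_contact_map(small_ensemble.ca_coords(),
                           small_ensemble.weights, 0.0)


class TestCVSeries:
    def test_rg_series_matches_per_frame(self, small_ensemble):
        series = cv_series(small_ensemble, "rg")
        per_frame = [radius_of_gyration(small_ensemble.frame(i))
                     for i in range(5)]
        assert np.allclose(series.values[:5], per_frame)
        assert series.units == "nm"

    def test_zeta_series_matches_per_frame_dihedral(self, small_ensemble):
        series = cv_series(small_ensemble, "zeta:17")
        top = small_ensemble.topology
        for i in range(5):
            c = small_ensemble.coords[i]
            want = dihedral_from_points(
                c[top.atom_index(16, "CA")], c[top.atom_index(16, "O")],
                c[top.atom_index(17, "CD")], c[top.atom_index(17, "CA")])
            assert series.values[i] == pytest.approx(want, abs=1e-9)

    def test_zeta_on_non_proline_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="proline"):
            cv_series(small_ensemble, "zeta:5")

    def test_unknown_cv_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="unknown CV"):
            cv_series(small_ensemble, "nope")
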