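"""Protocol parsing, shell grouping, spherical means, gradient algebra."""

import numpy as np
import pytest
from scipy.special import erf

from sandimri.protocol import (
    AcquisitionProtocol,
    b_to_gradient,
    compute_spherical_mean,
    connectome_protocol,
    gradient_to_b,
    group_shells,
    load_dwi,
    read_bvals_bvecs,
    save_nifti,
    write_bvals_bvecs,
    CONNECTOME_SHELLS,
    _fibonacci_directions,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadBvalsBvecs:
    def test_unit_conversion_from_s_per_mm2(self, tmp_path):
        bval = _write(tmp_path, "f.bval", "0 800 800\n")
        bvec = _write(tmp_path, "f.bvec", "0 1 0\n0 0 1\n0 0 0\n")
        p = read_bvals_bvecs(bval, bvec)
        assert np.allclose(p.b_per_volume, [0.0, 0.8, 0.8])
        assert np.allclose(p.directions[1], [1, 0, 0])
        assert np.allclose(p.directions[0], 0)

    def test_low_b_shell_kept_distinct_from_b0(self, tmp_path):
        bval = _write(tmp_path, "f.bval", "0 50 6000\n")
        bvec = _write(tmp_path, "f.bvec", "0 1 0\n0 0 1\n0 0 0\n")
        p = read_bvals_bvecs(bval, bvec)
        assert np.allclose(p.b_per_volume, [0.0, 0.05, 6.0])

    def test_row_vs_column_orientation_identical(self, tmp_path):
        proto = connectome_protocol()
        bval = tmp_path / "a.bval"
        bvec = tmp_path / "a.bvec"
        write_bvals_bvecs(proto, bval, bvec)
        p1 = read_bvals_bvecs(bval, bvec)
        # transpose bvec file to N x 3 and reread
        arr = np.loadtxt(bvec)
        bvec2 = tmp_path / "b.bvec"
        np.savetxt(bvec2, arr.T, fmt="%.8f")
        p2 = read_bvals_bvecs(bval, bvec2)
        assert np.allclose(p1.b_per_volume, p2.b_per_volume)
        assert np.allclose(p1.directions, p2.directions)

    def test_length_mismatch_and_bad_entries_error(self, tmp_path):
        bval = _write(tmp_path, "f.bval", "0 800\n")
        bvec = _write(tmp_path, "f.bvec", "0 1 0\n0 0 1\n0 0 0\n")
        with pytest.raises(ValueError, match="does not match"):
            read_bvals_bvecs(bval, bvec)
        bad = _write(tmp_path, "g.bval", "0 oops 800\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_bvals_bvecs(bad, bvec)

    def test_zero_direction_on_dw_volume_errors(self, tmp_path):
        bval = _write(tmp_path, "f.bval", "0 800 800\n")
        bvec = _write(tmp_path, "f.bvec", "0 1 0\n0 0 0\n0 0 0\n")
        with pytest.raises(ValueError, match="zero-norm"):
            read_bvals_bvecs(bval, bvec)


class TestShellGrouping:
    def test_connectome_protocol_has_eight_nonzero_shells(self, protocol, shells):
        assert shells.n_shells == 8
        assert np.allclose(shells.b_values, CONNECTOME_SHELLS)
        assert shells.b0_members.size > 0
        # 32 directions below b=2.3, 64 above
        for b, n in zip(shells.b_values, shells.directions_per_shell):
            assert n == (32 if b < 2.3 else 64)

    def test_all_b0_gives_empty_nonzero_set(self):
        p = AcquisitionProtocol(np.zeros(4), np.zeros((4, 3)))
        t = group_shells(p)
        assert t.n_shells == 0
        assert t.b0_members.size == 4

    def test_values_within_tolerance_merge(self):
        p = AcquisitionProtocol(np.array([0.0, 0.80, 0.81]),
                                np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]]))
        t = group_shells(p, tolerance=0.049)
        assert t.n_shells == 1
        assert len(t.members[0]) == 2

    def test_shells_disjoint_and_cover(self, protocol, shells):
        all_idx = np.concatenate([shells.b0_members] + list(shells.members))
        assert sorted(all_idx) == list(range(protocol.n_volumes))

    def test_permutation_invariance(self, protocol):
        rng = np.random.default_rng(0)
        perm = rng.permutation(protocol.n_volumes)
        p2 = AcquisitionProtocol(protocol.b_per_volume[perm],
                                 protocol.directions[perm])
        t1, t2 = group_shells(protocol), group_shells(p2)
        assert np.allclose(t1.b_values, t2.b_values)
        assert np.array_equal(t1.directions_per_shell, t2.directions_per_shell)

    def test_ambiguous_clustering_errors(self):
        # 0.84 is within 0.049 of both the 0.80 and 0.88 cluster centres
        p = AcquisitionProtocol(np.array([0.80, 0.88, 0.84]),
                                np.eye(3))
        with pytest.raises(ValueError, match="ambiguous"):
            group_shells(p, tolerance=0.049)


class TestSphericalMean:
    def test_constant_signal_gives_ones(self, protocol, shells):
        sm = compute_spherical_mean(np.full(protocol.n_volumes, 7.3),
                                    protocol, shells)
        assert np.allclose(sm.values, 1.0)

    def test_stick_shell_mean_matches_closed_form(self):
        # 64 directions, b=1, D=2: closed form sqrt(pi/(4bD)) erf(sqrt(bD))
        dirs = _fibonacci_directions(64)
        u = np.array([0.36, -0.48, 0.8])
        b = np.concatenate([[0.0], np.ones(64)])
        d = np.vstack([[0, 0, 0], dirs])
        p = AcquisitionProtocol(b, d)
        sig = np.concatenate([[1.0], np.exp(-1.0 * 2.0 * (dirs @ u) ** 2)])
        sm = compute_spherical_mean(sig, p)
        expected = np.sqrt(np.pi / 8.0) * erf(np.sqrt(2.0))
        assert expected == pytest.approx(0.5982, abs=2e-4)
        assert sm.values[0] == pytest.approx(expected, rel=0.02)

    def test_scale_invariance(self, protocol, shells):
        rng = np.random.default_rng(1)
        sig = rng.uniform(0.1, 1.0, protocol.n_volumes)
        a = compute_spherical_mean(sig, protocol, shells)
        b = compute_spherical_mean(5.5 * sig, protocol, shells)
        assert np.allclose(a.values, b.values)

    def test_linearity_at_fixed_b0(self, protocol, shells):
        rng = np.random.default_rng(2)
        s1 = rng.uniform(0.1, 1.0, protocol.n_volumes)
        s2 = rng.uniform(0.1, 1.0, protocol.n_volumes)
        b0 = shells.b0_members
        s1[b0] = 1.0
        s2[b0] = 1.0
        lhs = compute_spherical_mean(2 * s1 + 3 * s2 - 4 * np.where(
            np.isin(np.arange(protocol.n_volumes), b0), 1.0, 0.0), protocol, shells)
        # the -4 on the b=0 indicator keeps the combined b=0 reference at 1,
        # so the nonzero-shell means combine exactly linearly
        rhs = (2 * compute_spherical_mean(s1, protocol, shells).values
               + 3 * compute_spherical_mean(s2, protocol, shells).values)
        assert np.allclose(lhs.values, rhs, atol=1e-12)

    def test_nonpositive_b0_flagged(self, protocol):
        sig = np.zeros(protocol.n_volumes)
        with pytest.raises(ValueError, match="unfittable"):
            compute_spherical_mean(sig, protocol)


class TestGradientAmplitude:
    def test_paper_maximum_shell_under_scanner_limit(self):
        g = b_to_gradient(6.0, 8.0, 19.0)
        assert g == pytest.approx(283.2, abs=0.5)
        assert g < 300.0

    def test_zero_b_gives_zero(self):
        assert b_to_gradient(0.0, 8.0, 19.0) == 0.0

    def test_roundtrip(self):
        for b in (0.05, 0.8, 6.0):
            g = b_to_gradient(b, 8.0, 19.0)
            assert gradient_to_b(g, 8.0, 19.0) == pytest.approx(b, rel=1e-10)

    def test_bad_timings_error(self):
        with pytest.raises(ValueError):
            b_to_gradient(1.0, 19.0, 8.0)


class TestDwiIO:
    def test_roundtrip_and_mismatch(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.1, 1.0, (2, 2, 2, 3))
        save_nifti(tmp_path / "d.nii.gz", data)
        _write(tmp_path, "d.bval", "0 800 800\n")
        _write(tmp_path, "d.bvec", "0 1 0\n0 0 1\n0 0 0\n")
        loaded, affine, proto = load_dwi(tmp_path / "d.nii.gz",
                                         tmp_path / "d.bval", tmp_path / "d.bvec")
        assert np.array_equal(loaded, data)
        assert proto.n_volumes == 3
        _write(tmp_path, "e.bval", "0 800 800 800\n")
        _write(tmp_path, "e.bvec", "0 1 0 0\n0 0 1 0\n0 0 0 1\n")
        with pytest.raises(ValueError, match="3 volumes.*4"):
            load_dwi(tmp_path / "d.nii.gz", tmp_path / "e.bval",
                     tmp_path / "e.bvec")
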