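"""Essential-dynamics PCA: superposition, covariance modes, twist/bend
decomposition and group comparison."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from igtandem import (DegenerateGeometryError, IgtandemError,
                      compare_ensembles, covariance_pca, mode_angles,
                      superpose_ensemble)
from igtandem.structure import TrajectoryEnsemble
from igtandem.synthetic import gen_ig_tandem, gen_trajectory


def _labels(n):
    return [("A", i + 1, "", "ALA", "CA") for i in range(n)]


def _ens(coords, groups=None):
    f = coords.shape[0]
    return TrajectoryEnsemble(coords, _labels(coords.shape[1]),
                              groups or ["g"] * f,
                              [str(i) for i in range(f)])


@pytest.fixture(scope="module")
def base():
    return gen_ig_tandem(seed=0)


@pytest.fixture(scope="module")
def split(base):
    return base.metadata["split"]


def _pipeline(base, split, **kw):
    ens = gen_trajectory(base, **kw)
    ens = superpose_ensemble(
        ens, ens.domain_indices(split, "I10", kind="backbone"))
    return covariance_pca(ens, ens.select_indices(kind="backbone"))


class TestSuperpose:
    def test_rigidly_scattered_frames_collapse(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        frames = []
        for _ in range(6):
            r = Rotation.random(random_state=rng).as_matrix()
            frames.append(pts @ r.T + rng.normal(size=3) * 10)
        ens = superpose_ensemble(_ens(np.stack(frames)), np.arange(12))
        for f in range(6):
            rmsd = np.sqrt(((ens.coords[f] - ens.coords[0]) ** 2)
                           .sum(1).mean())
            assert rmsd < 1e-9

    def test_fit_on_domain_a_keeps_it_constant(self, base, split):
        ens = gen_trajectory(base, twist_range=40.0, n_frames=10,
                             noise_sd=0.0, seed=1)
        idx = ens.domain_indices(split, "I10", kind="backbone")
        fitted = superpose_ensemble(ens, idx)
        spread = fitted.coords[:, idx, :].std(axis=0).max()
        assert spread < 1e-9

    def test_empty_selection_errors(self, rng):
        ens = _ens(rng.normal(size=(3, 5, 3)))
        with pytest.raises(DegenerateGeometryError):
            superpose_ensemble(ens, np.array([], dtype=int))


class TestCovariancePca:
    def test_rank_one_ensemble(self, rng):
        mean = rng.normal(size=(8, 3))
        v = rng.normal(size=(8, 3))
        v /= np.linalg.norm(v)
        coords = np.stack([mean + v, mean - v])
        pc = covariance_pca(_ens(coords))
        assert pc.eigenvalues[0] > 1e-6
        assert np.all(pc.eigenvalues[1:] < 1e-12)
        overlap = abs(pc.eigenvectors[0] @ v.ravel())
        assert overlap == pytest.approx(1.0, abs=1e-9)

    def test_two_orthogonal_modes_variance_ratio(self, rng):
        mean = rng.normal(size=(10, 3))
        v1 = rng.normal(size=30)
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=30)
        v2 -= (v2 @ v1) * v1
        v2 /= np.linalg.norm(v2)
        t = np.linspace(0, 4 * np.pi, 64, endpoint=False)
        x = (mean.ravel()[None, :] + 2.0 * np.sin(t)[:, None] * v1
             + 1.0 * np.cos(3 * t)[:, None] * v2)
        pc = covariance_pca(_ens(x.reshape(64, 10, 3)))
        ratio = pc.eigenvalues[0] / pc.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        coords = rng.normal(size=(20, 6, 3))
        pc = covariance_pca(_ens(coords))
        x = coords.reshape(20, -1)
        total = ((x - x.mean(0)) ** 2).sum() / 19
        assert pc.eigenvalues.sum() == pytest.approx(total, rel=1e-10)
        assert pc.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_basis_invariant_under_frame_permutation(self, rng):
        coords = rng.normal(size=(15, 5, 3))
        pc1 = covariance_pca(_ens(coords))
        perm = rng.permutation(15)
        pc2 = covariance_pca(_ens(coords[perm]))
        for m in range(3):
            dot = abs(pc1.eigenvectors[m] @ pc2.eigenvectors[m])
            assert dot == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(pc1.eigenvalues, pc2.eigenvalues,
                                   rtol=1e-9)

    def test_projection_reconstruction_roundtrip(self, rng):
        coords = rng.normal(size=(12, 7, 3))
        pc = covariance_pca(_ens(coords))
        x = coords.reshape(12, -1) - pc.mean
        back = pc.projections @ pc.eigenvectors
        np.testing.assert_allclose(back, x, atol=1e-6)

    def test_eigenvector_orthonormality_and_ordering(self, rng):
        coords = rng.normal(size=(10, 6, 3))
        pc = covariance_pca(_ens(coords))
        gram = pc.eigenvectors @ pc.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(pc.n_modes), atol=1e-6)
        assert np.all(np.diff(pc.eigenvalues) <= 1e-12)
        assert np.all(pc.eigenvalues >= -1e-9)

    def test_mode_truncation_warns(self, rng):
        coords = rng.normal(size=(4, 5, 3))
        with pytest.warns(UserWarning, match="truncating"):
            covariance_pca(_ens(coords), n_modes=10)

    def test_single_frame_errors(self, rng):
        with pytest.raises(IgtandemError):
            covariance_pca(_ens(rng.normal(size=(1, 5, 3))))


class TestModeAngles:
    def test_planted_twist_range_recovered(self, base, split):
        pc = _pipeline(base, split, twist_range=68.0, n_frames=50,
                       noise_sd=0.1, seed=0)
        ang = mode_angles(pc, 0, split)
        assert ang.twist_range == pytest.approx(68.0, abs=3.0)
        assert ang.bend_range < 5.0
        assert pc.variance_fractions[0] >= 0.90

    def test_planted_bend_range_recovered(self, base, split):
        pc = _pipeline(base, split, bend_range=65.0, n_frames=50,
                       noise_sd=0.1, seed=0)
        ang = mode_angles(pc, 0, split)
        assert ang.bend_range == pytest.approx(65.0, abs=3.0)
        assert pc.variance_fractions[0] >= 0.90

    @pytest.mark.parametrize("theta", [10.0, 30.0, 68.0])
    def test_twist_amplitude_sweep(self, base, split, theta):
        pc = _pipeline(base, split, twist_range=theta, n_frames=50,
                       noise_sd=0.1, seed=7)
        ang = mode_angles(pc, 0, split)
        assert abs(ang.twist_range - theta) <= 0.05 * theta + 1.0

    def test_reconstruct_method_underestimates_large_twist(self, base, split):
        # linear mode reconstruction shortens a rotation's chord: the
        # reconstructed range must come out below the planted 68 degrees
        pc = _pipeline(base, split, twist_range=68.0, n_frames=50,
                       noise_sd=0.05, seed=3)
        frames = mode_angles(pc, 0, split, method="frames").twist_range
        recon = mode_angles(pc, 0, split, method="reconstruct").twist_range
        assert recon < frames
        assert recon == pytest.approx(68.0, abs=10.0)

    def test_zero_variance_mode_has_zero_ranges(self, base, split):
        pc = _pipeline(base, split, twist_range=40.0, n_frames=20,
                       noise_sd=0.0, seed=2)
        ang = mode_angles(pc, pc.n_modes - 1, split)
        assert ang.twist_range < 1e-6 and ang.bend_range < 1e-6

    def test_mode_out_of_range_errors(self, base, split):
        pc = _pipeline(base, split, twist_range=40.0, n_frames=10,
                       noise_sd=0.0, seed=2)
        with pytest.raises(IgtandemError):
            mode_angles(pc, 99, split)


def _two_group_pc(base, split, centers=(16.0, -16.0), n=40, seed=0):
    wt = gen_trajectory(base, twist_range=30.0, twist_center=centers[0],
                        n_frames=n, noise_sd=0.1, seed=seed, group="wt")
    mut = gen_trajectory(base, twist_range=30.0, twist_center=centers[1],
                         n_frames=n, noise_sd=0.1, seed=seed + 1, group="mut")
    ens = TrajectoryEnsemble.concatenate([wt, mut])
    ens = superpose_ensemble(
        ens, ens.domain_indices(split, "I10", kind="backbone"))
    return covariance_pca(ens, ens.select_indices(kind="backbone"))


class TestCompareEnsembles:
    def test_identical_distributions_overlap(self, base, split):
        pc = _two_group_pc(base, split, centers=(0.0, 0.0))
        rep = compare_ensembles(pc)
        assert abs(rep.separations[1]) < 0.5
        assert rep.overlaps[1] > 0.6

    def test_offset_groups_separate_with_wt_positive(self, base, split):
        pc = _two_group_pc(base, split)  # planted ~3 pooled-SD offset
        rep = compare_ensembles(pc)
        assert rep.separations[1] == pytest.approx(3.0, abs=1.0)
        assert rep.separations[1] > 2.0
        assert rep.overlaps[1] < 0.2
        stats = rep.stats
        wt_mean = stats[(stats.group == "wt") & (stats["mode"] == 1)]
        assert wt_mean["mean"].iloc[0] > 0  # sign convention of the report

    def test_small_group_errors(self, rng):
        coords = rng.normal(size=(5, 4, 3))
        ens = _ens(coords, groups=["a"] * 4 + ["b"])
        pc = covariance_pca(ens)
        with pytest.raises(IgtandemError, match="fewer than 2"):
            compare_ensembles(pc)
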