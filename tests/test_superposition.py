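import numpy as np
import pytest

from rnassess import (DPMatrix, Structure, aggregate_dp, build_duplex,
                      deformation_index, deformation_profile, global_rmsd,
                      kabsch_superpose, map_residues, perturb_hinge,
                      perturb_noise)
from rnassess.superposition import (DomainDefinition, SuperpositionError,
                                    parse_domain_ranges)

from conftest import random_rotation


def quaternion_rmsd(P, Q):
    """Independent oracle: Theobald-style quaternion eigenvalue RMSD."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    S = P.T @ Q
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
         S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
         S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
         -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0],
         S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]]])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max(((P ** 2).sum() + (Q ** 2).sum() - 2 * lam) / len(P), 0.0)
    return float(np.sqrt(msd))


def _rot_z(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th), 0],
                     [np.sin(th), np.cos(th), 0],
                     [0, 0, 1.0]])


class TestKabsch:
    def test_recovers_known_transform(self, rng):
        moving = rng.normal(size=(10, 3))
        R = _rot_z(90.0)
        t = np.array([5.0, -2.0, 1.0])
        fixed = moving @ R.T + t
        res = kabsch_superpose(moving, fixed)
        assert res.rmsd < 1e-9
        assert np.allclose(res.rotation, R, atol=1e-9)
        assert np.allclose(res.translation, t, atol=1e-9)

    def test_rotation_is_proper_orthogonal(self, rng):
        for _ in range(20):
            res = kabsch_superpose(rng.normal(size=(6, 3)),
                                   rng.normal(size=(6, 3)))
            assert abs(np.linalg.det(res.rotation) - 1) < 1e-9
            assert np.allclose(res.rotation.T @ res.rotation, np.eye(3),
                               atol=1e-9)

    def test_matches_quaternion_oracle_noisy(self, rng):
        pts = rng.normal(size=(5, 3))
        noisy = pts + rng.normal(scale=0.3, size=(5, 3))
        res = kabsch_superpose(pts, noisy)
        assert res.rmsd == pytest.approx(quaternion_rmsd(pts, noisy), abs=1e-8)

    def test_chiral_set_keeps_proper_rotation(self):
        # mirror image of a chiral 4-point set: best proper fit is nonzero
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mirror = pts * np.array([1, 1, -1.0])
        res = kabsch_superpose(pts, mirror)
        assert abs(np.linalg.det(res.rotation) - 1) < 1e-9
        assert res.rmsd > 0.1
        # brute-force: allowing the reflection would fit exactly
        P = pts - pts.mean(0)
        Q = mirror - mirror.mean(0)
        U, S, Vt = np.linalg.svd(P.T @ Q)
        reflected = Vt.T @ U.T   # det -1 here
        assert np.linalg.det(reflected) < 0
        fit = np.sqrt(((P @ reflected.T - Q) ** 2).sum(axis=1).mean())
        assert fit < 1e-9

    def test_errors(self, rng):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(SuperpositionError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))

    def test_oracle_agreement_many(self, rng):
        worst = 0.0
        for _ in range(200):
            n = int(rng.integers(3, 11))
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            worst = max(worst, abs(kabsch_superpose(P, Q).rmsd
                                   - quaternion_rmsd(P, Q)))
        assert worst < 1e-8


class TestGlobalRmsd:
    def test_self_is_zero(self, duplex12):
        s, _ = duplex12
        m = map_residues(s, s)
        assert global_rmsd(s, s, m) < 1e-9

    def test_rigid_motion_is_zero(self, duplex12, rng):
        s, _ = duplex12
        moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 10)
        m = map_residues(moved, s)
        assert global_rmsd(moved, s, m) < 1e-9

    def test_matches_direct_kabsch_on_noisy_copy(self, duplex12):
        s, _ = duplex12
        noisy = perturb_noise(s, 0.4, seed=7)
        m = map_residues(noisy, s)
        value = global_rmsd(noisy, s, m)
        # oracle: stack the heavy-atom coordinate arrays directly
        P, Q = [], []
        for r1, r2 in zip(noisy.residues(), s.residues()):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                P.append(a1.position)
                Q.append(a2.position)
        assert value == pytest.approx(
            kabsch_superpose(np.array(P), np.array(Q)).rmsd, abs=1e-9)

    def test_symmetry(self, duplex12):
        s, _ = duplex12
        noisy = perturb_noise(s, 0.5, seed=3)
        m_fwd = map_residues(noisy, s)
        m_rev = map_residues(s, noisy)
        assert global_rmsd(noisy, s, m_fwd) == pytest.approx(
            global_rmsd(s, noisy, m_rev), abs=1e-9)

    def test_noise_monotone_in_sigma(self, duplex12):
        s, _ = duplex12
        m = map_residues(s, s)
        means = []
        for sigma in (0.1, 0.5, 1.0, 2.0):
            vals = [global_rmsd(perturb_noise(s, sigma, seed=seed), s, m)
                    for seed in range(20)]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestDeformationProfile:
    def test_identical_all_zero(self, duplex8):
        s, _ = duplex8
        m = map_residues(s, s)
        dp = deformation_profile(s, s, m)
        assert np.nanmax(dp.values) < 1e-9

    def test_rigid_motion_all_zero(self, duplex8, rng):
        s, _ = duplex8
        moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 15)
        m = map_residues(moved, s)
        dp = deformation_profile(moved, s, m)
        assert np.nanmax(dp.values) < 1e-9

    def test_hinge_blocks(self, duplex12):
        s, _ = duplex12
        hinged, split = perturb_hinge(s, ("A", 6, ""), 30.0, seed=5)
        m = map_residues(hinged, s)
        dp = deformation_profile(hinged, s, m)
        idx = {k: i for i, k in enumerate(dp.residue_keys)}
        fixed = [idx[k] for k in split["fixed"]]
        moved = [idx[k] for k in split["moved"]]
        intra_fixed = dp.values[np.ix_(fixed, fixed)]
        intra_moved = dp.values[np.ix_(moved, moved)]
        inter = dp.values[np.ix_(fixed, moved)]
        assert np.nanmax(intra_fixed) <= 0.1
        assert np.nanmax(intra_moved) <= 0.1
        assert np.nanmean(inter) > 2.0

    def test_local_row_minimum_near_anchor(self, duplex12):
        s, _ = duplex12
        hinged, split = perturb_hinge(s, ("A", 6, ""), 40.0, seed=2)
        m = map_residues(hinged, s)
        dp = deformation_profile(hinged, s, m)
        idx = {k: i for i, k in enumerate(dp.residue_keys)}
        for key in split["fixed"]:
            if key not in idx:
                continue
            row = dp.values[idx[key]]
            assert row[idx[key]] <= np.nanmax(row) + 1e-12
            assert row[idx[key]] < 1e-9  # anchor distance to itself

    def test_degenerate_anchor_flagged(self, duplex8):
        s, _ = duplex8
        model = s.copy()
        # strip residue A1 down to 2 atoms in the model
        for cid, residues in model.chains:
            if cid == "A":
                residues[0].atoms = residues[0].atoms[:2]
        model = Structure(id="m", chains=model.chains)
        m = map_residues(model, s)
        dp = deformation_profile(model, s, m)
        assert ("A", 1, "") in dp.flagged_rows


class TestAggregateDp:
    def _dp(self, values, n=8):
        keys = [("A", i + 1, "") for i in range(n)]
        return DPMatrix(residue_keys=keys, values=np.asarray(values, float))

    def test_all_ones(self):
        dp = self._dp(np.ones((8, 8)))
        doms = [DomainDefinition("D1", {("A", i, "") for i in range(1, 5)}),
                DomainDefinition("D2", {("A", i, "") for i in range(5, 9)})]
        stats = aggregate_dp(dp, doms)
        assert len(stats) == 4
        for s_ in stats:
            assert s_.min == s_.max == s_.mean == 1.0

    def test_all_zeros(self):
        dp = self._dp(np.zeros((8, 8)))
        doms = [DomainDefinition("D1", {("A", i, "") for i in range(1, 9)})]
        stats = aggregate_dp(dp, doms)
        assert stats[0].min == stats[0].max == stats[0].mean == 0.0

    def test_min_le_mean_le_max(self, rng):
        dp = self._dp(np.abs(rng.normal(size=(8, 8))))
        doms = [DomainDefinition("D1", {("A", i, "") for i in range(1, 4)}),
                DomainDefinition("D2", {("A", i, "") for i in range(4, 9)})]
        for s_ in aggregate_dp(dp, doms):
            assert s_.min <= s_.mean <= s_.max

    def test_unknown_key_raises(self):
        dp = self._dp(np.zeros((8, 8)))
        doms = [DomainDefinition("D1", {("B", 1, "")})]
        with pytest.raises(ValueError):
            aggregate_dp(dp, doms)

    def test_hinge_intra_lt_inter(self, duplex12):
        s, _ = duplex12
        hinged, split = perturb_hinge(s, ("A", 6, ""), 30.0, seed=5)
        m = map_residues(hinged, s)
        dp = deformation_profile(hinged, s, m)
        doms = [DomainDefinition("fixed", set(split["fixed"])),
                DomainDefinition("moved", set(split["moved"]))]
        stats = {(x.domain_a, x.domain_b): x for x in aggregate_dp(dp, doms)}
        assert stats[("fixed", "fixed")].mean < stats[("fixed", "moved")].mean
        assert stats[("moved", "moved")].mean < stats[("moved", "fixed")].mean

    def test_parse_domain_ranges(self, duplex8):
        s, _ = duplex8
        keys = [r.key for r in s.residues()]
        doms = parse_domain_ranges({"P1": ["A:1-4", "B:5-8"], "P2": ["A:5-8"]},
                                   keys)
        by_name = {d.name: d for d in doms}
        assert len(by_name["P1"].members) == 8
        assert len(by_name["P2"].members) == 4
        with pytest.raises(ValueError):
            parse_domain_ranges({"bad": ["C:1-4"]}, keys)


class TestDeformationIndex:
    def test_arithmetic(self):
        assert deformation_index(4.0, 0.8) == pytest.approx(5.0)

    def test_inf_one_gives_rmsd(self):
        assert deformation_index(3.21, 1.0) == pytest.approx(3.21)

    def test_inf_zero_is_undefined(self):
        assert deformation_index(4.0, 0.0) is None
        assert deformation_index(4.0, None) is None

    def test_negative_rmsd_rejected(self):
        with pytest.raises(ValueError):
            deformation_index(-1.0, 0.5)
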