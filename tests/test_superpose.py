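import itertools

import numpy as np
import pytest

from foldphylo.superpose import (
    AlignParams,
    InsufficientPointsError,
    _dp_align,
    align_structures,
    kabsch,
)
from foldphylo.synthetic import make_fold

from conftest import mk_structure


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def brute_force_proper_rmsd(P, Q, n_grid=40):
    """Numeric oracle: best proper-rotation RMSD via dense quaternion search
    with local refinement."""
    rng = np.random.default_rng(123)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_for(R):
        return np.sqrt(((P0 - Q0 @ R.T) ** 2).sum() / len(P))

    best = np.inf
    best_R = None
    for _ in range(n_grid * 200):
        R = random_rotation(rng)
        r = rmsd_for(R)
        if r < best:
            best, best_R = r, R
    # crude local polish around the best sample
    for scale in (0.1, 0.03, 0.01, 0.003):
        for _ in range(300):
            d = rng.normal(scale=scale, size=3)
            c, s = np.cos(np.linalg.norm(d)), np.sin(np.linalg.norm(d))
            axis = d / (np.linalg.norm(d) + 1e-12)
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = (np.eye(3) + s * K + (1 - c) * (K @ K)) @ best_R
            r = rmsd_for(R)
            if r < best:
                best, best_R = r, R
    return best


class TestKabsch:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(7, 3))
        R, t, rmsd = kabsch(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        R0 = random_rotation(rng)
        Q = (P - [1, 2, 3]) @ R0.T + [5, 0, 0]
        R, t, rmsd = kabsch(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_corrected_vs_brute_force(self):
        # mirror image of a chiral set: an improper transform would give
        # rmsd 0, but only proper rotations are admissible (a planar set
        # would be recoverable by a 180° flip, so a fourth off-plane point
        # is required)
        P = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.0]])
        Q = P * np.array([1.0, -1.0, 1.0])
        R, t, rmsd = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1
        oracle = brute_force_proper_rmsd(P, Q)
        # the analytic optimum can only be at least as good as any sampled
        # rotation, and the sampler should approach it from above
        assert rmsd <= oracle + 1e-9
        assert oracle - rmsd <= 0.05 * rmsd

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def enumerate_monotone_matchings(S, gap):
    """Oracle: best score over all strictly monotone pair sets, scored as
    sum(S) - gap * (unmatched positions)."""
    na, nb = S.shape
    best = {"score": -np.inf, "pairs": None}

    def rec(i, j, score, k, pairs):
        if i == na or j == nb:
            total = score - gap * (na + nb - 2 * k)
            if total > best["score"] + 1e-12:
                best["score"] = total
                best["pairs"] = list(pairs)
            return
        rec(i + 1, j, score, k, pairs)
        rec(i, j + 1, score, k, pairs)
        pairs.append((i, j))
        rec(i + 1, j + 1, score + S[i, j], k + 1, pairs)
        pairs.pop()

    rec(0, 0, 0.0, 0, [])
    return best["score"], best["pairs"]


class TestDPAlignment:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dp_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 1, size=(6, 7))
        gap = 0.3
        oracle_score, _ = enumerate_monotone_matchings(S, gap)
        pairs = _dp_align(S, gap)
        score = sum(S[i, j] for i, j in pairs) - gap * (6 + 7 - 2 * len(pairs))
        assert score == pytest.approx(oracle_score, abs=1e-9)
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        assert ia == sorted(ia) and ib == sorted(ib)
        assert len(set(ia)) == len(ia) and len(set(ib)) == len(ib)


class TestAlignStructures:
    def test_self_alignment(self, fold60):
        r = align_structures(fold60, fold60)
        assert r.n_aligned == fold60.n
        assert r.rmsd <= 1e-6

    def test_middle_deletion(self, fold60):
        coords = np.delete(fold60.coords, slice(25, 35), axis=0)
        nums = [n for i, (n, _) in enumerate(fold60.residues) if not 25 <= i < 35]
        b = mk_structure(coords, id="del10")
        b.residues = [(n, "A") for n in nums]
        r = align_structures(fold60, b)
        assert r.n_aligned == fold60.n - 10
        assert r.rmsd <= 1e-6

    def test_noise_alignment_matches_simulation_oracle(self, fold60):
        sigma = 0.3
        # Monte-Carlo expectation of the optimally-superposed RMSD at this σ,
        # using the known residue correspondence
        rng = np.random.default_rng(99)
        expected = np.mean(
            [
                kabsch(fold60.coords, fold60.coords + rng.normal(scale=sigma, size=fold60.coords.shape))[2]
                for _ in range(30)
            ]
        )
        pert = fold60.coords + np.random.default_rng(7).normal(
            scale=sigma, size=fold60.coords.shape
        )
        r = align_structures(fold60, mk_structure(pert, id="noisy"))
        assert r.n_aligned >= 0.95 * fold60.n
        assert abs(r.rmsd - expected) <= 0.2 * expected

    def _diverged_copy(self, fold60, id="mut"):
        """A structurally related partner: noisy, with a terminal deletion."""
        rng = np.random.default_rng(17)
        coords = fold60.coords[:-6] + rng.normal(scale=0.25, size=(fold60.n - 6, 3))
        return mk_structure(coords, id=id)

    def test_rigid_motion_invariance(self, fold60):
        rng = np.random.default_rng(5)
        other = self._diverged_copy(fold60)
        base = align_structures(fold60, other)
        R0 = random_rotation(rng)
        moved = mk_structure(other.coords @ R0.T + [10.0, -3.0, 2.0], id=other.id)
        r = align_structures(fold60, moved)
        assert base.n_aligned > 0
        assert r.n_aligned == base.n_aligned
        assert r.rmsd == pytest.approx(base.rmsd, abs=1e-6)

    def test_symmetric_contract(self, fold60):
        other = self._diverged_copy(fold60, id="zmut")
        ab = align_structures(fold60, other)
        ba = align_structures(other, fold60)
        assert ab.n_aligned == ba.n_aligned > 0
        assert ab.rmsd == pytest.approx(ba.rmsd, abs=1e-6)
        assert sorted((j, i) for i, j in ab.pairs) == sorted(ba.pairs)

    def test_no_alignment_below_min_core(self):
        a = make_fold([("helix", 12)], seed=1, id="a")
        b = make_fold([("strand", 12)], seed=2, id="b")
        r = align_structures(a, b, AlignParams(min_core=13))
        assert r.n_aligned == 0
        assert np.isnan(r.rmsd)

    def test_monotone_refinement_pair_count_bound(self, fold60):
        r = align_structures(fold60, fold60)
        assert 0 <= r.n_aligned <= min(r.n_a, r.n_b)
        assert np.linalg.det(r.rotation) == pytest.approx(1.0, abs=1e-9)
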