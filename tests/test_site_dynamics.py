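"""Binding-site extraction, featurization, k-means and silhouette."""

import numpy as np
import pytest

from pocketome.site_dynamics import (
    EmptySiteError,
    centroid_frames,
    extract_binding_site,
    featurize,
    kmeans,
    select_k,
    silhouette,
)
from pocketome.structure_io import Atom, Residue, Structure, TrajectoryEnsemble
from pocketome.synthetic import FixtureSpec, make_trajectory


def _point_residue(chain, resseq, resname, name, xyz, element=None):
    return Residue(chain, resseq, "", resname,
                   [Atom(1, name, element or name[0], "", 1.0, np.array(xyz, float))])


def _toy_system(res_dists):
    """Ligand atom at origin; one CA-only residue per requested distance."""
    lig = _point_residue("L", 1, "LIG", "C1", [0, 0, 0])
    residues = [
        _point_residue("A", i + 1, "GLY", "CA", [d, 0.0, 0.0])
        for i, d in enumerate(res_dists)
    ]
    topo = Structure(id="toy", residues=residues + [lig])
    receptor = Structure(id="toy:receptor", residues=residues)
    frames = topo.coords()[None]
    return TrajectoryEnsemble(topology=topo, frames=frames), receptor, lig


class TestExtractBindingSite:
    def test_cutoff_is_closed_boundary(self):
        ens, receptor, lig = _toy_system([5.0, 9.5, 10.5])
        sel = extract_binding_site(ens, receptor, lig, cutoff=10.0)
        assert sel.residue_ids == frozenset({("A", 1, ""), ("A", 2, "")})
        # exactly at the cutoff is included
        ens10, rec10, lig10 = _toy_system([10.0])
        sel10 = extract_binding_site(ens10, rec10, lig10, cutoff=10.0)
        assert sel10.residue_ids == frozenset({("A", 1, "")})

    def test_union_over_frames(self):
        ens, receptor, lig = _toy_system([11.0])
        f2 = ens.frames[0].copy()
        f2[0, 0] = 9.0  # residue X moves inside the cutoff in frame 2
        ens2 = TrajectoryEnsemble(topology=ens.topology,
                                  frames=np.stack([ens.frames[0], f2]))
        sel = extract_binding_site(ens2, receptor, lig, cutoff=10.0)
        assert ("A", 1, "") in sel.residue_ids

    def test_empty_site_raises(self):
        ens, receptor, lig = _toy_system([5.0, 8.0])
        with pytest.raises(EmptySiteError, match="cutoff"):
            extract_binding_site(ens, receptor, lig, cutoff=0.5)


class TestFeaturize:
    def _site_system(self, fx_complex):
        topo = fx_complex.complex
        return topo

    def test_feature_dimensions(self):
        ens, receptor, lig = _toy_system([5.0, 8.0, 9.0])
        sel = extract_binding_site(ens, receptor, lig, cutoff=10.0)
        F = featurize(ens, sel, lig)
        # 1 ligand atom + 3 single-atom residues -> 12 columns
        assert F.X.shape == (1, 12)

    def test_rigid_motion_removed(self, fx_complex):
        from pocketome.synthetic import _rotation

        topo = fx_complex.complex
        base = topo.coords()
        R = _rotation([1.0, 2.0, 0.5], 1.1)
        moved = base @ R.T + np.array([5.0, -3.0, 2.0])
        ens = TrajectoryEnsemble(topology=topo, frames=np.stack([base, moved]))
        receptor = Structure(id="r", residues=[r for r in topo.residues
                                               if r.chain == "A"])
        lig = [r for r in topo.residues if r.chain == "L"][0]
        sel = extract_binding_site(ens, receptor, lig, cutoff=10.0)
        F = featurize(ens, sel, lig)
        np.testing.assert_allclose(F.X[0], F.X[1], atol=1e-6)

    def test_identical_frames_identical_rows(self, fx_complex):
        topo = fx_complex.complex
        base = topo.coords()
        ens = TrajectoryEnsemble(topology=topo, frames=np.repeat(base[None], 10, axis=0))
        receptor = Structure(id="r", residues=[r for r in topo.residues
                                               if r.chain == "A"])
        lig = [r for r in topo.residues if r.chain == "L"][0]
        sel = extract_binding_site(ens, receptor, lig, cutoff=10.0)
        F = featurize(ens, sel, lig)
        assert np.allclose(F.X, F.X[0])


def _blobs(rng, centers, n_per, sigma):
    X = np.concatenate([
        c + rng.normal(0.0, sigma, size=(n_per, len(c))) for c in centers
    ])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestKMeans:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X, truth = _blobs(rng, [np.zeros(3), np.full(3, 100.0)], 10, 0.5)
        model = kmeans(X, 2, seed=3)
        # compare partitions up to label permutation
        same = (model.labels == model.labels[0])
        assert np.array_equal(same, truth == truth[0])
        # exhaustive check: no 2-partition has lower inertia
        import itertools
        best = np.inf
        n = len(X)
        for mask_bits in range(1, 2 ** (n - 1)):
            mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
            if mask.sum() in (0, n):
                continue
            inertia = sum(((X[g] - X[g].mean(axis=0)) ** 2).sum()
                          for g in (mask, ~mask))
            best = min(best, inertia)
        assert model.inertia == pytest.approx(best, rel=1e-9)

    def test_identical_rows(self):
        X = np.ones((6, 4))
        model = kmeans(X, 2, seed=0)
        assert model.inertia == 0.0
        assert set(model.labels.tolist()) <= {0, 1}

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        m1 = kmeans(X, 4, seed=11)
        m2 = kmeans(X, 4, seed=11)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.inertia == m2.inertia

    def test_k_bounds(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans(X, 4, seed=0)
        with pytest.raises(ValueError):
            kmeans(X, 1, seed=0)


def _silhouette_bruteforce(X, labels):
    n = len(X)
    D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    vals = []
    for i in range(n):
        mine = labels[i]
        same = [j for j in range(n) if labels[j] == mine and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != mine)
        m = max(a, b)
        vals.append(0.0 if m == 0 else (b - a) / m)
    return float(np.mean(vals))


class TestSilhouette:
    def test_matches_bruteforce_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(40, 3))
            labels = rng.integers(0, 3, size=40)
            if len(set(labels.tolist())) < 2:
                continue
            ours = silhouette(X, labels)
            assert ours == pytest.approx(_silhouette_bruteforce(X, labels), abs=1e-10)
            from sklearn.metrics import silhouette_score
            assert ours == pytest.approx(silhouette_score(X, labels), abs=1e-8)

    def test_perfectly_separated_duplicates(self):
        X = np.array([[0.0, 0.0]] * 5 + [[50.0, 0.0]] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert silhouette(X, labels) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        vals = [silhouette(X, rng.integers(0, 2, size=40))
                for _ in range(20)]
        assert max(abs(v) for v in vals) < 0.15

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestSelectK:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_generating_k(self, k_true):
        rng = np.random.default_rng(k_true)
        centers = [rng.normal(scale=50.0, size=4) for _ in range(k_true)]
        X, _ = _blobs(rng, centers, 10, 0.5)
        k_best, model = select_k(X, seed=0)
        assert k_best == k_true
        assert model.silhouette > 0.9

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((1, 3)))


class TestCentroidFrames:
    def test_row_at_mean_wins(self):
        X = np.array([[0.0], [1.0], [2.0]])
        model = kmeans(X, 2, seed=0)
        cents = centroid_frames(X, model)
        for j, c in enumerate(cents):
            members = np.flatnonzero(model.labels == j)
            d = np.abs(X[members, 0] - model.means[j, 0])
            assert c == members[np.argmin(d)]

    def test_tie_takes_lowest_index(self):
        X = np.zeros((6, 2))
        model = kmeans(X, 2, seed=1)
        cents = centroid_frames(X, model)
        for j, c in enumerate(cents):
            assert c == int(np.flatnonzero(model.labels == j)[0])

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 4))
        model = kmeans(X, 2, seed=2)
        cents = centroid_frames(X, model)
        for j, c in enumerate(cents):
            members = np.flatnonzero(model.labels == j)
            dists = np.linalg.norm(X[members] - model.means[j], axis=1)
            assert c == members[np.argmin(dists)]


class TestTrajectoryFixtureClustering:
    def test_k_recovery_on_synthetic_trajectory(self):
        spec = FixtureSpec(seed=0, k_true=3, frames_per_cluster=10,
                           cluster_displacement=6.0, noise_sigma=0.3)
        ens, labels, fx = make_trajectory(spec)
        from pocketome.structure_io import split_complex
        receptor, ligand = split_complex(ens.topology, "A", "L")
        sel = extract_binding_site(ens, receptor, ligand, cutoff=10.0)
        F = featurize(ens, sel, ligand)
        k_best, model = select_k(F, seed=0)
        assert k_best == 3
        # partition matches the generating labels up to permutation
        import itertools
        for perm in itertools.permutations(range(3)):
            if np.array_equal(np.array(perm)[model.labels], labels):
                break
        else:
            pytest.fail("clusters do not match the generating labels")
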