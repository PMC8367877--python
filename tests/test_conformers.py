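"""Conformer curation: superposition RMSD, greedy clustering, selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from microthermo import (
    ClusterConfig,
    ConformerGeometry,
    best_rmsd,
    curation_pipeline,
    dedup_post_optimization,
    energy_window_filter,
    greedy_rmsd_cluster,
    kabsch_rmsd,
    select_top_k,
)
from microthermo.synthetic_data import generate_conformer_clouds


def geom(coords, energy=0.0, cid="g", labels=None, perms=()):
    coords = np.asarray(coords, dtype=float)
    labels = labels or ("C",) * len(coords)
    return ConformerGeometry(
        conformer_id=cid, coordinates=coords, atom_labels=tuple(labels),
        energy=energy, symmetry_permutations=perms,
    )


def rotation_z(deg):
    t = math.radians(deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )


def grid_rmsd_oracle(a, b, n_angles=60):
    """Brute-force minimum RMSD over a dense SO(3) Euler-angle grid with
    optimal (centroid) translation — independent of the SVD route."""
    A = a - a.mean(axis=0)
    B = b - b.mean(axis=0)
    best = math.inf
    angles = np.linspace(0.0, 2 * math.pi, n_angles, endpoint=False)
    half = np.linspace(0.0, math.pi, n_angles // 2 + 1)
    for alpha in angles:
        ca, sa = math.cos(alpha), math.sin(alpha)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for beta in half:
            cb, sb = math.cos(beta), math.sin(beta)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            m = rz1 @ ry
            for gamma in angles:
                cg, sg = math.cos(gamma), math.sin(gamma)
                rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                r = m @ rz2
                best = min(best, math.sqrt(np.mean(np.sum((A @ r.T - B) ** 2, axis=1))))
    return best


class TestKabschRmsd:
    def test_identical_is_zero(self):
        a = geom([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        coords = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.2, 0], [0.3, 0.4, 1.1]])
        moved = coords @ rotation_z(90).T + np.array([5.0, 5.0, 5.0])
        assert kabsch_rmsd(geom(coords), geom(moved)) == pytest.approx(0.0, abs=1e-8)

    def test_matches_so3_grid_oracle(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        b = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0]], dtype=float)
        exact = kabsch_rmsd(geom(a), geom(b))
        oracle = grid_rmsd_oracle(a, b)
        # the grid can only overestimate the true minimum
        assert exact <= oracle + 1e-9
        assert oracle - exact < 1e-3 * max(1.0, oracle / 0.3)
        assert exact == pytest.approx(oracle, abs=2e-3)

    def test_no_reflections_chirality_preserved(self):
        # a chiral 4-point set and its mirror image must NOT superpose to 0
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirror = coords * np.array([1, 1, -1])
        assert kabsch_rmsd(geom(coords), geom(mirror)) > 0.3

    def test_atom_mismatch_rejected(self):
        a = geom([[0, 0, 0], [1, 0, 0]], labels=("C", "N"))
        b = geom([[0, 0, 0], [1, 0, 0]], labels=("C", "O"))
        with pytest.raises(ValueError, match="atom mismatch"):
            kabsch_rmsd(a, b)

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=50)
    def test_pseudometric_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        pts = [rng.normal(size=(5, 3)) for _ in range(3)]
        g = [geom(p, cid=f"g{i}") for i, p in enumerate(pts)]
        d01, d10 = kabsch_rmsd(g[0], g[1]), kabsch_rmsd(g[1], g[0])
        assert d01 == pytest.approx(d10, abs=1e-9)  # symmetric
        d02, d12 = kabsch_rmsd(g[0], g[2]), kabsch_rmsd(g[1], g[2])
        assert d02 <= d01 + d12 + 1e-9  # triangle inequality

    def test_rdkit_cross_check(self):
        """Independent oracle: rdkit's alignment on the same coordinates."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import AllChem, rdMolAlign

        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.3, size=(6, 3))

        def to_mol(coords):
            mol = Chem.RWMol()
            for _ in range(len(coords)):
                mol.AddAtom(Chem.Atom(6))
            conf = Chem.Conformer(len(coords))
            for i, (x, y, z) in enumerate(coords):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            m = mol.GetMol()
            m.AddConformer(conf)
            return m

        ours = kabsch_rmsd(geom(a), geom(b))
        theirs = rdMolAlign.GetBestRMS(to_mol(a), to_mol(b))
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestBestRmsd:
    def test_defaults_to_kabsch(self):
        a = geom([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        b = geom([[0, 0, 0], [1, 0, 0], [0, 1.4, 0]])
        assert best_rmsd(a, b) == kabsch_rmsd(a, b)

    def test_symmetry_swap_recovers_zero(self):
        # two like-labelled atoms in inequivalent positions swapped in the
        # record order; only the permutation can recover the exact match
        coords = np.array(
            [[0, 0, 0], [1.2, 0, 0], [-1.0, 0.3, 0.4], [0, 1, 0], [0.3, 0.2, 0.9]],
            dtype=float,
        )
        swapped = coords[[0, 2, 1, 3, 4]]
        labels = ("C", "O", "O", "N", "H")
        a = geom(coords, labels=labels)
        b = geom(swapped, labels=labels)
        assert kabsch_rmsd(a, b) > 0.1
        swap = ((0, 2, 1, 3, 4),)
        assert best_rmsd(a, b, permutations=swap) == pytest.approx(0.0, abs=1e-8)

    def test_including_identity_never_hurts(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(4, 3))
        other = rng.normal(size=(4, 3))
        a, b = geom(coords), geom(other)
        perms = ((0, 1, 2, 3), (1, 0, 2, 3), (0, 1, 3, 2))
        assert best_rmsd(a, b, permutations=perms) <= kabsch_rmsd(a, b) + 1e-12

    def test_invalid_permutation_rejected(self):
        a = geom([[0, 0, 0], [1, 0, 0]], labels=("C", "N"))
        b = geom([[0, 0, 0], [1, 0, 0]], labels=("C", "N"))
        with pytest.raises(ValueError, match="element labels"):
            best_rmsd(a, b, permutations=((1, 0),))
        with pytest.raises(ValueError, match="bijection"):
            best_rmsd(a, b, permutations=((0, 0),))


class TestEnergyWindowFilter:
    def test_inclusive_boundary(self):
        confs = [geom([[0, 0, 0]], energy=e, cid=f"c{e}") for e in (0.0, 19.9, 20.0, 20.1)]
        kept = energy_window_filter(confs, ClusterConfig(energy_window=20.0))
        assert [c.energy for c in kept] == [0.0, 19.9, 20.0]

    def test_all_equal_all_kept(self):
        confs = [geom([[0, 0, 0]], energy=1.0, cid=f"c{i}") for i in range(4)]
        assert len(energy_window_filter(confs)) == 4

    def test_window_five(self):
        confs = [geom([[0, 0, 0]], energy=e, cid=f"c{e}") for e in (0.0, 4.0, 6.0)]
        kept = energy_window_filter(confs, ClusterConfig(energy_window=5.0))
        assert [c.energy for c in kept] == [0.0, 4.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            energy_window_filter([])


def chain_geometries():
    """A-B-C with RMSD(A,B)=RMSD(B,C)<0.5<=RMSD(A,C), E_A<E_B<E_C.

    Built by translating one atom of a 4-atom base along x; the measured
    superposition RMSDs are ~0.325 (adjacent) and ~0.647 (outer pair).
    """
    base = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], dtype=float)

    def shifted(dx, cid, e):
        c = base.copy()
        c[0, 0] += dx
        return geom(c, energy=e, cid=cid)

    a = shifted(0.0, "A", 0.0)
    b = shifted(0.81, "B", 1.0)
    c = shifted(1.62, "C", 2.0)
    return a, b, c


class TestGreedyCluster:
    def test_single_conformer(self):
        c = geom([[0, 0, 0]], energy=0.0)
        assert greedy_rmsd_cluster([c]) == [c]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            greedy_rmsd_cluster([])

    def test_three_separated_clouds(self):
        geoms, truth = generate_conformer_clouds(
            seed=11, n_clusters=3, jitter_sd=0.05,
            centroid_separation=3.0, points_per_cluster=5,
        )
        reps = greedy_rmsd_cluster(geoms, ClusterConfig(rmsd_cutoff=0.5))
        assert len(reps) == truth.n_clusters
        # each representative is the lowest-energy member of its cloud
        # (energies increase with index, clouds are generated cluster-major)
        rep_clusters = sorted(
            truth.memberships[int(r.conformer_id.split("_p")[1])] for r in reps
        )
        assert rep_clusters == [0, 1, 2]
        for r in reps:
            idx = int(r.conformer_id.split("_p")[1])
            cluster = truth.memberships[idx]
            members = [i for i, m in enumerate(truth.memberships) if m == cluster]
            assert idx == min(members)

    def test_huge_cutoff_single_representative(self):
        geoms, _ = generate_conformer_clouds(
            seed=2, n_clusters=2, jitter_sd=0.02,
            centroid_separation=2.0, points_per_cluster=3,
        )
        assert len(greedy_rmsd_cluster(geoms, ClusterConfig(rmsd_cutoff=100.0))) == 1

    def test_chain_hand_trace(self):
        a, b, c = chain_geometries()
        assert kabsch_rmsd(a, b) == pytest.approx(0.325, abs=0.02)
        assert kabsch_rmsd(b, c) == pytest.approx(0.325, abs=0.02)
        assert kabsch_rmsd(a, c) == pytest.approx(0.647, abs=0.03)
        reps = dedup_post_optimization([a, b, c], ClusterConfig(rmsd_cutoff=0.5))
        # greedy: A seeds; B within 0.5 of A -> dropped; C >= 0.5 from A -> kept
        assert [r.conformer_id for r in reps] == ["A", "C"]

    def test_converged_duplicates_keep_lower_energy(self):
        x = geom([[0, 0, 0], [2, 0, 0], [0, 2, 0]], energy=1.0, cid="hi")
        y = geom([[0.005, 0, 0], [2, 0, 0], [0, 2, 0]], energy=0.5, cid="lo")
        reps = dedup_post_optimization([x, y], ClusterConfig(rmsd_cutoff=0.5))
        assert [r.conformer_id for r in reps] == ["lo"]

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=25, deadline=None)
    def test_representative_separation_and_coverage(self, seed):
        rng = np.random.default_rng(seed)
        geoms = [
            geom(rng.normal(scale=1.0, size=(4, 3)), energy=float(rng.normal()),
                 cid=f"r{i}")
            for i in range(8)
        ]
        cutoff = 0.8
        reps = greedy_rmsd_cluster(geoms, ClusterConfig(rmsd_cutoff=cutoff))
        for r1, r2 in itertools.combinations(reps, 2):
            assert best_rmsd(r1, r2) >= cutoff - 1e-9
        # every discarded structure is near a representative of <= energy
        rep_ids = {r.conformer_id for r in reps}
        for g0 in geoms:
            if g0.conformer_id in rep_ids:
                continue
            assert any(
                best_rmsd(r, g0) < cutoff and r.energy <= g0.energy + 1e-12
                for r in reps
            )

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @hyp_settings(derandomize=True, max_examples=15, deadline=None)
    def test_monotone_in_cutoff_and_window(self, seed):
        rng = np.random.default_rng(seed)
        geoms = [
            geom(rng.normal(scale=1.2, size=(4, 3)),
                 energy=float(rng.uniform(0, 30)), cid=f"r{i}")
            for i in range(10)
        ]
        counts_cutoff = [
            len(greedy_rmsd_cluster(geoms, ClusterConfig(rmsd_cutoff=c)))
            for c in (0.3, 0.8, 1.5, 3.0)
        ]
        assert counts_cutoff == sorted(counts_cutoff, reverse=True)
        counts_window = [
            len(energy_window_filter(geoms, ClusterConfig(energy_window=w)))
            for w in (5.0, 10.0, 20.0, 40.0)
        ]
        assert counts_window == sorted(counts_window)


class TestSelectionAndPipeline:
    def test_top_k_fewer_than_k(self):
        confs = [geom([[0, 0, 0]], energy=float(i), cid=f"c{i}") for i in range(3)]
        assert len(select_top_k(confs, 5)) == 3

    def test_top_k_lowest_and_stable_ties(self):
        energies = [3.0, 1.0, 2.0, 1.0, 5.0, 0.5, 2.0]
        confs = [geom([[0, 0, 0]], energy=e, cid=f"c{i}") for i, e in enumerate(energies)]
        top = select_top_k(confs, 5)
        assert [c.energy for c in top] == [0.5, 1.0, 1.0, 2.0, 2.0]
        # ties resolved by input order
        assert [c.conformer_id for c in top] == ["c5", "c1", "c3", "c2", "c6"]

    def test_pipeline_idempotent(self):
        geoms, _ = generate_conformer_clouds(
            seed=9, n_clusters=4, jitter_sd=0.05,
            centroid_separation=2.5, points_per_cluster=4,
        )
        config = ClusterConfig(energy_window=20.0, rmsd_cutoff=0.5, max_representatives=5)
        once = curation_pipeline(geoms, config)
        twice = curation_pipeline(once, config)
        assert [c.conformer_id for c in once] == [c.conformer_id for c in twice]
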