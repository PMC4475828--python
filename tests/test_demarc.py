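"""Distances, trees, bin curves, the Stable Ecotype Model simulator,
its approximate-likelihood fit, and PE demarcation."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from ecodemarc import demarc

from conftest import planted_ecotype_sequences


def _mutate(seq: str, positions) -> str:
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = rot[out[p]]
    return "".join(out)


class TestCorrectedDistances:
    def test_identical_pair_distance_zero(self):
        dm = demarc.corrected_distances({"a": "ACGT" * 10, "b": "ACGT" * 10})
        assert dm["a", "b"] == 0.0

    def test_jukes_cantor_closed_form(self):
        # p = 0.1 -> d = -0.75 ln(1 - 0.4/3)
        seq = "A" * 100
        other = "C" * 10 + "A" * 90
        dm = demarc.corrected_distances({"a": seq, "b": other})
        assert dm["a", "b"] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3),
                                             abs=1e-12)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            demarc.corrected_distances({"a": "A" * 100, "b": "C" * 100})

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), size=60))
        seqs = {f"s{i}": _mutate(base, rng.choice(60, size=6, replace=False))
                for i in range(10)}
        dm = demarc.corrected_distances(seqs)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)


class TestNJTree:
    def test_two_taxa_cherry(self):
        dm = DistanceMatrix([[0, 0.2], [0.2, 0]], ["a", "b"])
        tree = demarc.nj_tree(dm)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"a": pytest.approx(0.1), "b": pytest.approx(0.1)}

    def test_four_taxon_additive_matrix_recovers_topology(self):
        # tree ((a:1,b:2):1,(c:1.5,d:1)); oracle: four-point condition
        labels = ["a", "b", "c", "d"]
        D = {("a", "b"): 3, ("a", "c"): 3.5, ("a", "d"): 3,
             ("b", "c"): 4.5, ("b", "d"): 4, ("c", "d"): 2.5}
        mat = np.zeros((4, 4))
        for (x, y), v in D.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        sums = {"ab|cd": D[("a", "b")] + D[("c", "d")],
                "ac|bd": D[("a", "c")] + D[("b", "d")],
                "ad|bc": D[("a", "d")] + D[("b", "c")]}
        assert min(sums, key=sums.get) == "ab|cd"  # oracle split
        tree = demarc.nj_tree(DistanceMatrix(mat, labels))
        clades = {frozenset(t.name for t in n.tips())
                  for n in tree.non_tips(include_self=True)}
        assert frozenset({"a", "b"}) in clades or frozenset({"c", "d"}) in clades

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), size=80))
        seqs = {f"s{i}": _mutate(base, rng.choice(80, size=8, replace=False))
                for i in range(6)}
        dm = demarc.corrected_distances(seqs)
        t1 = demarc.nj_tree(dm)
        shuffled = dm.filter(list(reversed(dm.ids)))
        t2 = demarc.nj_tree(shuffled)
        assert t1.compare_rfd(t2) == 0

    def test_single_taxon_raises(self):
        with pytest.raises(ValueError):
            demarc.nj_tree(DistanceMatrix([[0.0]], ["a"]))


class TestBinCurve:
    def test_identical_set_is_one_bin_below_strict(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        curve = demarc.bin_curve(dm)
        assert all(b == 1 for b in curve.bins)

    def test_two_separated_clusters(self):
        # within 0.001, between 0.05: 2 bins at 0.99, 1 bin at 0.94
        D = np.full((4, 4), 0.05)
        D[:2, :2] = 0.001
        D[2:, 2:] = 0.001
        np.fill_diagonal(D, 0)
        dm = DistanceMatrix(D, list("abcd"))
        curve = demarc.bin_curve(dm, criteria=[0.99, 0.94])
        assert curve.bins == (2, 1)

    def test_monotone_along_ladder(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = rng.integers(2, 12)
            M = np.abs(rng.normal(scale=0.02, size=(n, n)))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            curve = demarc.bin_curve(DistanceMatrix(M, [f"x{i}"
                                                        for i in range(n)]))
            assert all(a >= b for a, b in zip(curve.bins, curve.bins[1:]))

    def test_strictest_criterion_counts_distinct_variants(self):
        seqs = {"a": "AAAA", "b": "AAAT", "c": "AAAT"[:3] + "T"}
        dm = demarc.corrected_distances(seqs)
        curve = demarc.bin_curve(dm, criteria=[1.0])
        assert curve.bins[0] == 2  # b and c identical


class TestSimulateSES:
    def test_single_lineage_is_one_bin(self):
        out = demarc.simulate_ses(demarc.SESParams(0.1, 1.0, 1, 1.0), 1,
                                  324, seed=0)
        assert all(b == 1 for b in out.curve.bins)

    def test_strong_periodic_selection_collapses_ecotypes(self):
        # sigma -> infinity: within-ecotype diversity vanishes, so the
        # loosest criteria see ~npop clusters
        params = demarc.SESParams(omega=0.01, sigma=500.0, npop=3, drift=0.0)
        loose = [demarc.simulate_ses(params, 9, 324, seed=i).curve.bins[-1]
                 for i in range(100)]
        assert np.mean(loose) == pytest.approx(3, abs=0.3)

    def test_neutral_limit_matches_msprime_coalescent(self):
        """omega=0, npop=1, drift-only reduces to the neutral Kingman
        coalescent; mean bin counts must match msprime's."""
        msprime = pytest.importorskip("msprime")
        n, L, drift, reps = 8, 324, 1.0, 300
        ladder = demarc.identity_ladder()
        ours = np.zeros(len(ladder))
        params = demarc.SESParams(0.0, 0.0, 1, drift)
        for i in range(reps):
            ours += demarc.simulate_ses(params, n, L, seed=i).curve.bins
        ours /= reps
        theirs = np.zeros(len(ladder))
        for i in range(reps):
            ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                                      sequence_length=L, random_seed=i + 1)
            mts = msprime.sim_mutations(
                ts, rate=1.0 / (drift * L), random_seed=i + 1,
                discrete_genome=False)
            G = mts.genotype_matrix()
            D = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    D[a, b] = D[b, a] = (G[:, a] != G[:, b]).sum() / L
            theirs += demarc._bins_from_square(D, [1 - c for c in ladder])
        theirs /= reps
        assert np.abs(ours - theirs).max() < 0.35

    def test_event_cap_raises(self):
        params = demarc.SESParams(omega=0.0, sigma=0.0, npop=1, drift=0.0)
        with pytest.raises(demarc.FitError):
            demarc.simulate_ses(params, 4, 324, seed=0)

    def test_seeded_reproducibility(self):
        params = demarc.SESParams(0.02, 1.0, 3, 1.0)
        a = demarc.simulate_ses(params, 9, 324, seed=123)
        b = demarc.simulate_ses(params, 9, 324, seed=123)
        assert a.curve.bins == b.curve.bins
        assert np.array_equal(a.distances, b.distances)


class TestFitSES:
    def test_scale_symmetry_leaves_npop_unchanged(self):
        _, _, _, seqs = planted_ecotype_sequences(5, n_ecotypes=2, n_hfs=3)
        dm = demarc.corrected_distances(seqs)
        curve = demarc.bin_curve(dm)
        fit1 = demarc.fit_ses(curve, len(seqs), seed=9, dm=dm)

        scaled_dm = DistanceMatrix(dm.data * 2.0, dm.ids)
        scaled_ladder = tuple(1 - 2 * (1 - c) for c in curve.criteria)
        scaled_curve = demarc.bin_curve(scaled_dm, criteria=scaled_ladder)
        assert scaled_curve.bins == curve.bins
        cfg = demarc.FitConfig(seq_len=162)
        fit2 = demarc.fit_ses(scaled_curve, len(seqs), seed=9, dm=scaled_dm,
                              config=cfg)
        assert fit1.ml.npop == fit2.ml.npop

    def test_parameter_recovery_from_simulated_truth(self):
        """Median ML estimates over seeded trials recover the generating
        parameters (sigma within 3x; npop exactly in most trials; omega is
        only weakly identified by bin counts once splits exceed the ladder,
        so it gets a 10x band)."""
        true = demarc.SESParams(omega=0.02, sigma=1.0, npop=3, drift=1.0)
        oms, sgs, nps = [], [], []
        for trial in range(20):
            sim = demarc.simulate_ses(true, 9, 324, seed=3000 + trial)
            dm = DistanceMatrix(sim.distances,
                                [f"s{i}" for i in range(9)])
            fit = demarc.fit_ses(sim.curve, 9, seed=trial, dm=dm)
            oms.append(fit.ml.omega)
            sgs.append(fit.ml.sigma)
            nps.append(fit.ml.npop)
        assert sum(n == true.npop for n in nps) >= 12
        assert true.sigma / 3 <= np.median(sgs) <= true.sigma * 3
        assert true.omega / 10 <= np.median(oms) <= true.omega * 10

    def test_zero_likelihood_raises(self):
        curve = demarc.BinCurve((1.0, 0.99), (5, 5))
        cfg = demarc.FitConfig(n_replicates=5, npop_max=1,
                               sigma_grid=(1000.0,), drift_grid=(1000.0,))
        with pytest.raises(demarc.FitError, match="widen"):
            demarc.fit_ses(curve, 5, seed=0, config=cfg)


class TestDemarcate:
    def test_star_clade_is_single_pe_in_both_modes(self):
        _, _, _, seqs = planted_ecotype_sequences(6, n_ecotypes=1, n_hfs=4)
        dm = demarc.corrected_distances(seqs)
        tree = demarc.nj_tree(dm)
        cons, fine = demarc.demarcate_both(tree, seqs, seed=6)
        assert cons.n_pes() == 1 and fine.n_pes() == 1

    def test_three_planted_ecotypes_recovered_and_nested(self):
        _, _, _, seqs = planted_ecotype_sequences(7, n_ecotypes=3, n_hfs=3)
        dm = demarc.corrected_distances(seqs)
        tree = demarc.nj_tree(dm)
        cons, fine = demarc.demarcate_both(tree, seqs, seed=7)
        assert fine.n_pes() == 3
        assert cons.n_pes() <= 3
        for leaves in fine.clades.values():
            assert len({l.split("_")[0] for l in leaves}) == 1
        for fl in fine.clades.values():
            assert sum(set(fl) <= set(cl)
                       for cl in cons.clades.values()) == 1

    def test_partition_total_and_disjoint(self):
        _, _, _, seqs = planted_ecotype_sequences(8, n_ecotypes=2, n_hfs=3)
        dm = demarc.corrected_distances(seqs)
        tree = demarc.nj_tree(dm)
        part = demarc.demarcate(tree, seqs, demarc.FINE, seed=8)
        all_leaves = [t.name for t in tree.tips()]
        part.check(all_leaves)  # raises on violation
        assert set(part.assignment) == set(all_leaves)

    def test_demarcation_is_seed_deterministic(self):
        _, _, _, seqs = planted_ecotype_sequences(9, n_ecotypes=2, n_hfs=3)
        dm = demarc.corrected_distances(seqs)
        tree = demarc.nj_tree(dm)
        p1 = demarc.demarcate(tree, seqs, demarc.FINE, seed=4)
        p2 = demarc.demarcate(tree, seqs, demarc.FINE, seed=4)
        assert p1.assignment == p2.assignment
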