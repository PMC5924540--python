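"""Serial-coalescent simulator against closed forms and msprime."""

import numpy as np
import pytest

from mitopop.alignment import variable_sites
from mitopop.simulate import (
    ANCIENT_TIPS,
    DemographicModel,
    inject_missing,
    make_study_fixture,
    simulate_alignment,
    simulate_genealogy,
    study_demography,
)


def constant_demog(ne, g=1.0):
    return DemographicModel(epochs=[(0.0, ne)], generation_time=g)


class TestDemographicModel:
    def test_epoch_lookup(self):
        d = DemographicModel(epochs=[(0, 100), (1000, 50), (5000, 200)])
        assert d.size_at(0) == 100
        assert d.size_at(999.9) == 100
        assert d.size_at(1000) == 50
        assert d.size_at(10000) == 200

    @pytest.mark.parametrize("epochs", [
        [], [(100, 50)], [(0, 50), (0, 60)], [(0, -1)], [(0, 0)],
    ])
    def test_invalid_epochs_rejected(self, epochs):
        with pytest.raises(ValueError):
            DemographicModel(epochs=epochs)

    def test_json_roundtrip(self):
        d = study_demography()
        back = DemographicModel.from_json(d.to_json())
        assert back.epochs == d.epochs
        assert back.generation_time == d.generation_time


class TestSimulateGenealogy:
    def test_rejects_fewer_than_two_tips(self):
        with pytest.raises(ValueError):
            simulate_genealogy(constant_demog(100), [("a", 0.0)], seed=1)

    def test_deterministic_given_seed(self):
        tips = [(f"t{i}", 0.0) for i in range(6)]
        a = simulate_genealogy(constant_demog(500), tips, seed=9)
        b = simulate_genealogy(constant_demog(500), tips, seed=9)
        assert a.to_newick() == b.to_newick()

    def test_node_time_ordering_many_seeds(self):
        demog = study_demography()
        tips = [("a", 0.0), ("b", 0.0), ("c", 5025.0), ("d", 8470.0), ("e", 0.0)]
        for seed in range(300):
            gen = simulate_genealogy(demog, tips, seed=seed)
            for node in gen.internal_nodes():
                assert all(node.time > c.time for c in node.children)
            assert gen.tip_ages() == {"a": 0, "b": 0, "c": 5025.0, "d": 8470.0, "e": 0}

    def test_tmrca_bounded_by_oldest_tip(self):
        demog = constant_demog(200, g=1.0)
        for seed in range(200):
            gen = simulate_genealogy(demog, [("y", 0.0), ("o", 500.0)], seed=seed)
            assert gen.tmrca >= 500.0

    def test_pairwise_tmrca_matches_closed_form(self):
        """E[T2] = N generations for the haploid coalescent."""
        N = 1000.0
        demog = constant_demog(N, g=1.0)
        vals = np.array([
            simulate_genealogy(demog, [("a", 0.0), ("b", 0.0)], seed=s).tmrca
            for s in range(3000)
        ])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - N) < 3 * se

    def test_total_tree_length_matches_closed_form(self):
        """E[L] = 2N * sum_{i=1}^{n-1} 1/i for n contemporaneous tips."""
        N, n = 400.0, 10
        demog = constant_demog(N, g=1.0)
        tips = [(f"t{i}", 0.0) for i in range(n)]
        vals = np.array([
            simulate_genealogy(demog, tips, seed=s).total_branch_length()
            for s in range(2000)
        ])
        expected = 2 * N * sum(1 / i for i in range(1, n))
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_piecewise_epoch_boundary_respected(self):
        """With a huge recent epoch and a tiny old one, pairwise TMRCA
        concentrates just beyond the boundary."""
        demog = DemographicModel(epochs=[(0, 1e8), (100.0, 1.0)], generation_time=1.0)
        vals = [
            simulate_genealogy(demog, [("a", 0.0), ("b", 0.0)], seed=s).tmrca
            for s in range(300)
        ]
        # rate ~0 before 100, rate 1/2 per year after: nearly all events in (100, 130)
        assert np.mean([100 < v < 130 for v in vals]) > 0.95

    def test_msprime_tmrca_distribution_agreement(self):
        """Two-sample KS against an independent coalescent simulator."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import ks_2samp

        N, n, reps = 800.0, 5, 2000
        demog = constant_demog(N, g=1.0)
        tips = [(f"t{i}", 0.0) for i in range(n)]
        ours = np.array([
            simulate_genealogy(demog, tips, seed=s).tmrca for s in range(reps)
        ])
        theirs = np.empty(reps)
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n, population_size=N, ploidy=1,
                num_replicates=reps, random_seed=12345,
            )
        ):
            theirs[i] = ts.max_root_time
        assert ks_2samp(ours, theirs).pvalue > 0.01


class TestSimulateAlignment:
    def test_rejects_bad_inputs(self):
        gen = simulate_genealogy(constant_demog(100), [("a", 0), ("b", 0)], seed=1)
        with pytest.raises(ValueError):
            simulate_alignment(gen, mu=0.0, length=100)
        with pytest.raises(ValueError):
            simulate_alignment(gen, mu=1e-8, length=0)
        subs_tree = gen.scaled(1e-8, units="subs")
        with pytest.raises(ValueError):
            simulate_alignment(subs_tree, mu=1e-8, length=100)

    def test_tiny_rate_gives_monomorphic_alignments(self):
        gen = simulate_genealogy(constant_demog(1000), [("a", 0), ("b", 0)], seed=3)
        mono = 0
        for seed in range(100):
            aln = simulate_alignment(gen, mu=1e-12, length=200, seed=seed)
            mono += len(variable_sites(aln)) == 0
        assert mono >= 99

    def test_pairwise_differences_match_theta(self):
        """E[pi] = theta = 2*N*mu per site in the small-theta regime."""
        N, mu, L = 500.0, 1e-5, 1000
        demog = constant_demog(N, g=1.0)
        diffs = np.empty(1500)
        for s in range(len(diffs)):
            gen = simulate_genealogy(demog, [("a", 0), ("b", 0)], seed=s)
            aln = simulate_alignment(gen, mu=mu, length=L, seed=s + 10**6)
            diffs[s] = (aln.matrix[0] != aln.matrix[1]).sum()
        expected = 2 * N * mu * L
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - expected) < 3 * se

    def test_segregating_sites_match_watterson(self):
        """E[S] = theta*L * sum_{i<n} 1/i for n contemporaneous tips."""
        N, mu, L, n = 300.0, 1e-5, 1000, 10
        demog = constant_demog(N, g=1.0)
        tips = [(f"t{i}", 0.0) for i in range(n)]
        counts = np.empty(1200)
        for s in range(len(counts)):
            gen = simulate_genealogy(demog, tips, seed=s)
            aln = simulate_alignment(gen, mu=mu, length=L, seed=s + 10**6)
            counts[s] = len(variable_sites(aln))
        expected = 2 * N * mu * L * sum(1 / i for i in range(1, n))
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_hky_model_runs_and_respects_frequencies(self):
        gen = simulate_genealogy(constant_demog(100, g=1.0),
                                 [(f"t{i}", 0.0) for i in range(4)], seed=5)
        aln = simulate_alignment(
            gen, mu=1e-4, length=4000, model="HKY", kappa=4.0,
            base_freqs=[0.4, 0.3, 0.2, 0.1], seed=11,
        )
        freq_a = (aln.matrix == "A").mean()
        assert 0.3 < freq_a < 0.5  # equilibrium ~0.4


class TestInjectMissing:
    @staticmethod
    def _aln():
        gen = simulate_genealogy(constant_demog(100, g=1.0),
                                 [("a", 0), ("b", 0), ("c", 0)], seed=1)
        return simulate_alignment(gen, mu=1e-5, length=1000, seed=2)

    def test_fraction_zero_identity(self):
        aln = self._aln()
        out = inject_missing(aln, ["a"], fraction=0.0, seed=4)
        assert np.array_equal(out.matrix, aln.matrix)

    def test_fraction_one_all_missing(self):
        out = inject_missing(self._aln(), ["b"], fraction=1.0, seed=4)
        assert np.all(out.matrix[1] == "N")
        assert not np.any(out.matrix[0] == "N")

    def test_block_granularity_bound(self):
        out = inject_missing(self._aln(), ["a"], fraction=0.2, block_length=50, seed=8)
        n_missing = int((out.matrix[0] == "N").sum())
        assert 200 <= n_missing <= 250  # >= fraction, overshoot < one block

    def test_unknown_target_rejected(self):
        with pytest.raises(KeyError):
            inject_missing(self._aln(), ["zz"], fraction=0.5)


class TestStudyFixture:
    def test_bundle_byte_identical_across_reruns(self, tmp_path):
        p1 = make_study_fixture(seed=5, scale=0.05).write(tmp_path / "a")
        p2 = make_study_fixture(seed=5, scale=0.05).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_tip_dates_exactly_two_ancient(self, tmp_path, small_fixture):
        paths = small_fixture.write(tmp_path)
        ages = {}
        for line in paths["dates"].read_text().splitlines():
            sid, age = line.split("\t")
            ages[sid] = float(age)
        nonzero = sorted(a for a in ages.values() if a > 0)
        assert nonzero == [5025.0, 8470.0]
        assert len(ages) == 54

    def test_true_model_roundtrips_through_reader(self, tmp_path, small_fixture):
        paths = small_fixture.write(tmp_path)
        back = DemographicModel.from_json(paths["demography"].read_text())
        assert back.epochs == small_fixture.demography.epochs

    def test_demography_shape(self):
        d = study_demography()
        n_anc = d.epochs[-1][1]
        assert d.epochs[-1][0] == 6000.0
        # at least 4 decline steps between 2000 and 6000 BP
        decline = [(s, n) for s, n in d.epochs if 2000 <= s < 6000]
        assert len(decline) >= 4
        assert min(n for _, n in d.epochs) < n_anc / 2
        # recent sizes recover toward the ancestral level
        assert d.epochs[0][1] > d.size_at(2500)

    def test_scale_shrinks_alignment(self):
        fx = make_study_fixture(seed=3, scale=0.1)
        assert fx.alignment.n_sites == round(0.1 * 4054) + round(0.1 * 655)
        assert fx.alignment.partitions["coding"][1] == round(0.1 * 4054)
        with pytest.raises(ValueError):
            make_study_fixture(seed=3, scale=0.0)

    def test_genealogy_written_in_years(self, tmp_path, small_fixture):
        from mitopop.genealogy import Genealogy

        paths = small_fixture.write(tmp_path)
        ages = {label: age for label, age in ANCIENT_TIPS}
        back = Genealogy.from_newick(str(paths["genealogy"]),
                                     tip_ages=ages)
        assert back.units == "years"
        assert back.tmrca == pytest.approx(small_fixture.genealogy.tmrca, rel=1e-6)
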