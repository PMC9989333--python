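import numpy as np
import pytest
from scipy import stats

from mutspectra.demography import Epoch, Population, PopulationModel, SplitEvent, build_basic_model
from mutspectra.mutation_model import (
    MutationType,
    apply_fold_shift,
    build_uniform_matrix,
    normalize_overall_rate,
    type_index,
)
from mutspectra.sequence import generate_sequence
from mutspectra.simulator import (
    CoalescenceError,
    Genealogy,
    forward_wf_oracle,
    place_mutations,
    simulate_dataset,
    simulate_genealogy,
)


def harmonic(n):
    return sum(1.0 / i for i in range(1, n))


class TestSimulateGenealogy:
    def test_single_lineage_is_an_error(self, single_pop_model):
        with pytest.raises(ValueError):
            simulate_genealogy(single_pop_model, {"p": 1}, seed=0)

    def test_unknown_population(self, single_pop_model):
        with pytest.raises(KeyError):
            simulate_genealogy(single_pop_model, {"nope": 2}, seed=0)

    def test_disconnected_populations_raise(self):
        model = PopulationModel(
            populations=(Population("a", (Epoch(0.0, 100),)), Population("b", (Epoch(0.0, 100),))),
        )
        # validate() flags the two roots before simulation begins
        with pytest.raises((CoalescenceError, ValueError)):
            simulate_genealogy(model, {"a": 2, "b": 2}, seed=0)

    def test_mean_t2_matches_closed_form(self, single_pop_model):
        """E[T2] = 2N generations for a diploid population of N."""
        R = 4000
        seeds = np.random.SeedSequence(31).spawn(R)
        t = np.array([simulate_genealogy(single_pop_model, {"p": 2}, seed=s).tmrca for s in seeds])
        se = t.std() / np.sqrt(R)
        assert abs(t.mean() - 20_000) < 3 * se

    def test_no_cross_population_coalescence_before_split(self, constant_model):
        g = simulate_genealogy(constant_model, {"ancestral": 5, "derived": 5}, seed=7)
        kids = g.children()
        split_t = 4000.0
        for node in range(g.n_leaves, g.n_nodes):
            leaves = g.descendant_leaves(node, kids)
            pops = {g.leaf_population[l] for l in leaves}
            if len(pops) > 1:
                assert g.time[node] > split_t

    def test_growth_epoch_shortens_recent_coalescence(self):
        """A population growing toward the present (large now, small in the
        past) coalesces faster than a constant one of the present size."""
        grown = PopulationModel(
            populations=(Population("p", (Epoch(0.0, 50_000, growth_rate=0.002),)),)
        )
        flat = PopulationModel(populations=(Population("p", (Epoch(0.0, 50_000),)),))
        R = 400
        seeds = np.random.SeedSequence(5).spawn(R)
        t_g = np.mean([simulate_genealogy(grown, {"p": 2}, seed=s).tmrca for s in seeds])
        t_f = np.mean([simulate_genealogy(flat, {"p": 2}, seed=s).tmrca for s in seeds])
        assert t_g < t_f

    def test_matches_msprime_on_decline_model(self):
        """Cross-validation against msprime as an independent structured
        coalescent implementation (three-population formulation so both
        sampled populations are active from the present)."""
        msprime = pytest.importorskip("msprime")
        model = build_basic_model("decline")
        R = 800
        seeds = np.random.SeedSequence(17).spawn(R)
        mine = np.array(
            [simulate_genealogy(model, {"ancestral": 5, "derived": 5}, seed=s).tmrca for s in seeds]
        )
        dem = msprime.Demography()
        dem.add_population(name="anc", initial_size=10_000)
        dem.add_population(name="pA", initial_size=10_000)
        dem.add_population(name="pB", initial_size=1_000)
        dem.add_population_split(time=4000, derived=["pA", "pB"], ancestral="anc")
        theirs = np.array(
            [
                msprime.sim_ancestry(
                    samples={"pA": 5, "pB": 5}, demography=dem, ploidy=2,
                    random_seed=int(i) + 1,
                ).max_root_time
                for i in range(R)
            ]
        )
        se = np.sqrt(mine.var() / R + theirs.var() / R)
        assert abs(mine.mean() - theirs.mean()) < 3 * se


class TestPlaceMutations:
    def test_zero_branch_lengths_give_empty_table(self, uniform_seq, norm_matrix):
        g = Genealogy(
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, 0.0]),
            leaf_population=["p", "p"],
            sample_index={"p": np.array([0, 1], dtype=np.int32)},
            segments=[[(0.0, 0.0, "p")], [(0.0, 0.0, "p")], []],
        )
        table = place_mutations(g, uniform_seq, norm_matrix, seed=0)
        assert len(table) == 0

    def test_unnormalized_matrix_rejected(self, single_pop_model, uniform_seq):
        g = simulate_genealogy(single_pop_model, {"p": 4}, seed=1)
        with pytest.raises(ValueError, match="normalized"):
            place_mutations(g, uniform_seq, build_uniform_matrix(), seed=0)

    def test_watterson_expected_segregating_sites(self, single_pop_model, uniform_seq, norm_matrix):
        """Mean segregating-site count matches 4*N*mu*L*sum(1/i)."""
        R, n = 80, 20
        seeds = np.random.SeedSequence(23).spawn(R)
        S = []
        for s in seeds:
            tab = simulate_dataset(single_pop_model, uniform_seq, norm_matrix, {"p": n}, 10_000, seed=s)
            S.append(len(tab))
        S = np.asarray(S, dtype=float)
        expected = 4 * 10_000 * 1e-8 * len(uniform_seq) * harmonic(n)
        assert abs(S.mean() - expected) < 3 * S.std() / np.sqrt(R)

    def test_positions_unique_and_interior(self, two_pop_table, uniform_seq):
        assert len(np.unique(two_pop_table.positions)) == len(two_pop_table)
        assert two_pop_table.positions.min() >= 1
        assert two_pop_table.positions.max() <= len(uniform_seq) - 2

    def test_folded_sfs_matches_neutral_expectation(self, single_pop_model, uniform_seq, norm_matrix):
        """Folded site-frequency spectrum proportional to 1/i + 1/(n-i)."""
        n = 10
        counts = []
        seeds = np.random.SeedSequence(29).spawn(120)
        for s in seeds:
            tab = simulate_dataset(single_pop_model, uniform_seq, norm_matrix, {"p": n}, 10_000, seed=s)
            c = tab.derived_count("p")
            counts.append(np.minimum(c, n - c))
        folded = np.bincount(np.concatenate(counts), minlength=n // 2 + 1)[1 : n // 2 + 1]
        expect = np.array(
            [(1 / i + 1 / (n - i)) / (1 + (i == n - i)) for i in range(1, n // 2 + 1)]
        )
        expect = expect / expect.sum() * folded.sum()
        chi2 = np.sum((folded - expect) ** 2 / expect)
        assert chi2 < stats.chi2.ppf(0.999, df=len(expect) - 1)

    def test_fold_shift_elevates_type_fraction(self, single_pop_model, uniform_seq):
        """2x TCC>T matrix roughly doubles that type's share among variants."""
        shifted = normalize_overall_rate(
            apply_fold_shift(build_uniform_matrix(), MutationType("TCC", "T"), 2.0),
            uniform_seq, 1e-8,
        )
        idx = type_index(MutationType("TCC", "T"))
        hits = total = 0
        for s in np.random.SeedSequence(37).spawn(60):
            tab = simulate_dataset(single_pop_model, uniform_seq, shifted, {"p": 20}, 10_000, seed=s)
            ti = tab.type_indices()
            hits += int(np.sum(ti == idx))
            total += len(ti)
        frac = hits / total
        expected = 2 / 193  # one doubled entry among 192 equal ones
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(frac - expected) < 4 * se

    def test_per_population_matrices_shift_only_one_population(self, uniform_seq):
        """A shift restricted to the derived population leaves the ancestral
        population's spectrum at baseline."""
        model = build_basic_model("constant")
        base = normalize_overall_rate(build_uniform_matrix(), uniform_seq, 1e-8)
        shifted = normalize_overall_rate(
            apply_fold_shift(build_uniform_matrix(), MutationType("TCC", "T"), 8.0),
            uniform_seq, 1e-8,
        )
        idx = type_index(MutationType("TCC", "T"))
        counts = {"ancestral": [0, 0], "derived": [0, 0]}
        for s in np.random.SeedSequence(41).spawn(40):
            tab = simulate_dataset(
                model, uniform_seq, {"ancestral": base, "derived": shifted},
                {"ancestral": 20, "derived": 20}, 10_000, seed=s,
            )
            from mutspectra.spectra import private_segregating

            for pop in counts:
                priv = private_segregating(tab, pop)
                ti = priv.type_indices()
                counts[pop][0] += int(np.sum(ti == idx))
                counts[pop][1] += len(ti)
        frac_anc = counts["ancestral"][0] / counts["ancestral"][1]
        frac_der = counts["derived"][0] / counts["derived"][1]
        assert frac_der > 3 * frac_anc
        se = np.sqrt((1 / 192) * (191 / 192) / counts["ancestral"][1])
        assert abs(frac_anc - 1 / 192) < 4 * se


class TestSimulateDataset:
    def test_seeded_run_reproducible(self, constant_model, uniform_seq, norm_matrix):
        a = simulate_dataset(constant_model, uniform_seq, norm_matrix, {"ancestral": 10, "derived": 10}, 10_000, seed=5)
        b = simulate_dataset(constant_model, uniform_seq, norm_matrix, {"ancestral": 10, "derived": 10}, 10_000, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.derived_codes, b.derived_codes)
        assert (a.genotypes != b.genotypes).nnz == 0

    def test_window_length_validation(self, constant_model, uniform_seq, norm_matrix):
        with pytest.raises(ValueError):
            simulate_dataset(constant_model, uniform_seq, norm_matrix, {"ancestral": 4}, len(uniform_seq) + 1, seed=0)

    def test_variant_count_scales_with_length(self, single_pop_model, norm_matrix):
        """Doubling the sequence roughly doubles the expected variant count
        (linearity of the Watterson expectation)."""
        R = 40
        means = {}
        for L in (50_000, 100_000):
            seq = generate_sequence(L, (0.25,) * 4, seed=47)
            m = normalize_overall_rate(build_uniform_matrix(), seq, 1e-8)
            S = [
                len(simulate_dataset(single_pop_model, seq, m, {"p": 10}, 10_000, seed=s))
                for s in np.random.SeedSequence(L).spawn(R)
            ]
            means[L] = (np.mean(S), np.std(S) / np.sqrt(R))
        ratio = means[100_000][0] / means[50_000][0]
        se = ratio * np.sqrt(
            (means[100_000][1] / means[100_000][0]) ** 2 + (means[50_000][1] / means[50_000][0]) ** 2
        )
        assert abs(ratio - 2.0) < 3 * se


@pytest.fixture(scope="module")
def tiny():
    model = PopulationModel(populations=(Population("p", (Epoch(0.0, 50),)),))
    seq = generate_sequence(1002, (0.25,) * 4, seed=51)
    matrix = normalize_overall_rate(build_uniform_matrix(), seq, 1e-5)
    return model, seq, matrix


class TestForwardWFOracle:
    def test_zero_rate_gives_empty_table(self, tiny):
        model, seq, _ = tiny
        zero = normalize_overall_rate(build_uniform_matrix(), seq, 0.0)
        assert len(forward_wf_oracle(model, {"p": 10}, seq, zero, seed=1)) == 0

    def test_seed_determinism(self, tiny):
        model, seq, matrix = tiny
        a = forward_wf_oracle(model, {"p": 10}, seq, matrix, seed=3)
        b = forward_wf_oracle(model, {"p": 10}, seq, matrix, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert (a.genotypes != b.genotypes).nnz == 0

    def test_size_guard(self, tiny):
        _, seq, matrix = tiny
        big = PopulationModel(populations=(Population("p", (Epoch(0.0, 1000),)),))
        with pytest.raises(ValueError, match="guard"):
            forward_wf_oracle(big, {"p": 10}, seq, matrix, seed=0)

    def test_engine_agrees_with_oracle(self, tiny):
        """Backward engine vs forward Wright-Fisher: mean segregating sites
        agree within 3 standard errors at N=50."""
        model, seq, matrix = tiny
        R = 250
        S_wf = np.array(
            [len(forward_wf_oracle(model, {"p": 10}, seq, matrix, seed=s))
             for s in np.random.SeedSequence(61).spawn(R)], dtype=float,
        )
        S_co = np.array(
            [
                len(place_mutations(simulate_genealogy(model, {"p": 10}, seed=s), seq, matrix, seed=s))
                for s in np.random.SeedSequence(67).spawn(R)
            ],
            dtype=float,
        )
        se = np.sqrt(S_wf.var() / R + S_co.var() / R)
        assert abs(S_wf.mean() - S_co.mean()) < 3 * se

    def test_engine_agrees_with_oracle_split_model(self):
        """Same agreement on a two-population split model, per population."""
        model = PopulationModel(
            populations=(Population("a", (Epoch(0.0, 60),)), Population("b", (Epoch(0.0, 30),))),
            splits=(SplitEvent(120.0, "b", "a"),),
        )
        seq = generate_sequence(802, (0.25,) * 4, seed=71)
        matrix = normalize_overall_rate(build_uniform_matrix(), seq, 2e-5)
        R = 200
        S_wf = {"a": [], "b": []}
        S_co = {"a": [], "b": []}
        for s in np.random.SeedSequence(73).spawn(R):
            t = forward_wf_oracle(model, {"a": 8, "b": 8}, seq, matrix, seed=s)
            for p in S_wf:
                c = t.derived_count(p)
                S_wf[p].append(int(np.sum((c > 0) & (c < 8))))
        for s in np.random.SeedSequence(79).spawn(R):
            g = simulate_genealogy(model, {"a": 8, "b": 8}, seed=s)
            t = place_mutations(g, seq, matrix, seed=s)
            for p in S_co:
                c = t.derived_count(p)
                S_co[p].append(int(np.sum((c > 0) & (c < 8))))
        for p in ("a", "b"):
            wf, co = np.asarray(S_wf[p], float), np.asarray(S_co[p], float)
            se = np.sqrt(wf.var() / R + co.var() / R)
            assert abs(wf.mean() - co.mean()) < 3 * se, p

    def test_migration_not_supported(self, tiny):
        from mutspectra.demography import MigrationRate, SplitEvent

        model = PopulationModel(
            populations=(Population("a", (Epoch(0.0, 50),)), Population("b", (Epoch(0.0, 50),))),
            splits=(SplitEvent(100.0, "b", "a"),),
            migrations=(MigrationRate("a", "b", 0.01),),
        )
        _, seq, matrix = tiny
        with pytest.raises(NotImplementedError):
            forward_wf_oracle(model, {"a": 4, "b": 4}, seq, matrix, seed=0)
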