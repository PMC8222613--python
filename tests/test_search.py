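import numpy as np
import pytest

from dcmsearch.estimation import GaussianDensity, PriorSpec, PosteriorEstimate
from dcmsearch.model_space import annotate_table
from dcmsearch.search import (
    BMROracle,
    SearchConfig,
    TableOracle,
    characterize,
    ga,
    ges,
    ghd,
    posthoc_greedy,
    run_search,
)
from dcmsearch.synthetic import LandscapeSpec, generate_landscape

from conftest import make_spec


@pytest.fixture(scope="module")
def oracle12(landscape12):
    return TableOracle(landscape12)


def _cfg(**kw):
    return SearchConfig(**kw)


class TestOracle:
    def test_cache_does_not_increment_counter(self, landscape12):
        oracle = TableOracle(landscape12)
        bv = landscape12.bitvectors[5]
        oracle.evaluate(bv)
        oracle.evaluate(bv)
        oracle.evaluate(landscape12.bitvectors[9])
        assert oracle.n_evaluated == 2

    def test_unknown_model_rejected(self, landscape12, spec9):
        oracle = TableOracle(landscape12)
        with pytest.raises(KeyError):
            oracle.evaluate("not-a-bitvector")


class TestGES:
    def test_finds_planted_optimum_from_random_inits(self, landscape12):
        best = landscape12.best_bitvector
        for seed in range(20):
            oracle = TableOracle(landscape12)
            res = ges(oracle, _cfg(seed=seed))
            assert res.final_bitvector == best
            assert res.dfe == pytest.approx(0.0)

    def test_init_at_optimum_evaluates_only_neighborhood(self, landscape12):
        oracle = TableOracle(landscape12)
        best = landscape12.best_bitvector
        res = ges(oracle, _cfg(init="given", init_bitvector=best))
        assert res.final_bitvector == best
        n_neighbors = sum(
            1 for b in range(len(best))
            if oracle.space.is_valid(best[:b] + ("01"[best[b] == "0"])
                                     + best[b + 1:]))
        assert res.n_estimated == 1 + n_neighbors

    def test_rugged_landscape_reaches_a_local_peak(self, spec12):
        table = generate_landscape(LandscapeSpec(
            constraints=spec12, kind="rugged", seed=5,
            n_epistatic_pairs=4))
        fe_best = table.fe(table.best_bitvector)
        for seed in (0, 1, 2):
            oracle = TableOracle(table)
            res = ges(oracle, _cfg(seed=seed))
            assert res.final_fe <= fe_best + 1e-12
            winners = [t["fe"] for t in res.trajectory]
            assert all(b >= a for a, b in zip(winners, winners[1:]))

    def test_deterministic_given_init(self, landscape12):
        r1 = ges(TableOracle(landscape12), _cfg(seed=3))
        r2 = ges(TableOracle(landscape12), _cfg(seed=3))
        assert r1.final_bitvector == r2.final_bitvector
        assert r1.trajectory == r2.trajectory

    def test_returned_fe_is_max_over_evaluated(self, landscape12):
        oracle = TableOracle(landscape12)
        res = ges(oracle, _cfg(seed=11))
        fes = [oracle.evaluate(bv).fe
               for t in res.trajectory for bv in t["evaluated"]]
        assert res.final_fe == max(fes)


class TestGHD:
    def test_neighborhood_size_bounded_by_free_bits(self, landscape12):
        oracle = TableOracle(landscape12)
        res = ghd(oracle, _cfg(seed=0))
        nb = oracle.space.n_bits
        for t in res.trajectory[1:]:
            assert len(t["evaluated"]) <= nb

    def test_finds_planted_optimum_from_random_inits(self, landscape12):
        best = landscape12.best_bitvector
        for seed in range(20):
            res = ghd(TableOracle(landscape12), _cfg(seed=seed))
            assert res.final_bitvector == best

    def test_escapes_ges_phase_trap(self, spec9):
        # a landscape where improving requires mixing an addition with
        # removals in one sweep: GHD's mixed neighborhood still climbs
        table = generate_landscape(LandscapeSpec(
            constraints=spec9, kind="rugged", seed=13,
            n_epistatic_pairs=3))
        fe_ges = ges(TableOracle(table), _cfg(seed=4)).final_fe
        fe_ghd = ghd(TableOracle(table), _cfg(seed=4)).final_fe
        assert fe_ghd >= fe_ges - 1e-12

    def test_deterministic(self, landscape12):
        r1 = ghd(TableOracle(landscape12), _cfg(seed=8))
        r2 = ghd(TableOracle(landscape12), _cfg(seed=8))
        assert r1.final_bitvector == r2.final_bitvector
        assert r1.n_estimated == r2.n_estimated


class TestGA:
    def test_population_contract(self, landscape12):
        oracle = TableOracle(landscape12)
        res = ga(oracle, _cfg(seed=0))
        seen = set()
        for t in res.trajectory:
            for bv in t["evaluated"]:
                assert bv not in seen  # never re-evaluated
                assert oracle.space.is_valid(bv)
                seen.add(bv)
        for t in res.trajectory[1:]:
            assert len(t["evaluated"]) <= 16  # 16 offspring per generation

    def test_finds_optimum_in_most_runs(self, landscape12):
        best = landscape12.best_bitvector
        hits = sum(
            ga(TableOracle(landscape12), _cfg(seed=s)).final_bitvector == best
            for s in range(20))
        assert hits >= 18

    def test_same_seed_identical_trajectory(self, landscape12):
        r1 = ga(TableOracle(landscape12), _cfg(seed=5))
        r2 = ga(TableOracle(landscape12), _cfg(seed=5))
        assert r1.trajectory == r2.trajectory
        assert r1.final_bitvector == r2.final_bitvector

    def test_returned_fe_is_max_over_evaluated(self, landscape12):
        oracle = TableOracle(landscape12)
        res = ga(oracle, _cfg(seed=2))
        fes = [oracle.evaluate(bv).fe
               for t in res.trajectory for bv in t["evaluated"]]
        assert res.final_fe == max(fes)


class TestOptimizedVariants:
    def test_probability_guidance_reduces_evaluations(self, sharp_landscape16):
        # sharp synthetic probabilities let the primed variants skip
        # low-information moves: strictly fewer unique evaluations on average
        for base_fn, name in ((ges, "ges"), (ghd, "ghd"), (ga, "ga")):
            n_base, n_opt = [], []
            for seed in range(10):
                n_base.append(base_fn(TableOracle(sharp_landscape16),
                                      _cfg(seed=seed)).n_estimated)
                n_opt.append(base_fn(TableOracle(sharp_landscape16),
                                     _cfg(seed=seed, optimized=True)
                                     ).n_estimated)
            assert np.mean(n_opt) < np.mean(n_base), name

    def test_run_search_dispatches_primed_names(self, landscape12):
        res = run_search(TableOracle(landscape12),
                         _cfg(algorithm="ges'", seed=1))
        assert res.algorithm == "ges'"


def _posthoc_problem(null_index, strength=2.0, d=5, T=200, seed=0):
    """Linear-Gaussian full model with one truly null coefficient."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(T, d))
    beta = np.full(d, strength)
    beta[null_index] = 0.0
    sigma2 = 1.0
    y = X @ beta + rng.normal(0, 1.0, T)
    S0 = np.eye(d)
    P = X.T @ X / sigma2 + np.linalg.inv(S0)
    S = np.linalg.inv(P)
    m = S @ (X.T @ y / sigma2)
    spec = make_spec(n_regions=2, n_modulatory=0, n_driving=0)  # 2 free bits
    return GaussianDensity(m, S), GaussianDensity(np.zeros(d), S0)


class TestPosthoc:
    def test_null_parameter_pruned_first(self, spec9):
        # build a full "model" whose free set matches spec9's 9 bits
        rng = np.random.default_rng(1)
        d = 9
        X = rng.normal(size=(300, d))
        beta = np.full(d, 1.5)
        beta[4] = 0.0
        y = X @ beta + rng.normal(0, 1.0, 300)
        S0 = np.eye(d)
        P = X.T @ X + np.linalg.inv(S0)
        S = np.linalg.inv(P)
        m = S @ (X.T @ y)
        post = PosteriorEstimate(
            density=GaussianDensity(m, S), fe=0.0, accuracy=0.0,
            complexity=0.0, probability=np.ones(d), lambda_=0.0,
            fe_trace=[0.0], keys=list(spec9.bits),
            structure=spec9.structure("1" * 9))
        priors = PriorSpec(keys=list(spec9.bits),
                           density=GaussianDensity(np.zeros(d), S0))
        res = posthoc_greedy(post, priors, spec9)
        assert res.final_bitvector == "111101111"
        assert res.trajectory[0]["removed_group"] == 4
        assert res.n_estimated == 0
        assert res.n_bmr > 0

    def test_all_supported_returns_full_model(self, spec9):
        rng = np.random.default_rng(2)
        d = 9
        X = rng.normal(size=(300, d))
        beta = np.full(d, 2.0)
        y = X @ beta + rng.normal(0, 1.0, 300)
        S0 = np.eye(d)
        P = X.T @ X + np.linalg.inv(S0)
        S = np.linalg.inv(P)
        m = S @ (X.T @ y)
        post = PosteriorEstimate(
            density=GaussianDensity(m, S), fe=0.0, accuracy=0.0,
            complexity=0.0, probability=np.ones(d), lambda_=0.0,
            fe_trace=[0.0], keys=list(spec9.bits),
            structure=spec9.structure("1" * 9))
        priors = PriorSpec(keys=list(spec9.bits),
                           density=GaussianDensity(np.zeros(d), S0))
        res = posthoc_greedy(post, priors, spec9)
        assert res.final_bitvector == "1" * 9


class TestBMROracleConsistency:
    def test_table_and_bmr_backends_agree(self, spec8):
        """A table built by the BMR estimator must reproduce the exact same
        search trajectories as querying BMR live (2^8 space)."""
        d = spec8.n_free_bits
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, d))
        beta = rng.normal(0, 1.0, d)
        y = X @ beta + rng.normal(0, 1.0, 200)
        S0 = np.eye(d)
        P = X.T @ X + np.linalg.inv(S0)
        S = np.linalg.inv(P)
        m = S @ (X.T @ y)
        post = PosteriorEstimate(
            density=GaussianDensity(m, S), fe=-100.0, accuracy=0.0,
            complexity=0.0, probability=np.ones(d), lambda_=0.0,
            fe_trace=[0.0], keys=list(spec8.bits),
            structure=spec8.structure("1" * d))
        priors = PriorSpec(keys=list(spec8.bits),
                           density=GaussianDensity(np.zeros(d), S0))
        live = BMROracle(post, priors, spec8)
        # exhaustively tabulate the BMR evidence
        from dcmsearch.model_space import ModelRecord, ModelSpaceTable

        records = []
        probe = BMROracle(post, priors, spec8)
        n, mm, ii = spec8.n_regions, spec8.n_modulatory, spec8.n_driving
        for code in range(1 << d):
            bv = format(code, f"0{d}b")
            ev = probe.evaluate(bv)
            pA = np.zeros((n, n))
            pB = np.zeros((mm, n, n))
            pC = np.zeros((n, ii))
            for b, key in enumerate(spec8.bits):
                if key[0] == "A":
                    pA[key[1], key[2]] = ev.bit_probabilities[b]
                elif key[0] == "B":
                    pB[key[1], key[2], key[3]] = ev.bit_probabilities[b]
                else:
                    pC[key[1], key[2]] = ev.bit_probabilities[b]
            records.append(ModelRecord(
                id=code, bitvector=bv, fe=ev.fe,
                A=np.zeros((n, n)), B=np.zeros((mm, n, n)),
                C=np.zeros((n, ii)), pA=pA, pB=pB, pC=pC))
        table = ModelSpaceTable.from_records(spec8, records)
        annotate_table(table)
        for algorithm, seed in (("ges", 1), ("ghd", 2), ("ga", 3)):
            res_live = run_search(BMROracle(post, priors, spec8),
                                  _cfg(algorithm=algorithm, seed=seed))
            res_tab = run_search(TableOracle(table),
                                 _cfg(algorithm=algorithm, seed=seed))
            assert res_live.final_bitvector == res_tab.final_bitvector
            assert [t["evaluated"] for t in res_live.trajectory] == \
                   [t["evaluated"] for t in res_tab.trajectory]


class TestCharacterize:
    def test_summary_shape_and_determinism(self, landscape12):
        summary, runs = characterize(
            ["ges", "ghd"], lambda: TableOracle(landscape12), n_runs=5,
            seeds=[0, 1, 2, 3, 4])
        assert list(summary["algorithm"]) == ["ges", "ghd"]
        assert {"dFe_mean", "dFe_std", "Hd_mean", "Hd_std", "N_mean",
                "N_std"} <= set(summary.columns)
        assert len(runs) == 10

    def test_fixed_init_deterministic_algorithm_has_zero_spread(
            self, landscape12):
        cfg = SearchConfig(init="given",
                           init_bitvector=landscape12.bitvectors[17])
        summary, _ = characterize(
            ["ges"], lambda: TableOracle(landscape12), n_runs=4,
            seeds=[0, 1, 2, 3], config=cfg)
        assert summary.loc[0, "dFe_std"] == 0.0
        assert summary.loc[0, "N_std"] == 0.0

    def test_ga_needs_more_evaluations_than_ges(self, landscape12):
        summary, _ = characterize(
            ["ges", "ga"], lambda: TableOracle(landscape12), n_runs=10,
            seeds=list(range(10)))
        by = summary.set_index("algorithm")
        assert by.loc["ga", "N_mean"] > by.loc["ges", "N_mean"]
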