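"""Topological model-space search for DCM.

All algorithms walk over bitvector-encoded model structures and consult a
pluggable :class:`EvidenceOracle` for free energy (and, optionally,
per-parameter posterior probabilities). Backends: a pre-estimated
model-space table (fast lookup), live variational Laplace estimation, or
Bayesian model reduction from a single estimated full model.

Algorithms:

* GES — greedy search alternating a removal phase and an addition phase
  (one connection changed at a time) until neither improves the evidence.
* GHD — greedy search over the full Hamming-distance-1 neighborhood
  (additions and removals considered simultaneously).
* GA — a genetic algorithm over the bitvector codes: 4 survivors breed 16
  offspring per generation via two-point crossover and mutation (50%
  probability, 2-8 bit flips), duplicates and constraint violations are
  regenerated, and the best 4 of the 20 survive.
* post-hoc — greedy BMR pruning of parameters from the estimated full
  model, no further estimation required.

The optimized variants (GES', GHD', GA') exploit posterior parameter
probabilities accumulated over previously evaluated models: GES'/GHD'
refuse to remove a connection whose running-mean probability is >= 0.9;
GA' replaces offspring containing a connection whose running-mean
probability is < 0.3 with a fresh mutant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimation import (
    GaussianDensity,
    PosteriorEstimate,
    PriorSpec,
    bmr_reduce,
    parameter_probability,
    variational_laplace,
)
from .forward import BOLDDataset, HemodynamicParams
from .model_space import ConstraintSpec, ModelSpaceTable, hamming_bits

__all__ = [
    "BitSpace",
    "ConstraintBitSpace",
    "FreeBitSpace",
    "EvidenceOracle",
    "TableOracle",
    "VLOracle",
    "BMROracle",
    "SearchConfig",
    "SearchResult",
    "ges",
    "ghd",
    "ga",
    "posthoc_greedy",
    "greedy_bmr_prune",
    "run_search",
    "characterize",
]


class BitSpace:
    """A search space of fixed-length bitvectors with a validity rule."""

    n_bits: int

    def is_valid(self, bitvector: str) -> bool:  # pragma: no cover
        raise NotImplementedError

    def random_valid(self, rng: np.random.Generator, max_tries: int = 1000) -> str:
        for _ in range(max_tries):
            bv = "".join(rng.choice(["0", "1"], size=self.n_bits))
            if self.is_valid(bv):
                return bv
        raise RuntimeError("could not draw a valid random bitvector")


class ConstraintBitSpace(BitSpace):
    """Bit space induced by a model-space :class:`ConstraintSpec`."""

    def __init__(self, spec: ConstraintSpec):
        self.spec = spec
        self.n_bits = spec.n_free_bits

    def is_valid(self, bitvector: str) -> bool:
        return self.spec.is_valid_bits(bitvector)


class FreeBitSpace(BitSpace):
    """Unconstrained bit space (every assignment valid)."""

    def __init__(self, n_bits: int):
        self.n_bits = n_bits

    def is_valid(self, bitvector: str) -> bool:
        return len(bitvector) == self.n_bits


@dataclass
class Evaluation:
    fe: float
    bit_probabilities: np.ndarray | None = None


class EvidenceOracle:
    """Uniform evidence interface with caching and an evaluation counter.

    Repeated queries for the same bitvector hit the cache and do not
    increment the counter N of unique evaluations.
    """

    def __init__(self, space: BitSpace):
        self.space = space
        self._cache: dict[str, Evaluation] = {}

    @property
    def n_evaluated(self) -> int:
        return len(self._cache)

    @property
    def known_best(self) -> str | None:
        return None

    def reset(self) -> None:
        self._cache.clear()

    def evaluate(self, bitvector: str) -> Evaluation:
        if bitvector not in self._cache:
            self._cache[bitvector] = self._evaluate(bitvector)
        return self._cache[bitvector]

    def _evaluate(self, bitvector: str) -> Evaluation:  # pragma: no cover
        raise NotImplementedError


class TableOracle(EvidenceOracle):
    """Evidence lookup in a pre-estimated model-space table."""

    def __init__(self, table: ModelSpaceTable):
        super().__init__(ConstraintBitSpace(table.spec))
        self.table = table
        self._best = table.best_bitvector

    @property
    def known_best(self) -> str | None:
        return self._best

    def _evaluate(self, bitvector: str) -> Evaluation:
        if bitvector not in self.table:
            raise KeyError(f"model {bitvector} not in table")
        return Evaluation(
            fe=self.table.fe(bitvector),
            bit_probabilities=self.table.bit_probabilities(bitvector),
        )


class VLOracle(EvidenceOracle):
    """Live variational Laplace estimation of each queried model."""

    def __init__(self, data: BOLDDataset, spec: ConstraintSpec,
                 hemo: HemodynamicParams | None = None, **vl_options):
        super().__init__(ConstraintBitSpace(spec))
        self.data = data
        self.spec = spec
        self.hemo = hemo
        self.vl_options = vl_options
        self.posteriors: dict[str, PosteriorEstimate] = {}

    def reset(self) -> None:
        super().reset()
        self.posteriors.clear()

    def _evaluate(self, bitvector: str) -> Evaluation:
        structure = self.spec.structure(bitvector)
        est = variational_laplace(
            self.data, structure, hemo=self.hemo, **self.vl_options)
        self.posteriors[bitvector] = est
        probs = np.full(self.spec.n_free_bits, np.nan)
        mats = est.matrices()
        for b, key in enumerate(self.spec.bits):
            if key[0] == "A":
                probs[b] = mats["pA"][key[1], key[2]]
            elif key[0] == "B":
                probs[b] = mats["pB"][key[1], key[2], key[3]]
            else:
                probs[b] = mats["pC"][key[1], key[2]]
        return Evaluation(fe=est.fe, bit_probabilities=probs)


class BMROracle(EvidenceOracle):
    """Evidence of any nested model by Bayesian model reduction from one
    estimated full model: every query is a closed-form Gaussian reduction,
    evaluated around the full model's free-energy optimum."""

    def __init__(self, full_posterior: PosteriorEstimate, priors: PriorSpec,
                 spec: ConstraintSpec, zero_var: float = 1e-8):
        super().__init__(ConstraintBitSpace(spec))
        self.full = full_posterior
        self.priors = priors
        self.spec = spec
        self.zero_var = zero_var
        # map each free bit onto its parameter index in the full free set
        self._bit_to_param = []
        key_index = {key: p for p, key in enumerate(priors.keys)}
        for key in spec.bits:
            if key not in key_index:
                raise ValueError(
                    f"free bit {key} has no parameter in the full model")
            self._bit_to_param.append(key_index[key])

    def _evaluate(self, bitvector: str) -> Evaluation:
        var = np.diag(self.priors.density.cov).copy()
        for b, bit in enumerate(bitvector):
            if bit == "0":
                var[self._bit_to_param[b]] = self.zero_var
        reduced_prior = GaussianDensity(self.priors.density.mean, np.diag(var))
        dF, q_r = bmr_reduce(self.full.density, self.priors.density,
                             reduced_prior)
        p = parameter_probability(q_r.mean, q_r.sd())
        probs = np.array([p[self._bit_to_param[b]]
                          for b in range(len(bitvector))])
        return Evaluation(fe=self.full.fe + dF, bit_probabilities=probs)


# ---------------------------------------------------------------------------
# search algorithms
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    population: int = 20
    parents: int = 4
    offspring: int = 16
    mutation_prob: float = 0.5
    mutation_bits: tuple[int, int] = (2, 8)
    idle_stop: int = 3
    max_regen: int = 2000


@dataclass
class SearchConfig:
    """Search settings shared by all algorithms."""

    algorithm: str = "ges"
    optimized: bool = False
    keep_threshold: float = 0.9
    drop_threshold: float = 0.3
    seed: int | None = None
    init: str = "random"  # random | full | given
    init_bitvector: str | None = None
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.keep_threshold <= 1 and 0 <= self.drop_threshold <= 1):
            raise ValueError("probability thresholds must lie in [0, 1]")


@dataclass
class SearchResult:
    """Outcome of one search run."""

    algorithm: str
    final_bitvector: str
    final_fe: float
    trajectory: list[dict]
    n_estimated: int
    n_bmr: int | None = None
    dfe: float | None = None
    hd: int | None = None

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "bitvector": self.final_bitvector,
            "Fe": self.final_fe,
            "dFe": self.dfe,
            "Hd": self.hd,
            "N": self.n_estimated,
        }


class _ProbTracker:
    """Running mean of each bit's posterior probability over all evaluated
    models that include that bit."""

    def __init__(self, n_bits: int):
        self.sums = np.zeros(n_bits)
        self.counts = np.zeros(n_bits, dtype=int)

    def update(self, bitvector: str, ev: Evaluation) -> None:
        if ev.bit_probabilities is None:
            return
        for b, bit in enumerate(bitvector):
            p = ev.bit_probabilities[b]
            if bit == "1" and np.isfinite(p):
                self.sums[b] += p
                self.counts[b] += 1

    def mean(self, b: int) -> float:
        if self.counts[b] == 0:
            return np.nan
        return self.sums[b] / self.counts[b]


def _flip(bv: str, b: int) -> str:
    return bv[:b] + ("0" if bv[b] == "1" else "1") + bv[b + 1 :]


def _initial(oracle: EvidenceOracle, config: SearchConfig,
             rng: np.random.Generator) -> str:
    if config.init == "given":
        if config.init_bitvector is None:
            raise ValueError("init='given' requires init_bitvector")
        return config.init_bitvector
    if config.init == "full":
        bv = "1" * oracle.space.n_bits
        if not oracle.space.is_valid(bv):
            raise ValueError("full model violates space constraints")
        return bv
    return oracle.space.random_valid(rng)


def _safe_eval(oracle, bv, tracker, trajectory_entry):
    try:
        ev = oracle.evaluate(bv)
    except Exception as exc:  # oracle failure: skip, record
        warnings.warn(f"oracle failed on {bv}: {exc}")
        trajectory_entry.setdefault("failed", []).append(bv)
        return None
    tracker.update(bv, ev)
    return ev


def _finish(algorithm, oracle, evaluated, trajectory, n0, n_bmr=None):
    # the returned model is the best among everything evaluated
    best_bv = min(evaluated, key=lambda bv: (-evaluated[bv], bv))
    fe = evaluated[best_bv]
    dfe = hd = None
    if oracle.known_best is not None:
        dfe = oracle.evaluate(oracle.known_best).fe - fe
        hd = hamming_bits(best_bv, oracle.known_best)
    return SearchResult(
        algorithm=algorithm,
        final_bitvector=best_bv,
        final_fe=fe,
        trajectory=trajectory,
        n_estimated=oracle.n_evaluated - n0,
        n_bmr=n_bmr,
        dfe=dfe,
        hd=hd,
    )


def ges(oracle: EvidenceOracle, config: SearchConfig) -> SearchResult:
    """Greedy equivalence-style search: alternating removal and addition
    phases, one connection changed at a time, until a local optimum."""
    rng = np.random.default_rng(config.seed)
    tracker = _ProbTracker(oracle.space.n_bits)
    n0 = oracle.n_evaluated
    current = _initial(oracle, config, rng)
    entry = {"phase": "init", "evaluated": [current]}
    ev = _safe_eval(oracle, current, tracker, entry)
    if ev is None:
        raise RuntimeError("oracle failed on the initial model")
    current_fe = ev.fe
    evaluated = {current: current_fe}
    trajectory = [dict(entry, winner=current, fe=current_fe)]

    improved_cycle = True
    while improved_cycle:
        improved_cycle = False
        for phase in ("remove", "add"):
            while True:
                want = "1" if phase == "remove" else "0"
                cands = []
                for b in range(oracle.space.n_bits):
                    if current[b] != want:
                        continue
                    if (config.optimized and phase == "remove"):
                        mp = tracker.mean(b)
                        if np.isfinite(mp) and mp >= config.keep_threshold:
                            continue  # connection fixed: too probable to drop
                    nb = _flip(current, b)
                    if oracle.space.is_valid(nb):
                        cands.append(nb)
                entry = {"phase": phase, "evaluated": []}
                best_bv, best_fe = None, current_fe
                for nb in sorted(cands):
                    evn = _safe_eval(oracle, nb, tracker, entry)
                    if evn is None:
                        continue
                    entry["evaluated"].append(nb)
                    evaluated[nb] = evn.fe
                    if evn.fe > best_fe:
                        best_bv, best_fe = nb, evn.fe
                if best_bv is None:
                    break
                current, current_fe = best_bv, best_fe
                improved_cycle = True
                trajectory.append(dict(entry, winner=current, fe=current_fe))
    return _finish("ges'" if config.optimized else "ges",
                   oracle, evaluated, trajectory, n0)


def ghd(oracle: EvidenceOracle, config: SearchConfig) -> SearchResult:
    """Greedy Hamming-distance search: each iteration evaluates the whole
    Hd<=1 neighborhood and moves to the best improving neighbor."""
    rng = np.random.default_rng(config.seed)
    tracker = _ProbTracker(oracle.space.n_bits)
    n0 = oracle.n_evaluated
    current = _initial(oracle, config, rng)
    entry = {"phase": "init", "evaluated": [current]}
    ev = _safe_eval(oracle, current, tracker, entry)
    if ev is None:
        raise RuntimeError("oracle failed on the initial model")
    current_fe = ev.fe
    evaluated = {current: current_fe}
    trajectory = [dict(entry, winner=current, fe=current_fe)]

    while True:
        cands = []
        for b in range(oracle.space.n_bits):
            if config.optimized and current[b] == "1":
                mp = tracker.mean(b)
                if np.isfinite(mp) and mp >= config.keep_threshold:
                    continue
            nb = _flip(current, b)
            if oracle.space.is_valid(nb):
                cands.append(nb)
        entry = {"phase": "neighborhood", "evaluated": []}
        best_bv, best_fe = None, current_fe
        for nb in sorted(cands):
            evn = _safe_eval(oracle, nb, tracker, entry)
            if evn is None:
                continue
            entry["evaluated"].append(nb)
            evaluated[nb] = evn.fe
            if evn.fe > best_fe:
                best_bv, best_fe = nb, evn.fe
        if best_bv is None:
            break
        current, current_fe = best_bv, best_fe
        trajectory.append(dict(entry, winner=current, fe=current_fe))
    return _finish("ghd'" if config.optimized else "ghd",
                   oracle, evaluated, trajectory, n0)


def _mutate(bv: str, rng: np.random.Generator, lo: int, hi: int) -> str:
    nb = len(bv)
    k = int(rng.integers(lo, min(hi, nb) + 1))
    pos = rng.choice(nb, size=min(k, nb), replace=False)
    out = list(bv)
    for b in pos:
        out[b] = "0" if out[b] == "1" else "1"
    return "".join(out)


def _crossover(p1: str, p2: str, rng: np.random.Generator) -> str:
    nb = len(p1)
    a, b = sorted(rng.choice(nb + 1, size=2, replace=False))
    return p1[:a] + p2[a:b] + p1[b:]


def ga(oracle: EvidenceOracle, config: SearchConfig) -> SearchResult:
    """Genetic algorithm over bitvector codes (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    g = config.ga
    tracker = _ProbTracker(oracle.space.n_bits)
    n0 = oracle.n_evaluated
    seen: set[str] = set()
    evaluated: dict[str, float] = {}
    trajectory: list[dict] = []

    def fresh_random() -> str | None:
        for _ in range(g.max_regen):
            bv = oracle.space.random_valid(rng)
            if bv not in seen:
                return bv
        return None

    def fresh_mutant(pool: Sequence[str]) -> str | None:
        for _ in range(g.max_regen):
            base = pool[int(rng.integers(len(pool)))]
            bv = _mutate(base, rng, *g.mutation_bits)
            if oracle.space.is_valid(bv) and bv not in seen:
                return bv
        return None

    def low_prob_connection(bv: str) -> bool:
        # a candidate is discarded when the running-mean probability of the
        # connections it contains averages below the drop threshold
        ps = [tracker.mean(b) for b, bit in enumerate(bv) if bit == "1"]
        ps = [p for p in ps if np.isfinite(p)]
        return bool(ps) and float(np.mean(ps)) < config.drop_threshold

    # initial population: a random model and three mutated variants
    first = fresh_random()
    if first is None:
        raise RuntimeError("cannot draw an initial model")
    seen.add(first)
    population = [first]
    while len(population) < g.parents:
        bv = fresh_mutant(population)
        if bv is None:
            bv = fresh_random()
        if bv is None:
            break
        seen.add(bv)
        population.append(bv)
    entry = {"phase": "init", "evaluated": []}
    for bv in population:
        ev = _safe_eval(oracle, bv, tracker, entry)
        if ev is not None:
            entry["evaluated"].append(bv)
            evaluated[bv] = ev.fe
    survivors = sorted(population, key=lambda bv: (-evaluated.get(bv, -np.inf), bv))
    survivors = survivors[: g.parents]
    trajectory.append(dict(entry, winner=survivors[0],
                           fe=evaluated[survivors[0]]))

    idle = 0
    while idle < g.idle_stop:
        offspring: list[str] = []
        early_stop = False
        attempts = 0
        while len(survivors) + len(offspring) < g.population:
            attempts += 1
            if attempts > g.max_regen:
                warnings.warn(
                    "could not produce enough unique valid offspring; "
                    "terminating generation early")
                early_stop = True
                break
            i, j = rng.choice(len(survivors), size=2, replace=False)
            child = _crossover(survivors[i], survivors[j], rng)
            if rng.random() < g.mutation_prob:
                child = _mutate(child, rng, *g.mutation_bits)
            if config.optimized and low_prob_connection(child):
                repl = fresh_mutant(survivors + offspring)
                if repl is None:
                    continue
                child = repl
            if not oracle.space.is_valid(child) or child in seen:
                continue
            seen.add(child)
            offspring.append(child)
        entry = {"phase": "generation", "evaluated": []}
        for bv in offspring:
            ev = _safe_eval(oracle, bv, tracker, entry)
            if ev is not None:
                entry["evaluated"].append(bv)
                evaluated[bv] = ev.fe
        pool = survivors + [bv for bv in offspring if bv in evaluated]
        incumbent = set(survivors)
        # ties keep the incumbent survivor (stable elitist selection)
        new_survivors = sorted(
            pool, key=lambda bv: (-evaluated[bv], bv not in incumbent, bv)
        )[: g.parents]
        trajectory.append(dict(entry, winner=new_survivors[0],
                               fe=evaluated[new_survivors[0]]))
        if set(new_survivors) == set(survivors):
            idle += 1
        else:
            idle = 0
        survivors = new_survivors
        if early_stop:
            break
    return _finish("ga'" if config.optimized else "ga",
                   oracle, evaluated, trajectory, n0)


def greedy_bmr_prune(
    posterior: GaussianDensity,
    prior: GaussianDensity,
    groups: Sequence[Sequence[int]],
    zero_var: float = 1e-8,
) -> tuple[np.ndarray, list[dict], int]:
    """Greedy BMR pruning over parameter groups.

    Each group is a set of parameter indices removed (prior variance shrunk
    to ~0) together. Iteratively removes the group whose removal most
    increases the reduced log evidence, until no removal improves it.
    Returns (kept mask over groups, trajectory, number of BMR evaluations).
    """
    var0 = np.diag(prior.cov).copy()
    kept = np.ones(len(groups), dtype=bool)
    n_bmr = 0
    trajectory: list[dict] = []

    def reduced_df(mask):
        nonlocal n_bmr
        var = var0.copy()
        for gi, keep in enumerate(mask):
            if not keep:
                for p in groups[gi]:
                    var[p] = zero_var
        dF, _ = bmr_reduce(posterior, prior,
                           GaussianDensity(prior.mean, np.diag(var)))
        n_bmr += 1
        return dF

    current_df = reduced_df(kept)
    while True:
        best_gi, best_df = None, current_df
        for gi in range(len(groups)):
            if not kept[gi]:
                continue
            cand = kept.copy()
            cand[gi] = False
            dF = reduced_df(cand)
            if dF > best_df:
                best_gi, best_df = gi, dF
        if best_gi is None:
            break
        kept[best_gi] = False
        current_df = best_df
        trajectory.append({"removed_group": best_gi, "dF": best_df})
    return kept, trajectory, n_bmr


def posthoc_greedy(
    full_posterior: PosteriorEstimate,
    priors: PriorSpec,
    constraints: ConstraintSpec,
) -> SearchResult:
    """Post-hoc model selection: greedy BMR pruning of free connectivity
    bits from the estimated full model. Costs no further model estimation
    (N is reported as BMR evaluations only).

    Note the pruned model optimizes evidence alone; it may violate
    structural constraints such as modulation-requires-connection, as the
    pruning works purely on shrinkage priors.
    """
    key_index = {key: p for p, key in enumerate(priors.keys)}
    groups = []
    for key in constraints.bits:
        if key not in key_index:
            raise ValueError(f"bit {key} not among the full model's parameters")
        groups.append([key_index[key]])
    kept, trail, n_bmr = greedy_bmr_prune(
        full_posterior.density, priors.density, groups)
    final_bv = "".join("1" if k else "0" for k in kept)
    var = np.diag(priors.density.cov).copy()
    for gi, k in enumerate(kept):
        if not k:
            var[groups[gi][0]] = 1e-8
    dF, _ = bmr_reduce(full_posterior.density, priors.density,
                       GaussianDensity(priors.density.mean, np.diag(var)))
    return SearchResult(
        algorithm="posthoc",
        final_bitvector=final_bv,
        final_fe=full_posterior.fe + dF,
        trajectory=trail,
        n_estimated=0,
        n_bmr=n_bmr + 1,
    )


_ALGORITHMS: dict[str, Callable] = {"ges": ges, "ghd": ghd, "ga": ga}


def run_search(oracle: EvidenceOracle, config: SearchConfig) -> SearchResult:
    try:
        fn = _ALGORITHMS[config.algorithm.rstrip("'")]
    except KeyError:
        raise ValueError(f"unknown algorithm {config.algorithm!r}") from None
    if config.algorithm.endswith("'"):
        config = SearchConfig(**{**config.__dict__, "algorithm":
                                 config.algorithm.rstrip("'"),
                                 "optimized": True})
    return fn(oracle, config)


def characterize(
    algorithms: Sequence[str],
    oracle_factory: Callable[[], EvidenceOracle],
    n_runs: int = 20,
    seeds: Sequence[int] | None = None,
    config: SearchConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run each algorithm ``n_runs`` times with randomized initialization
    and summarize dFe, Hd and N (mean and sd across runs).

    ``oracle_factory`` must return a fresh (or reset) oracle whose counter
    starts at the run's beginning; the oracle must know the space's best
    model so dFe and Hd are defined. Returns (summary, per-run records).
    """
    base = config or SearchConfig()
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    rows = []
    for name in algorithms:
        for run, seed in enumerate(seeds):
            oracle = oracle_factory()
            cfg = SearchConfig(**{**base.__dict__, "algorithm": name,
                                  "seed": seed})
            res = run_search(oracle, cfg)
            rows.append({
                "algorithm": name, "run": run, "seed": seed,
                "dFe": res.dfe, "Hd": res.hd, "N": res.n_estimated,
                "Fe": res.final_fe, "bitvector": res.final_bitvector,
            })
    runs = pd.DataFrame(rows)
    summary = runs.groupby("algorithm", sort=False)[["dFe", "Hd", "N"]].agg(
        ["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return summary.reset_index(), runs
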