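"""Parametric empirical Bayes (PEB): a hierarchical linear-Gaussian model
over subjects' DCM parameters.

The second level treats each subject's posterior mean as a noisy
observation of a group-level linear model,

    theta_i ~ N( sum_j X_ij beta_j ,  Sigma_i + exp(-gamma) I ),

where X is the between-subject design matrix (first column all ones — the
group mean or "commonalities" — then mean-centered covariates such as a
laterality index, handedness, gender and age), Sigma_i is subject i's
first-level posterior covariance and exp(-gamma) the between-subject
variance (one precision component, scalar gamma estimated by maximizing
the second-level free energy). The group effects beta carry a Gaussian
prior; everything at this level is conjugate, so the posterior over beta
and the free energy are closed-form given gamma, and nested group models
can be scored exactly with Bayesian model reduction.

First-level posteriors are never modified (read-only contract).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .estimation import (
    GaussianDensity,
    ParamKey,
    PosteriorEstimate,
    bmr_reduce,
    parameter_probability,
)
from .search import (
    EvidenceOracle,
    Evaluation,
    FreeBitSpace,
    SearchConfig,
    SearchResult,
    greedy_bmr_prune,
    run_search,
)

__all__ = [
    "PEBDesign",
    "PEBPosterior",
    "fit_peb",
    "peb_bmr_auto",
    "peb_topological_search",
    "PEBOracle",
]


@dataclass
class PEBDesign:
    """Between-subject design matrix: first column all ones
    (commonalities), remaining covariates mean-centered."""

    X: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate names do not match design width")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the constant "
                             "(commonalities)")
        # mean-center covariates so the constant carries the group mean
        if self.X.shape[1] > 1:
            self.X = self.X.copy()
            self.X[:, 1:] -= self.X[:, 1:].mean(axis=0)
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # name the offending columns for the caller
            bad = []
            for c in range(1, self.X.shape[1]):
                sub = np.delete(self.X, c, axis=1)
                if np.linalg.matrix_rank(sub) == rank:
                    bad.append(self.covariate_names[c])
            raise ValueError(
                f"design matrix is rank deficient (collinear: {bad or 'constant'})")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class PEBPosterior:
    """Group-level posterior over (covariate x parameter) effects."""

    density: GaussianDensity  # over beta, stacked covariate-major
    prior: GaussianDensity
    fe: float
    gamma: float  # log between-subject precision
    design: PEBDesign
    param_keys: list[ParamKey]
    probability: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probability = np.atleast_1d(
            parameter_probability(self.density.mean, self.density.sd()))

    @property
    def n_params(self) -> int:
        return len(self.param_keys)

    def effect(self, covariate: str) -> np.ndarray:
        """Posterior mean of one covariate's effect on every parameter."""
        c = self.design.covariate_names.index(covariate)
        d = self.n_params
        return self.density.mean[c * d : (c + 1) * d]

    def beta_index(self, covariate: int, param: int) -> int:
        return covariate * self.n_params + param


def _second_level(
    M: np.ndarray,            # subjects x d posterior means
    Sigmas: list[np.ndarray], # per-subject posterior covariances
    X: np.ndarray,
    prior: GaussianDensity,
    gamma: float,
    gamma_prior: tuple[float, float],
) -> tuple[float, GaussianDensity]:
    """Closed-form evidence and beta posterior of the linear second level
    for a fixed between-subject log precision gamma."""
    S, d = M.shape
    c = X.shape[1]
    sigma_b = np.exp(-gamma)
    # precision-weighted accumulation over subjects
    P = np.linalg.inv(prior.cov).copy()
    b = P @ prior.mean
    logdet_terms = 0.0
    quad = 0.0
    for i in range(S):
        Vi = Sigmas[i] + sigma_b * np.eye(d)
        Li = np.linalg.cholesky(Vi)
        Pi = np.linalg.inv(Vi)
        logdet_terms += 2.0 * np.log(np.diag(Li)).sum()
        xi = X[i]
        # design row acts as Kronecker(xi, I_d)
        P += np.kron(np.outer(xi, xi), Pi)
        b += np.kron(xi, Pi @ M[i])
        quad += M[i] @ Pi @ M[i]
    Sq = np.linalg.inv(P)
    mq = Sq @ b
    # log marginal likelihood of all subject means + Gaussian prior on beta
    sign0, logdet_prior = np.linalg.slogdet(prior.cov)
    signq, logdet_post = np.linalg.slogdet(Sq)
    m0 = prior.mean
    P0 = np.linalg.inv(prior.cov)
    fe = -0.5 * (
        S * d * np.log(2.0 * np.pi)
        + logdet_terms
        + quad
        + m0 @ P0 @ m0
        - mq @ P @ mq
        + logdet_prior
        - logdet_post
    )
    mg, vg = gamma_prior
    fe += -0.5 * (gamma - mg) ** 2 / vg - 0.5 * np.log(2.0 * np.pi * vg)
    return float(fe), GaussianDensity(mq, 0.5 * (Sq + Sq.T))


def fit_peb(
    subject_posteriors: list[PosteriorEstimate | GaussianDensity],
    design: PEBDesign,
    param_keys: list[ParamKey] | None = None,
    prior_var_mean: float = 1.0,
    prior_var_covariate: float = 1.0,
    gamma_prior: tuple[float, float] = (0.0, 16.0),
    gamma_bounds: tuple[float, float] = (-8.0, 8.0),
) -> PEBPosterior:
    """Fit the group-level PEB model.

    All subjects must share the same structure and parameter ordering.
    The between-subject log precision gamma is optimized by maximizing the
    closed-form second-level free energy; beta's posterior follows
    conjugately. Deterministic; first-level posteriors are left untouched.
    """
    if len(subject_posteriors) != design.n_subjects:
        raise ValueError("number of subjects does not match the design")
    dens = [p.density if isinstance(p, PosteriorEstimate) else p
            for p in subject_posteriors]
    d = dens[0].dim
    if any(q.dim != d for q in dens):
        raise ValueError("subjects must share the full structure and "
                         "parameter ordering")
    if param_keys is None:
        first = subject_posteriors[0]
        param_keys = (list(first.keys)
                      if isinstance(first, PosteriorEstimate)
                      else [("p", i) for i in range(d)])
    M = np.vstack([q.mean for q in dens])
    Sigmas = [q.cov for q in dens]
    c = design.n_covariates
    var = np.concatenate([
        np.full(d, prior_var_mean if j == 0 else prior_var_covariate)
        for j in range(c)
    ])
    prior = GaussianDensity(np.zeros(c * d), np.diag(var))

    def neg_fe(gamma):
        fe, _ = _second_level(M, Sigmas, design.X, prior, gamma, gamma_prior)
        return -fe

    opt = minimize_scalar(neg_fe, bounds=gamma_bounds, method="bounded",
                          options={"xatol": 1e-3})
    gamma = float(opt.x)
    fe, q = _second_level(M, Sigmas, design.X, prior, gamma, gamma_prior)
    return PEBPosterior(density=q, prior=prior, fe=fe, gamma=gamma,
                        design=design, param_keys=list(param_keys))


def _group_mean_groups(
    peb: PEBPosterior, which: str | list[ParamKey]
) -> tuple[list[list[int]], list[ParamKey]]:
    """Indices of prunable group-mean (commonalities) effects."""
    if isinstance(which, str):
        if which == "all":
            selected = list(peb.param_keys)
        elif which in ("a", "b", "c"):
            selected = [k for k in peb.param_keys
                        if k[0].lower() == which
                        and not (k[0] == "A" and k[1] == k[2])]
        else:
            raise ValueError(f"unknown parameter scope {which!r}")
    else:
        selected = list(which)
    idx = {key: p for p, key in enumerate(peb.param_keys)}
    groups = [[peb.beta_index(0, idx[key])] for key in selected]
    return groups, selected


def peb_bmr_auto(
    peb: PEBPosterior, which: str | list[ParamKey] = "all"
) -> tuple[PEBPosterior, list[ParamKey]]:
    """Automatic greedy BMR search over nested group models: iteratively
    prunes the group-effect parameter whose removal most increases the
    second-level free energy. Returns the reduced PEB posterior and the
    list of pruned parameter keys."""
    groups, selected = _group_mean_groups(peb, which)
    kept, _, _ = greedy_bmr_prune(peb.density, peb.prior, groups)
    pruned = [key for key, k in zip(selected, kept) if not k]
    var = np.diag(peb.prior.cov).copy()
    for g, k in zip(groups, kept):
        if not k:
            for p in g:
                var[p] = 1e-8
    dF, q_r = bmr_reduce(peb.density, peb.prior,
                         GaussianDensity(peb.prior.mean, np.diag(var)))
    reduced = PEBPosterior(
        density=q_r, prior=peb.prior, fe=peb.fe + dF, gamma=peb.gamma,
        design=peb.design, param_keys=peb.param_keys,
    )
    return reduced, pruned


class PEBOracle(EvidenceOracle):
    """Evidence oracle over nested group-mean models, scored by BMR from
    the fitted PEB posterior. Every query is a closed-form reduction —
    no model estimation is spent."""

    def __init__(self, peb: PEBPosterior,
                 which: str | list[ParamKey] = "b",
                 zero_var: float = 1e-8):
        self.peb = peb
        self.groups, self.selected = _group_mean_groups(peb, which)
        super().__init__(FreeBitSpace(len(self.groups)))
        self.zero_var = zero_var
        self.n_bmr = 0

    @property
    def known_best(self) -> str | None:
        return None

    def _evaluate(self, bitvector: str) -> Evaluation:
        var = np.diag(self.peb.prior.cov).copy()
        for b, bit in enumerate(bitvector):
            if bit == "0":
                for p in self.groups[b]:
                    var[p] = self.zero_var
        dF, q_r = bmr_reduce(
            self.peb.density, self.peb.prior,
            GaussianDensity(self.peb.prior.mean, np.diag(var)))
        self.n_bmr += 1
        p = parameter_probability(q_r.mean, q_r.sd())
        probs = np.array([p[self.groups[b][0]]
                          for b in range(len(bitvector))])
        return Evaluation(fe=self.peb.fe + dF, bit_probabilities=probs)


def peb_topological_search(
    peb: PEBPosterior,
    algorithm: str = "ges",
    which: str | list[ParamKey] = "b",
    config: SearchConfig | None = None,
    seed: int | None = None,
) -> tuple[SearchResult, list[ParamKey]]:
    """Topological search (GES / GHD / GA) over nested group-mean models,
    with evidence supplied by BMR from the fitted PEB posterior.

    GES and GHD start from the full group model; GA starts from randomized
    connectivity. Only the presence/absence of group-mean effects is
    searched — covariate effects (e.g. the laterality index) are never
    mutated. Returns the search result plus the keys of removed effects.
    """
    oracle = PEBOracle(peb, which=which)
    base = config or SearchConfig()
    init = "random" if algorithm.rstrip("'") == "ga" else "full"
    cfg = SearchConfig(**{**base.__dict__, "algorithm": algorithm,
                          "seed": seed if seed is not None else base.seed,
                          "init": init})
    res = run_search(oracle, cfg)
    removed = [key for key, bit in zip(oracle.selected, res.final_bitvector)
               if bit == "0"]
    return res, removed
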