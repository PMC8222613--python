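"""Posterior estimation for DCMs: variational Laplace (VL) and Bayesian
model reduction (BMR).

VL maximizes the variational free energy

    Fe = accuracy - complexity,   complexity = KL(q || prior),

a lower bound on log model evidence, under a Gaussian approximation q to the
posterior over the free parameters. The loop is a Gauss-Newton ascent with
Levenberg-style step control, interleaved with Newton updates of the
observation-noise log-precision lambda (single hyperparameter, Gaussian
hyperprior). Gradients of the BOLD prediction are finite differences,
evaluated in one batched integrator call.

BMR evaluates any nested model (a model whose prior only shrinks variances
of the full model's prior) in closed form from the full model's posterior,
without touching the data. It is exact for linear-Gaussian models; for DCM
it is the standard fast approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .forward import (
    BOLDDataset,
    HemodynamicParams,
    IntegrationError,
    NeuralParams,
    predict_bold_batch,
)
from .model_space import ModelRecord, ModelStructure

__all__ = [
    "GaussianDensity",
    "PriorSpec",
    "PosteriorEstimate",
    "FreeEnergy",
    "default_priors",
    "variational_laplace",
    "free_energy",
    "gaussian_kl",
    "parameter_probability",
    "bmr_reduce",
    "posterior_to_record",
]


@dataclass
class GaussianDensity:
    """A multivariate Gaussian over the free parameters."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")
        asym = np.abs(self.cov - self.cov.T).max() if self.cov.size else 0.0
        if asym > 1e-8 * max(1.0, np.abs(self.cov).max()):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if self.cov.size:
            w = np.linalg.eigvalsh(self.cov)
            if w.min() < -1e-8 * max(1.0, w.max()):
                raise ValueError("covariance must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


# parameter keys: ("A", i, j) — diagonal entries are self-decay log-scalings;
# ("B", k, i, j); ("C", i, k); ("Hkappa", i); ("Htau", i) — hemodynamic
# log-scalings of the per-region defaults.
ParamKey = tuple


@dataclass
class PriorSpec:
    """Gaussian prior over the free parameter vector plus the hyperprior on
    the observation-noise log-precision lambda. Structure-off parameters are
    excluded from the free set entirely."""

    keys: list[ParamKey]
    density: GaussianDensity
    lambda_mean: float = 0.0
    lambda_var: float = 16.0

    def __post_init__(self) -> None:
        if len(self.keys) != self.density.dim:
            raise ValueError("prior dimension does not match parameter keys")


# default prior variances per parameter block
PRIOR_VAR = {
    "A_off": 0.5,           # between-region coupling (Hz); the 8/n^2 DCM
                            # convention at n = 4
    "A_self": 1.0 / 64.0,   # self-decay log-scaling (unitless)
    "B": 0.25,              # modulatory effects (Hz; sd 0.5 keeps
                            # plausible modulations within ~1 Hz)
    "C": 0.25,              # driving effects (Hz)
    "H": 1.0 / 256.0,       # hemodynamic log-scalings (tight around defaults)
}


def free_parameter_keys(
    structure: ModelStructure, estimate_hemo: bool = True
) -> list[ParamKey]:
    """Ordered free-parameter set of a structure: all present A entries
    (diagonal always), present B and C entries, then per-region hemodynamic
    log-scalings (kappa, tau)."""
    n = structure.A.shape[0]
    keys: list[ParamKey] = []
    for i in range(n):
        for j in range(n):
            if i == j or structure.A[i, j]:
                keys.append(("A", i, j))
    m = structure.B.shape[0]
    for k in range(m):
        for i in range(n):
            for j in range(n):
                if structure.B[k, i, j]:
                    keys.append(("B", k, i, j))
    for i in range(n):
        for k in range(structure.C.shape[1]):
            if structure.C[i, k]:
                keys.append(("C", i, k))
    if estimate_hemo:
        for i in range(n):
            keys.append(("Hkappa", i))
        for i in range(n):
            keys.append(("Htau", i))
    return keys


def default_priors(
    structure: ModelStructure, estimate_hemo: bool = True
) -> PriorSpec:
    """Zero-mean block priors: loose on between-region A/B/C, tighter on
    self-decay scalings, tight on hemodynamic scalings."""
    keys = free_parameter_keys(structure, estimate_hemo)
    var = np.empty(len(keys))
    for p, key in enumerate(keys):
        if key[0] == "A":
            var[p] = PRIOR_VAR["A_self"] if key[1] == key[2] else PRIOR_VAR["A_off"]
        elif key[0] == "B":
            var[p] = PRIOR_VAR["B"]
        elif key[0] == "C":
            var[p] = PRIOR_VAR["C"]
        else:
            var[p] = PRIOR_VAR["H"]
    return PriorSpec(
        keys=keys,
        density=GaussianDensity(np.zeros(len(keys)), np.diag(var)),
    )


def _theta_to_params(
    theta: np.ndarray, keys: list[ParamKey], structure: ModelStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map a parameter vector onto (A, B, C, kappa-scale, tau-scale)."""
    n = structure.A.shape[0]
    m = structure.B.shape[0]
    i_d = structure.C.shape[1]
    A = np.zeros((n, n))
    B = np.zeros((m, n, n))
    C = np.zeros((n, i_d))
    hk = np.zeros(n)
    ht = np.zeros(n)
    for p, key in enumerate(keys):
        if key[0] == "A":
            A[key[1], key[2]] = theta[p]
        elif key[0] == "B":
            B[key[1], key[2], key[3]] = theta[p]
        elif key[0] == "C":
            C[key[1], key[2]] = theta[p]
        elif key[0] == "Hkappa":
            hk[key[1]] = theta[p]
        else:
            ht[key[1]] = theta[p]
    return A, B, C, hk, ht


class _Predictor:
    """Batched BOLD prediction over parameter vectors for one structure."""

    def __init__(self, data: BOLDDataset, structure: ModelStructure,
                 keys: list[ParamKey], hemo: HemodynamicParams,
                 n_substeps: int = 1):
        self.data = data
        self.structure = structure
        self.keys = keys
        self.hemo = hemo
        self.n_substeps = n_substeps
        n = structure.A.shape[0]
        self.base = hemo.per_region(n)  # kappa, gamma, tau, alpha, e0, eff

    def __call__(self, thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        nb = thetas.shape[0]
        n = self.structure.A.shape[0]
        A = np.empty((nb, n, n))
        B = np.empty((nb,) + self.structure.B.shape)
        C = np.empty((nb,) + self.structure.C.shape)
        kappa = np.empty((nb, n))
        tau = np.empty((nb, n))
        for b in range(nb):
            Ab, Bb, Cb, hk, ht = _theta_to_params(
                thetas[b], self.keys, self.structure)
            A[b], B[b], C[b] = Ab, Bb, Cb
            kappa[b] = self.base[0] * np.exp(hk)
            tau[b] = self.base[2] * np.exp(ht)
        rep = lambda v: np.broadcast_to(v, (nb, n)).copy()
        hemo = (kappa, rep(self.base[1]), tau, rep(self.base[3]),
                rep(self.base[4]), rep(self.base[5]))
        y = predict_bold_batch(
            A, B, C, hemo, self.hemo.v0, self.data.design, self.data.tr,
            self.data.n_scans, self.n_substeps,
        )
        return y.reshape(nb, -1)


@dataclass
class FreeEnergy:
    total: float
    accuracy: float
    complexity: float


def gaussian_kl(q: GaussianDensity, p: GaussianDensity) -> float:
    """KL(q || p) between two Gaussians, in nats."""
    d = q.dim
    if p.dim != d:
        raise ValueError("dimension mismatch")
    if d == 0:
        return 0.0
    sign_p, logdet_p = np.linalg.slogdet(p.cov)
    sign_q, logdet_q = np.linalg.slogdet(q.cov)
    if sign_p <= 0 or sign_q <= 0:
        raise ValueError("covariances must be positive definite for KL")
    pinv = np.linalg.inv(p.cov)
    dm = q.mean - p.mean
    return 0.5 * (
        np.trace(pinv @ q.cov) + dm @ pinv @ dm - d + logdet_p - logdet_q
    )


def free_energy(
    q: GaussianDensity,
    prior: GaussianDensity,
    residuals: np.ndarray,
    lam: float,
    jacobian: np.ndarray | None = None,
    lambda_prior: tuple[float, float] = (0.0, 16.0),
) -> FreeEnergy:
    """Laplace free energy: accuracy (expected log likelihood under q, with
    i.i.d. Gaussian noise of log-precision lam) minus complexity
    (KL(q || prior)), plus the hyperprior penalty on lam."""
    e = np.asarray(residuals, dtype=float).ravel()
    ntot = e.size
    prec = np.exp(lam)
    trace_term = 0.0
    if jacobian is not None and q.dim:
        trace_term = prec * np.einsum("ij,ik,jk->", jacobian, jacobian, q.cov)
    accuracy = -0.5 * (
        ntot * np.log(2.0 * np.pi) - ntot * lam + prec * (e @ e) + trace_term
    )
    ml, vl = lambda_prior
    accuracy += -0.5 * (lam - ml) ** 2 / vl
    complexity = gaussian_kl(q, prior)
    return FreeEnergy(total=accuracy - complexity, accuracy=accuracy,
                      complexity=complexity)


def parameter_probability(mean, sd):
    """Posterior probability that a parameter shares the sign of its mean:
    Phi(|mean| / sd). Returns 0.5 at mean = 0 and 1 in the sd -> 0 limit for
    nonzero mean."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, np.abs(mean) / np.where(sd > 0, sd, 1.0), np.inf)
        z = np.where((sd == 0) & (mean == 0), 0.0, z)
    return np.where(np.isinf(z), 1.0, stats.norm.cdf(z))


@dataclass
class PosteriorEstimate:
    """VL output: Gaussian posterior q, free energy, per-parameter sign
    probabilities, noise hyperparameter and the Fe iteration trace."""

    density: GaussianDensity
    fe: float
    accuracy: float
    complexity: float
    probability: np.ndarray
    lambda_: float
    fe_trace: list[float]
    keys: list[ParamKey]
    structure: ModelStructure
    converged: bool = True

    def matrices(self) -> dict[str, np.ndarray]:
        """Posterior means and probabilities arranged as A/B/C matrices."""
        A, B, C, _, _ = _theta_to_params(
            self.density.mean, self.keys, self.structure)
        n, m = A.shape[0], B.shape[0]
        pA = np.zeros((n, n))
        pB = np.zeros((m, n, n))
        pC = np.zeros(C.shape)
        for p, key in enumerate(self.keys):
            if key[0] == "A":
                pA[key[1], key[2]] = self.probability[p]
            elif key[0] == "B":
                pB[key[1], key[2], key[3]] = self.probability[p]
            elif key[0] == "C":
                pC[key[1], key[2]] = self.probability[p]
        return {"A": A, "B": B, "C": C, "pA": pA, "pB": pB, "pC": pC}


def variational_laplace(
    data: BOLDDataset,
    structure: ModelStructure,
    priors: PriorSpec | None = None,
    hemo: HemodynamicParams | None = None,
    max_iter: int = 128,
    tol: float = 1e-2,
    fd_step: float = 1e-4,
    estimate_hemo: bool = True,
    n_substeps: int = 1,
) -> PosteriorEstimate:
    """Gauss-Newton variational Laplace estimation of one model.

    The Fe trace is non-decreasing over accepted steps; convergence is
    declared when |dFe| < tol for 3 consecutive iterations. If the loop hits
    max_iter first, the best-so-far estimate is returned with
    ``converged=False``.
    """
    hemo = hemo or HemodynamicParams()
    if priors is None:
        priors = default_priors(structure, estimate_hemo)
    keys = priors.keys
    d = len(keys)
    if data.n_regions != structure.A.shape[0]:
        raise ValueError("data and structure disagree on region count")
    predict = _Predictor(data, structure, keys, hemo, n_substeps)
    y = data.Y.ravel()
    ntot = y.size

    m0 = priors.density.mean
    S0 = priors.density.cov
    P0 = np.linalg.pinv(S0)
    theta = m0.copy()
    lam = priors.lambda_mean
    lam_prior = (priors.lambda_mean, priors.lambda_var)

    def jacobian_and_pred(th):
        batch = np.vstack([th] + [th + fd_step * np.eye(d)[i] for i in range(d)])
        preds = predict(batch)
        h0 = preds[0]
        J = (preds[1:] - h0).T / fd_step
        return h0, J

    def update_lambda(lam, e, J, n_inner=8):
        for _ in range(n_inner):
            P = np.exp(lam) * (J.T @ J) + P0
            Sq = np.linalg.inv(P)
            tr = np.einsum("ij,ik,jk->", J, J, Sq)
            g = 0.5 * (ntot - np.exp(lam) * (e @ e + tr)) \
                - (lam - lam_prior[0]) / lam_prior[1]
            h = -0.5 * np.exp(lam) * (e @ e + tr) - 1.0 / lam_prior[1]
            step = np.clip(-g / h, -2.0, 2.0)
            # cap the log-precision: near-noiseless data otherwise drives
            # it to overflow
            lam = np.clip(lam + step, lam_prior[0] - 16.0,
                          lam_prior[0] + 16.0)
            if abs(step) < 1e-4:
                break
        return lam

    h0, J = jacobian_and_pred(theta)
    e = y - h0
    lam = update_lambda(lam, e, J)
    P = np.exp(lam) * (J.T @ J) + P0
    Sq = np.linalg.inv(P)
    q = GaussianDensity(theta, Sq)
    fe = free_energy(q, priors.density, e, lam, J, lam_prior).total
    trace = [fe]
    damping = 1.0
    stall = 0
    converged = False
    best = (fe, theta.copy(), Sq.copy(), lam, e.copy(), J.copy())

    for _ in range(max_iter):
        grad = np.exp(lam) * (J.T @ e) - P0 @ (theta - m0)
        accepted = False
        for _try in range(8):
            P_damp = P + damping * np.diag(np.diag(P))
            try:
                dtheta = np.linalg.solve(P_damp, grad)
            except np.linalg.LinAlgError:
                warnings.warn("singular curvature; regularizing")
                dtheta = np.linalg.lstsq(P_damp, grad, rcond=None)[0]
            cand = theta + dtheta
            try:
                h_c, J_c = jacobian_and_pred(cand)
            except IntegrationError:
                damping *= 4.0  # divergent proposal: shorten the step
                continue
            e_c = y - h_c
            lam_c = update_lambda(lam, e_c, J_c)
            P_c = np.exp(lam_c) * (J_c.T @ J_c) + P0
            try:
                Sq_c = np.linalg.inv(P_c)
            except np.linalg.LinAlgError:
                warnings.warn("singular curvature; regularizing")
                Sq_c = np.linalg.pinv(P_c)
            q_c = GaussianDensity(cand, 0.5 * (Sq_c + Sq_c.T))
            fe_c = free_energy(q_c, priors.density, e_c, lam_c, J_c,
                               lam_prior).total
            if fe_c > fe or _try == 7 and fe_c > fe - 1e-9:
                theta, e, J, lam, P, Sq = cand, e_c, J_c, lam_c, P_c, Sq_c
                accepted = True
                damping = max(damping / 2.0, 1.0 / 64.0)
                break
            damping *= 4.0
        if not accepted:
            converged = True  # no uphill step exists: local optimum reached
            break
        dfe = fe_c - fe
        fe = fe_c
        trace.append(fe)
        if fe > best[0]:
            best = (fe, theta.copy(), Sq.copy(), lam, e.copy(), J.copy())
        stall = stall + 1 if abs(dfe) < tol else 0
        if stall >= 3:
            converged = True
            break

    fe, theta, Sq, lam, e, J = best
    q = GaussianDensity(theta, 0.5 * (Sq + Sq.T))
    comp = free_energy(q, priors.density, e, lam, J, lam_prior)
    prob = parameter_probability(theta, q.sd())
    return PosteriorEstimate(
        density=q,
        fe=comp.total,
        accuracy=comp.accuracy,
        complexity=comp.complexity,
        probability=np.atleast_1d(prob),
        lambda_=lam,
        fe_trace=trace,
        keys=keys,
        structure=structure,
        converged=converged,
    )


def _precision(cov: np.ndarray, zero_var: float = 1e-10) -> np.ndarray:
    """Invert a prior/posterior covariance, treating (near-)zero variances as
    infinite precision capped at 1/zero_var."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    if d == 0:
        return cov.copy()
    diag = np.diag(cov).copy()
    off = cov - np.diag(diag)
    if np.abs(off).max() < 1e-15:  # diagonal case: exact elementwise limit
        return np.diag(1.0 / np.clip(diag, zero_var, None))
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate covariance; using pseudo-inverse")
        return np.linalg.pinv(cov)


def bmr_reduce(
    full_posterior: GaussianDensity,
    full_prior: GaussianDensity,
    reduced_prior: GaussianDensity,
    check_nesting: bool = True,
) -> tuple[float, GaussianDensity]:
    """Bayesian model reduction.

    Given the full model's prior and posterior and a reduced prior that only
    shrinks prior variances (a nested model), returns the log-evidence
    difference dF = log Z_reduced - log Z_full and the reduced posterior, in
    closed form. Exact for linear-Gaussian models.
    """
    d = full_posterior.dim
    if full_prior.dim != d or reduced_prior.dim != d:
        raise ValueError("dimension mismatch between densities")
    if check_nesting:
        v_full = np.diag(full_prior.cov)
        v_red = np.diag(reduced_prior.cov)
        if np.any(v_red > v_full * (1 + 1e-9) + 1e-12):
            raise ValueError(
                "reduced prior is not nested: variances must only shrink")
    P0 = _precision(full_prior.cov)
    Pq = _precision(full_posterior.cov)
    Pr = _precision(reduced_prior.cov)
    m0, mq, mr = full_prior.mean, full_posterior.mean, reduced_prior.mean
    Pqr = Pq + Pr - P0
    try:
        Sqr = np.linalg.inv(Pqr)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate reduced precision; using pseudo-inverse")
        Sqr = np.linalg.pinv(Pqr)
    mqr = Sqr @ (Pq @ mq + Pr @ mr - P0 @ m0)

    def _slogdet(M):
        sign, ld = np.linalg.slogdet(M)
        if sign <= 0:
            raise ValueError("non-positive-definite precision in reduction")
        return ld

    dF = 0.5 * (
        _slogdet(Pr) - _slogdet(P0) + _slogdet(Pq) - _slogdet(Pqr)
    ) - 0.5 * (
        mr @ Pr @ mr - m0 @ P0 @ m0 + mq @ Pq @ mq - mqr @ Pqr @ mqr
    )
    return float(dF), GaussianDensity(mqr, 0.5 * (Sqr + Sqr.T))


def posterior_to_record(
    est: PosteriorEstimate, model_id: int
) -> ModelRecord:
    """Package a VL posterior as a model-space database row."""
    mats = est.matrices()
    return ModelRecord(
        id=model_id,
        bitvector=est.structure.bitvector,
        fe=est.fe,
        A=mats["A"], B=mats["B"], C=mats["C"],
        pA=mats["pA"], pB=mats["pB"], pC=mats["pC"],
    )
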