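"""Bilinear neural dynamics coupled to the Balloon-Windkessel hemodynamic
model: the generative forward model that maps DCM parameters to BOLD.

Neural states x (one per region) evolve as

    dx/dt = (A + sum_k u_k B_k) x + C u

a bilinear Taylor approximation of network dynamics around the resting point
f(0, 0) = 0. Diagonal entries of A (and of each B_k) are unitless
log-scaling factors of a fixed -0.5 Hz self-decay, so the effective
self-connection -0.5 * exp(a_ii + sum_k u_k b_ii,k) is negative for any real
parameter value.

Each region's neural activity drives a vasodilatory signal s, inflow f,
venous volume v and deoxyhemoglobin content q:

    ds/dt = eff * x - kappa * s - gamma * (f - 1)
    df/dt = s
    tau * dv/dt = f - v**(1/alpha)
    tau * dq/dt = f * E(f, E0)/E0 - v**(1/alpha) * q/v

with E(f, E0) = 1 - (1 - E0)**(1/f) the oxygen extraction fraction. The
observed BOLD signal (percent change) is

    y = 100 * V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))

with k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2. Flow, volume and dHb are
integrated in log space so positivity is structural. The integrator is a
fixed-step classical Runge-Kutta (RK4) scheme at microtime resolution
(default TR/16).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_space import ConstraintSpec, ModelStructure

__all__ = [
    "NeuralParams",
    "HemodynamicParams",
    "StimulusDesign",
    "BOLDDataset",
    "IntegrationError",
    "neural_derivative",
    "predict_bold",
    "predict_bold_batch",
    "hrf_curve",
    "simulate_dataset",
    "block_design",
]

SELF_DECAY = -0.5  # Hz, fixed baseline self-inhibition
MICROTIME_DIVISOR = 16  # microtime bins per scan


class IntegrationError(RuntimeError):
    pass


@dataclass
class NeuralParams:
    """Connection strengths: A (n x n, Hz; diagonal = log-scalings of the
    -0.5 Hz self-decay), B (m x n x n, Hz) per modulatory condition,
    C (n x i, Hz per unit input) per driving condition."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()
                and np.isfinite(self.C).all()):
            raise ValueError("non-finite neural parameters")

    def masked(self, structure: ModelStructure) -> "NeuralParams":
        """Zero every parameter whose structure bit is absent. Diagonal A
        entries are always kept (self-connections are always estimated)."""
        A = self.A * structure.A
        np.fill_diagonal(A, np.diag(self.A))
        return NeuralParams(A=A, B=self.B * structure.B, C=self.C * structure.C)


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel parameters, one value per region unless scalar.

    kappa: vasodilatory signal decay (1/s); gamma: autoregulatory flow
    feedback (1/s); tau: mean transit time (s); alpha: vessel stiffness
    exponent; e0: resting oxygen extraction fraction; efficacy:
    neurovascular coupling of x into s; v0: resting venous volume fraction
    (global).
    """

    kappa: np.ndarray | float = 0.64
    gamma: np.ndarray | float = 0.32
    tau: np.ndarray | float = 2.0
    alpha: np.ndarray | float = 0.32
    e0: np.ndarray | float = 0.4
    efficacy: np.ndarray | float = 1.0
    v0: float = 0.04

    def validate(self) -> None:
        for name in ("kappa", "gamma", "tau", "efficacy"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"hemodynamic parameter {name} must be positive")
        if np.any((np.asarray(self.e0) <= 0) | (np.asarray(self.e0) >= 1)):
            raise ValueError("resting oxygen extraction E0 must lie in (0, 1)")
        if np.any((np.asarray(self.alpha) <= 0) | (np.asarray(self.alpha) >= 1)):
            raise ValueError("stiffness exponent alpha must lie in (0, 1)")

    def per_region(self, n: int) -> tuple[np.ndarray, ...]:
        self.validate()
        out = []
        for name in ("kappa", "gamma", "tau", "alpha", "e0", "efficacy"):
            v = np.asarray(getattr(self, name), dtype=float)
            out.append(np.broadcast_to(v, (n,)).copy())
        return tuple(out)


@dataclass
class StimulusDesign:
    """Microtime stimulus regressors: U is (T_u x n_conditions), one column
    per condition in constraint-spec order, sampled every ``dt`` seconds."""

    U: np.ndarray
    dt: float
    condition_names: list[str]
    condition_roles: list[str]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.dt <= 0:
            raise ValueError("microtime step dt must be positive")
        if self.U.ndim != 2 or self.U.shape[1] != len(self.condition_names):
            raise ValueError("U must be (T_u, n_conditions)")

    @property
    def u_modulatory(self) -> np.ndarray:
        idx = [k for k, r in enumerate(self.condition_roles) if r == "modulatory"]
        return self.U[:, idx]

    @property
    def u_driving(self) -> np.ndarray:
        idx = [k for k, r in enumerate(self.condition_roles) if r == "driving"]
        return self.U[:, idx]


def block_design(
    spec: ConstraintSpec,
    onsets: dict[str, list[tuple[float, float]]],
    total_time: float,
    dt: float,
) -> StimulusDesign:
    """Compile (onset, duration) boxcars per condition into microtime
    regressors aligned with the constraint spec's condition order."""
    names = [c.name for c in spec.conditions]
    roles = [c.role for c in spec.conditions]
    t_u = int(round(total_time / dt))
    U = np.zeros((t_u, len(names)))
    for k, name in enumerate(names):
        for onset, duration in onsets.get(name, []):
            a = int(round(onset / dt))
            b = int(round((onset + duration) / dt))
            U[a : min(b, t_u), k] = 1.0
    return StimulusDesign(U=U, dt=dt, condition_names=names, condition_roles=roles)


@dataclass
class BOLDDataset:
    """Regional BOLD time series (T x n, percent signal change) plus the
    design that produced them and, for simulations, the ground truth."""

    Y: np.ndarray
    tr: float
    design: StimulusDesign
    region_names: list[str]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if not np.isfinite(self.Y).all():
            raise ValueError("BOLD data contain non-finite values")

    @property
    def n_scans(self) -> int:
        return self.Y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.Y.shape[1]


def neural_derivative(
    x: np.ndarray, u: np.ndarray, params: NeuralParams, roles: list[str]
) -> np.ndarray:
    """dx/dt = (A + sum_k u_k B_k) x + C u at one time point.

    ``u`` holds all condition values in spec order; ``roles`` maps them onto
    B (modulatory) and C (driving) columns. Diagonal A/B entries are treated
    as log-scalings of the -0.5 Hz self-decay.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(u).all()):
        raise ValueError("non-finite state or input")
    u_mod = u[[k for k, r in enumerate(roles) if r == "modulatory"]]
    u_drv = u[[k for k, r in enumerate(roles) if r == "driving"]]
    J = _effective_jacobian(params.A, params.B, u_mod)
    return J @ x + params.C @ u_drv


def _effective_jacobian(A, B, u_mod):
    J = A - np.diag(np.diag(A))
    diag_scale = np.diag(A).copy()
    for k in range(len(u_mod)):
        Bk = B[k]
        J = J + u_mod[k] * (Bk - np.diag(np.diag(Bk)))
        diag_scale = diag_scale + u_mod[k] * np.diag(Bk)
    return J + np.diag(SELF_DECAY * np.exp(diag_scale))


@njit(cache=True)
def _integrate_batch(Aoff, Adiag, Boff, Bdiag, C, Umod, Udrv, dt, spb, T, n_sub,
                     kappa, gamma, tau, alpha, e0, eff, v0):  # pragma: no cover
    """RK4 integration of the joint neural + hemodynamic system for a batch
    of parameter sets sharing one stimulus design.

    States per region: x, s, lf = log f, lv = log v, lq = log q.
    Returns (batch, T, n) BOLD sampled at the end of each scan, with n_sub
    RK4 substeps per microtime bin.
    """
    nb = Aoff.shape[0]
    n = Aoff.shape[1]
    m = Boff.shape[1]
    ndrv = C.shape[2]
    y = np.zeros((nb, T, n))
    x = np.zeros((nb, n))
    s = np.zeros((nb, n))
    lf = np.zeros((nb, n))
    lv = np.zeros((nb, n))
    lq = np.zeros((nb, n))
    k1x = np.zeros(n); k1s = np.zeros(n); k1f = np.zeros(n)
    k1v = np.zeros(n); k1q = np.zeros(n)
    J = np.zeros((n, n))
    dsc = np.zeros(n)
    h = dt / n_sub
    step = 0
    alive = np.ones(nb, dtype=np.bool_)
    for scan in range(T):
        for _ in range(spb):
            for b in range(nb):
                if not alive[b]:
                    continue
                # effective Jacobian for this microtime bin (input held)
                for i in range(n):
                    dsc[i] = Adiag[b, i]
                    for j in range(n):
                        J[i, j] = Aoff[b, i, j]
                for k in range(m):
                    uk = Umod[step, k]
                    if uk != 0.0:
                        for i in range(n):
                            dsc[i] += uk * Bdiag[b, k, i]
                            for j in range(n):
                                J[i, j] += uk * Boff[b, k, i, j]
                for i in range(n):
                    J[i, i] = SELF_DECAY * np.exp(dsc[i])
                drive = np.zeros(n)
                for k in range(ndrv):
                    uk = Udrv[step, k]
                    if uk != 0.0:
                        for i in range(n):
                            drive[i] += C[b, i, k] * uk
                for _sub in range(n_sub):
                    # RK4 with J, drive frozen over the microtime bin
                    xa = x[b]; sa = s[b]; lfa = lf[b]; lva = lv[b]; lqa = lq[b]
                    ax = np.zeros(n); as_ = np.zeros(n); af = np.zeros(n)
                    av = np.zeros(n); aq = np.zeros(n)
                    cx = xa.copy(); cs = sa.copy(); cf = lfa.copy()
                    cv = lva.copy(); cq = lqa.copy()
                    for stage in range(4):
                        if stage == 1 or stage == 2:
                            w = 0.5
                        elif stage == 3:
                            w = 1.0
                        else:
                            w = 0.0
                        if stage > 0:
                            for i in range(n):
                                cx[i] = xa[i] + w * h * k1x[i]
                                cs[i] = sa[i] + w * h * k1s[i]
                                cf[i] = lfa[i] + w * h * k1f[i]
                                cv[i] = lva[i] + w * h * k1v[i]
                                cq[i] = lqa[i] + w * h * k1q[i]
                        for i in range(n):
                            acc = drive[i]
                            for j in range(n):
                                acc += J[i, j] * cx[j]
                            k1x[i] = acc
                            # clamp log-states so a diverging trajectory
                            # cannot divide by zero before the guard trips
                            lfc = min(max(cf[i], -15.0), 15.0)
                            lvc = min(max(cv[i], -15.0), 15.0)
                            lqc = min(max(cq[i], -15.0), 15.0)
                            f = np.exp(lfc)
                            v = np.exp(lvc)
                            q = np.exp(lqc)
                            k1s[i] = (eff[b, i] * cx[i] - kappa[b, i] * cs[i]
                                      - gamma[b, i] * (f - 1.0))
                            k1f[i] = cs[i] / f
                            fout = v ** (1.0 / alpha[b, i])
                            k1v[i] = (f - fout) / (tau[b, i] * v)
                            ee = 1.0 - (1.0 - e0[b, i]) ** (1.0 / f)
                            k1q[i] = (f * ee / e0[b, i] - fout * q / v) / (
                                tau[b, i] * q)
                        wsum = 1.0 / 6.0 if (stage == 0 or stage == 3) else 1.0 / 3.0
                        for i in range(n):
                            ax[i] += wsum * k1x[i]
                            as_[i] += wsum * k1s[i]
                            af[i] += wsum * k1f[i]
                            av[i] += wsum * k1v[i]
                            aq[i] += wsum * k1q[i]
                    for i in range(n):
                        x[b, i] = xa[i] + h * ax[i]
                        s[b, i] = sa[i] + h * as_[i]
                        lf[b, i] = lfa[i] + h * af[i]
                        lv[b, i] = lva[i] + h * av[i]
                        lq[b, i] = lqa[i] + h * aq[i]
            step += 1
            for b in range(nb):
                if not alive[b]:
                    continue
                # divergence guard: stop integrating a runaway member
                for i in range(n):
                    if (not np.isfinite(x[b, i])) or abs(x[b, i]) > 1e6 \
                            or abs(lf[b, i]) > 15.0 or abs(lv[b, i]) > 15.0 \
                            or abs(lq[b, i]) > 15.0:
                        alive[b] = False
                        break
        for b in range(nb):
            if not alive[b]:
                for i in range(n):
                    y[b, scan, i] = np.nan
                continue
            for i in range(n):
                v = np.exp(lv[b, i])
                q = np.exp(lq[b, i])
                kk1 = 7.0 * e0[b, i]
                kk2 = 2.0
                kk3 = 2.0 * e0[b, i] - 0.2
                y[b, scan, i] = 100.0 * v0 * (
                    kk1 * (1.0 - q) + kk2 * (1.0 - q / v) + kk3 * (1.0 - v))
    return y


def predict_bold_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    hemo: tuple[np.ndarray, ...],
    v0: float,
    design: StimulusDesign,
    tr: float,
    n_scans: int,
    n_substeps: int = 1,
) -> np.ndarray:
    """Predict BOLD for a batch of parameter sets (leading axis = batch).

    A: (batch, n, n); B: (batch, m, n, n); C: (batch, n, i); hemo: tuple of
    (batch, n) arrays (kappa, gamma, tau, alpha, e0, efficacy).
    """
    A = np.ascontiguousarray(A, dtype=float)
    B = np.ascontiguousarray(B, dtype=float)
    C = np.ascontiguousarray(C, dtype=float)
    nb, n = A.shape[0], A.shape[1]
    spb = int(round(tr / design.dt))
    if abs(spb * design.dt - tr) > 1e-9 * tr or spb < 1:
        raise ValueError("microtime step must divide the repetition time")
    need = n_scans * spb
    Umod = np.ascontiguousarray(design.u_modulatory[:need], dtype=float)
    Udrv = np.ascontiguousarray(design.u_driving[:need], dtype=float)
    if Umod.shape[0] < need:
        raise ValueError(
            f"design covers {Umod.shape[0]} microtime bins, need {need}"
        )
    Adiag = np.ascontiguousarray(np.diagonal(A, axis1=1, axis2=2))
    Aoff = A.copy()
    for b in range(nb):
        np.fill_diagonal(Aoff[b], 0.0)
    Bdiag = np.ascontiguousarray(np.diagonal(B, axis1=2, axis2=3))
    Boff = B.copy()
    for b in range(nb):
        for k in range(B.shape[1]):
            np.fill_diagonal(Boff[b, k], 0.0)
    kappa, gamma, tau, alpha, e0, eff = (
        np.ascontiguousarray(h, dtype=float) for h in hemo
    )
    y = _integrate_batch(
        Aoff, Adiag, Boff, Bdiag, C, Umod, Udrv, design.dt, spb, n_scans,
        n_substeps, kappa, gamma, tau, alpha, e0, eff, v0,
    )
    if not np.isfinite(y).all():
        b, scan, reg = np.argwhere(~np.isfinite(y))[0]
        raise IntegrationError(
            f"integration diverged in region {int(reg)} at scan {int(scan)}"
        )
    return y


def predict_bold(
    structure: ModelStructure,
    neural: NeuralParams,
    hemo: HemodynamicParams,
    design: StimulusDesign,
    tr: float,
    n_scans: int,
    n_substeps: int = 1,
) -> np.ndarray:
    """Noiseless predicted BOLD (n_scans x n regions, percent signal change)
    for one model. Parameters are masked by the structure first."""
    p = neural.masked(structure)
    n = p.A.shape[0]
    hr = tuple(h[None, :] for h in hemo.per_region(n))
    y = predict_bold_batch(
        p.A[None], p.B[None], p.C[None], hr, hemo.v0, design, tr, n_scans,
        n_substeps,
    )
    return y[0]


def hrf_curve(
    hemo: HemodynamicParams,
    duration: float = 32.0,
    dt: float = 0.125,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hemodynamic response of one region to a unit-area driving impulse.

    Runs the same integrator as :func:`predict_bold` on a one-region model
    (self-decay at its -0.5 Hz default, no modulation) whose single driving
    input is a one-bin impulse of area ``amplitude``. Returns (t, y) sampled
    every ``dt`` seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t_u = int(round(duration / dt))
    U = np.zeros((t_u, 1))
    U[0, 0] = amplitude / dt
    design = StimulusDesign(
        U=U, dt=dt, condition_names=["impulse"], condition_roles=["driving"]
    )
    hr = tuple(h[None, :] for h in hemo.per_region(1))
    y = predict_bold_batch(
        np.zeros((1, 1, 1)), np.zeros((1, 0, 1, 1)), np.ones((1, 1, 1)),
        hr, hemo.v0, design, tr=dt, n_scans=t_u,
    )
    t = dt * np.arange(1, t_u + 1)
    return t, y[0, :, 0]


def simulate_dataset(
    structure: ModelStructure,
    neural: NeuralParams,
    hemo: HemodynamicParams,
    design: StimulusDesign,
    tr: float,
    n_scans: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    region_names: list[str] | None = None,
) -> BOLDDataset:
    """Simulate a BOLD dataset: predicted signal plus i.i.d. Gaussian noise.

    The generative structure, parameters and seed are recorded in
    ``ground_truth`` for recovery studies.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    y = predict_bold(structure, neural, hemo, design, tr, n_scans)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    names = region_names or list(structure.spec.region_names)
    return BOLDDataset(
        Y=y,
        tr=tr,
        design=design,
        region_names=names,
        ground_truth={
            "structure": structure,
            "neural": neural,
            "hemo": hemo,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
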