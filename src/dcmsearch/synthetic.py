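"""Synthetic model-space landscapes with planted optima.

These generators produce fully specified model-space tables — free energy,
distances and per-parameter posterior probabilities for every valid model —
so search and inference machinery can be exercised and characterized
without any DCM estimation.

The *additive* landscape scores every model by its Hamming distance to a
planted optimum,

    Fe(model) = fe_base - gain * Hd(model, optimum) + noise ,

where the i.i.d. Gaussian noise (absent by default) is clipped so the
planted optimum always keeps strictly maximal Fe. Noiseless, the landscape
is unimodal: the optimum is its only local optimum, and corr(dFe, Hd) = 1.
A requested target correlation rho < 1 is hit by deriving the noise scale
from sd(Hd) over the space: rho = gain*sd(Hd) / sqrt(gain^2 sd(Hd)^2 +
sigma^2). The *rugged* landscape adds epistatic pair rewards that carve
additional local optima without beating the planted one.

Synthetic per-parameter probabilities are a logistic map of each bit's
weight, sharpened by a tunable factor — an invention of this package (real
probabilities come from DCM posteriors), chosen so that probability-guided
search variants are testable: bits present in the optimum get p > 1/2,
bits absent from it p < 1/2, saturating to {1, 0} as sharpness grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_space import (
    ConstraintSpec,
    ModelRecord,
    ModelSpaceTable,
    annotate_table,
    hamming_bits,
)

__all__ = ["LandscapeSpec", "generate_landscape", "landscape_report",
           "LandscapeReport"]


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic fitness landscape over a constraint space."""

    constraints: ConstraintSpec
    optimum: str | None = None  # planted optimum bitvector (random if None)
    kind: str = "additive"  # additive | rugged
    rho: float = 1.0  # target corr(dFe, Hd) in (0, 1]
    noise_scale: float | None = None  # i.i.d. Fe noise sd (derived from
    # rho when None)
    sharpness: float = 4.0  # probability saturation
    fe_base: float = 0.0
    gain: float = 3.0  # per-bit Fe cost (nats)
    n_epistatic_pairs: int = 3  # rugged only
    seed: int | None = None
    guard: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("target correlation rho must lie in (0, 1]")
        if self.kind not in ("additive", "rugged"):
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        if self.noise_scale is not None and self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


def generate_landscape(spec: LandscapeSpec) -> ModelSpaceTable:
    """Generate a fully annotated synthetic model-space table.

    Every valid structure receives an Fe from the additive (or rugged)
    construction, and probability matrices whose free-bit entries follow
    the logistic sharpness map. Raises if the achieved dFe-Hd correlation
    falls short of the requested one by more than 0.15 (infeasible noise).
    """
    cons = spec.constraints
    nb = cons.n_free_bits
    if nb > spec.guard:
        raise ValueError(f"{nb} free bits exceeds guard {spec.guard}")
    rng = np.random.default_rng(spec.seed)

    if spec.optimum is None:
        while True:
            opt = "".join(rng.choice(["0", "1"], size=nb))
            if cons.is_valid_bits(opt):
                break
    else:
        opt = spec.optimum
        if len(opt) != nb or not cons.is_valid_bits(opt):
            raise ValueError("planted optimum invalid under constraints")
    opt_bits = np.array([int(c) for c in opt])

    valid_bvs = []
    hds = []
    opt_int = int(opt, 2) if nb else 0
    for code in range(1 << nb):
        bv = format(code, f"0{nb}b") if nb else ""
        if cons.is_valid_bits(bv):
            valid_bvs.append(bv)
            hds.append(bin(code ^ opt_int).count("1"))
    hds = np.array(hds)

    # noise scale: explicit, or derived to hit the target dFe-Hd correlation
    if spec.noise_scale is not None:
        sigma = spec.noise_scale
    elif spec.rho < 1.0 and hds.std() > 0:
        sigma = spec.gain * hds.std() * np.sqrt(1.0 / spec.rho**2 - 1.0)
    else:
        sigma = 0.0

    pairs: list[tuple[int, int, float]] = []
    if spec.kind == "rugged":
        flat = rng.permutation(nb)
        for p in range(min(spec.n_epistatic_pairs, nb // 2)):
            i, j = int(flat[2 * p]), int(flat[2 * p + 1])
            # reward joint deviation: a local optimum at the double flip,
            # never above the planted optimum (gain < e < 2 * gain)
            pairs.append((i, j, 1.4 * spec.gain))

    # per-bit probabilities shared by all models: bits present in the
    # optimum score high, absent bits low, saturating with sharpness
    sign = 2.0 * opt_bits - 1.0
    p_bit = 1.0 / (1.0 + np.exp(-spec.sharpness * sign))

    records = []
    n = cons.n_regions
    m, i_d = cons.n_modulatory, cons.n_driving
    for bv, hd in zip(valid_bvs, hds):
        bits = np.array([int(c) for c in bv])
        diff = bits != opt_bits
        fe = spec.fe_base - spec.gain * float(hd)
        for i, j, e in pairs:
            if diff[i] and diff[j]:
                fe += e
        if sigma > 0 and bv != opt:
            # clipped below the model's distance penalty so the planted
            # optimum keeps strictly maximal Fe
            cap = 0.95 * spec.gain * hd
            fe += float(np.clip(rng.normal(0.0, sigma), -cap, cap))
        A = cons.fixed_on_a.astype(float)
        B = cons.fixed_on_b.astype(float)
        C = cons.fixed_on_c.astype(float)
        pA = cons.fixed_on_a.astype(float)
        pB = cons.fixed_on_b.astype(float)
        pC = cons.fixed_on_c.astype(float)
        for b, key in enumerate(cons.bits):
            strength = 0.3 * bits[b]  # nominal synthetic posterior mean
            if key[0] == "A":
                A[key[1], key[2]] = strength
                pA[key[1], key[2]] = p_bit[b]
            elif key[0] == "B":
                B[key[1], key[2], key[3]] = strength
                pB[key[1], key[2], key[3]] = p_bit[b]
            else:
                C[key[1], key[2]] = strength
                pC[key[1], key[2]] = p_bit[b]
        records.append(ModelRecord(
            id=len(records) + 1, bitvector=bv, fe=fe,
            A=A, B=B, C=C, pA=pA, pB=pB, pC=pC,
        ))
    table = ModelSpaceTable.from_records(cons, records)
    report = annotate_table(table)
    if table.best_bitvector != opt:
        raise RuntimeError("planted optimum is not the table's best model")
    if (spec.kind == "additive" and np.isfinite(report.r)
            and report.r < spec.rho - 0.15):
        # rugged landscapes trade correlation for epistasis by design
        raise ValueError(
            f"achieved corr(dFe, Hd) = {report.r:.3f} falls short of the "
            f"requested {spec.rho}; reduce noise_scale or the target rho")
    return table


@dataclass
class LandscapeReport:
    """Joint structure of a model-space landscape."""

    r_dfe_hd: float
    p_value: float
    fe_min: float
    fe_max: float
    n_local_optima: int
    joint_hist: pd.DataFrame  # counts over (Hd, dFe bin)


def landscape_report(table: ModelSpaceTable, n_dfe_bins: int = 20
                     ) -> LandscapeReport:
    """Summarize an annotated table: corr(dFe, Hd), Fe range, the joint
    dFe-by-Hd histogram, and the exhaustive count of Hd-1 local optima."""
    report = annotate_table(table)
    df = table.df
    fe = df["Fe"].to_numpy(dtype=float)
    hd = df["Hd"].to_numpy(dtype=int)
    dfe = df["dFe"].to_numpy(dtype=float)

    fe_by_bv = dict(zip(df["Bitvector"], fe))
    nb = table.spec.n_free_bits
    n_local = 0
    for bv, f in fe_by_bv.items():
        is_opt = True
        for b in range(nb):
            nbv = bv[:b] + ("0" if bv[b] == "1" else "1") + bv[b + 1:]
            if nbv in fe_by_bv and fe_by_bv[nbv] >= f:
                is_opt = False
                break
        if is_opt:
            n_local += 1

    edges = np.linspace(0.0, max(dfe.max(), 1e-9), n_dfe_bins + 1)
    rows = []
    for h in range(int(hd.max()) + 1):
        counts, _ = np.histogram(dfe[hd == h], bins=edges)
        for k in range(n_dfe_bins):
            rows.append({"Hd": h, "dFe_low": edges[k], "dFe_high": edges[k + 1],
                         "count": int(counts[k])})
    return LandscapeReport(
        r_dfe_hd=report.r,
        p_value=report.p_value,
        fe_min=float(fe.min()),
        fe_max=float(fe.max()),
        n_local_optima=n_local,
        joint_hist=pd.DataFrame(rows),
    )
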