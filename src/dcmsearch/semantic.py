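"""Packaged configuration of the four-region semantic-decision network.

The network has four frontal regions — left ventral (lvF), left dorsal
(ldF), right ventral (rvF) and right dorsal (rdF) — and three experimental
conditions: "Pictures" and "Words" modulate connectivity, while "Task"
(all trials) drives every region directly.

The constrained model space has 16 free bits (65,536 models):

* 8 free endogenous (A) bits: the within-hemisphere dorsoventral
  connections (lvF<->ldF, rvF<->rdF) and the interhemispheric homotopic
  connections (lvF<->rvF, ldF<->rdF), in both directions. The four
  "crossed" connections (lvF<->rdF, ldF<->rvF) are fixed off — an
  assumption of this package, since only the count of free A entries is
  published, not their identity.
* 8 free modulatory (B) bits: "Pictures" and "Words" each may modulate the
  four self-connections.
* C is fixed: "Task" drives all four regions.
"""

from __future__ import annotations

import numpy as np

from .model_space import Condition, ConstraintSpec

__all__ = [
    "REGIONS",
    "CONDITIONS",
    "semantic_constraints",
    "TRUE_STRUCTURE_BITS",
    "semantic_benchmark",
]

REGIONS = ["lvF", "ldF", "rvF", "rdF"]
CONDITIONS = [
    Condition("Pictures", "modulatory"),
    Condition("Words", "modulatory"),
    Condition("Task", "driving"),
]

# index pairs (target i, source j) of the 8 free endogenous connections
_FREE_A = [
    (0, 1), (1, 0),  # lvF <-> ldF (left dorsoventral)
    (2, 3), (3, 2),  # rvF <-> rdF (right dorsoventral)
    (0, 2), (2, 0),  # lvF <-> rvF (ventral homotopic)
    (1, 3), (3, 1),  # ldF <-> rdF (dorsal homotopic)
]


def semantic_constraints() -> ConstraintSpec:
    """The constrained 2^16-model space of the semantic-decision network."""
    n = 4
    fixed_off_a = np.ones((n, n), dtype=bool)
    np.fill_diagonal(fixed_off_a, False)
    for i, j in _FREE_A:
        fixed_off_a[i, j] = False
    # modulation is free only on self-connections, for the 2 modulatory inputs
    fixed_off_b = np.ones((2, n, n), dtype=bool)
    for k in range(2):
        for r in range(n):
            fixed_off_b[k, r, r] = False
    # "Task" drives every region; driving inputs are fixed
    fixed_on_c = np.ones((n, 1), dtype=bool)
    return ConstraintSpec(
        n_regions=n,
        conditions=CONDITIONS,
        fixed_off_a=fixed_off_a,
        fixed_off_b=fixed_off_b,
        fixed_on_c=fixed_on_c,
        modulation_requires_connection=True,
        region_names=REGIONS,
    )


# ground-truth structure of the packaged synthetic benchmark (free bits in
# row-major A order, then B): all free endogenous connections present except
# those into rdF; "Pictures" modulates the ventral self-connections, "Words"
# the left-hemisphere ones
TRUE_STRUCTURE_BITS = "1111110010101100"


def semantic_benchmark(seed: int, snr: float = 1.0, n_scans: int = 200,
                       tr: float = 3.6):
    """A reproducible synthetic dataset shaped like the semantic-decision
    experiment: 4 regions, 3 conditions, blocked design, additive Gaussian
    noise calibrated to the requested signal-to-noise ratio (signal sd over
    noise sd).

    Connection strengths are drawn per seed from ranges a practitioner
    would consider realistic for task fMRI: between-region coupling
    0.2-0.5 Hz of either sign, self-connection modulation 0.3-0.6 Hz,
    driving effects 0.3 Hz. The 3.6 s repetition time matches the
    emulated experiment. Returns (dataset, neural_params, structure);
    the dataset also carries the ground truth.
    """
    from .forward import (HemodynamicParams, IntegrationError, NeuralParams,
                          block_design, predict_bold, simulate_dataset)

    spec = semantic_constraints()
    structure = spec.structure(TRUE_STRUCTURE_BITS)
    rng = np.random.default_rng(seed)
    n = spec.n_regions
    # redraw until the effective Jacobian is stable for every on/off
    # combination of the modulatory inputs (dynamically plausible network)
    for _ in range(200):
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and structure.A[i, j]:
                    A[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 0.5)
        B = np.zeros((2, n, n))
        for k in range(2):
            for i in range(n):
                if structure.B[k, i, i]:
                    B[k, i, i] = rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.6)
        stable = True
        for u0 in (0.0, 1.0):
            for u1 in (0.0, 1.0):
                J = A.copy()
                np.fill_diagonal(
                    J, -0.5 * np.exp(u0 * np.diag(B[0]) + u1 * np.diag(B[1])))
                if np.linalg.eigvals(J).real.max() > -0.15:
                    stable = False
        if not stable:
            continue
        C = np.full((n, 1), 0.3)
        neural = NeuralParams(A, B, C)
        hemo = HemodynamicParams()
        total = tr * n_scans
        # 20 s task cycles; Pictures and Words alternate between task blocks
        design = block_design(
            spec,
            {
                "Task": [(20.0 * c, 10.0) for c in range(int(total // 20))],
                "Pictures": [(40.0 * c, 10.0)
                             for c in range(int(total // 40))],
                "Words": [(40.0 * c + 20.0, 10.0)
                          for c in range(int(total // 40))],
            },
            total_time=total,
            dt=tr / 16.0,
        )
        try:
            signal = predict_bold(structure, neural, hemo, design, tr,
                                  n_scans)
        except IntegrationError:
            continue  # hemodynamically implausible draw; redraw
        break
    else:
        raise RuntimeError("could not draw a stable ground-truth network")
    noise_sd = float(signal.std()) / snr
    dataset = simulate_dataset(structure, neural, hemo, design, tr, n_scans,
                               noise_sd=noise_sd, seed=seed)
    return dataset, neural, structure
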