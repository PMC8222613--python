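"""Bayesian model selection across models and families.

Fixed-effects (FFX) selection sums log evidence over subjects and applies a
softmax. Random-effects (RFX) selection treats model identity as a random
effect over subjects and Gibbs-samples the population frequencies from a
Dirichlet-multinomial hierarchy, yielding expected and exceedance
probabilities.

The semantic-decision model space supports family-wise hypotheses along
three partitions of its 27 base modulation patterns (the cross of three
3-level questions): whether connectivity is modulated by words, pictures or
both (task); on the left, right or both sides (laterality); in ventral,
dorsal or both frontal regions (dorsoventral). Each base pattern carries
2^8 = 256 endogenous-connectivity variants; each partition splits the 27
patterns into three families of 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model_space import ConstraintSpec, ModelStructure, hamming_bits
from .semantic import REGIONS, semantic_constraints

__all__ = [
    "EvidenceMatrix",
    "FamilyScheme",
    "RfxResult",
    "ffx_bms",
    "rfx_gibbs",
    "build_semantic_families",
    "match_to_families",
    "family_match_summary",
]


@dataclass
class EvidenceMatrix:
    """Subjects x models log-evidence (Fe) matrix, columns keyed by model
    bitvectors (or family names)."""

    fe: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.fe = np.atleast_2d(np.asarray(self.fe, dtype=float))
        if not np.isfinite(self.fe).all():
            raise ValueError("log evidences must be finite")
        if self.fe.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")

    @property
    def n_subjects(self) -> int:
        return self.fe.shape[0]

    @property
    def n_models(self) -> int:
        return self.fe.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceMatrix":
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


def ffx_bms(evidence: EvidenceMatrix) -> np.ndarray:
    """Fixed-effects BMS: posterior model probabilities from the softmax of
    summed log evidences (overflow-guarded). Adding a constant to any
    subject's row leaves the result unchanged."""
    if evidence.n_models < 2:
        raise ValueError("need at least two models to compare")
    total = evidence.fe.sum(axis=0)
    z = total - total.max()
    p = np.exp(z)
    return p / p.sum()


@dataclass
class RfxResult:
    """Random-effects BMS output."""

    expected_probability: np.ndarray
    exceedance_probability: np.ndarray
    alpha: np.ndarray  # posterior mean Dirichlet counts
    samples: np.ndarray | None = None
    columns: list[str] | None = None


def rfx_gibbs(
    evidence: EvidenceMatrix,
    families: "FamilyScheme | None" = None,
    partition: str | None = None,
    n_samples: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
    alpha0: float = 1.0,
    keep_samples: bool = False,
) -> RfxResult:
    """Gibbs-sampled random-effects Bayesian model selection.

    Samples subject-level model assignments and population frequencies r
    under a Dirichlet(alpha0) prior; the expected probabilities are the
    posterior mean of r and the exceedance probability of model k is the
    posterior probability that r_k exceeds every other frequency. With a
    family scheme, model evidences are first aggregated into family
    evidences by log-sum-exp with a uniform within-family prior (which
    corrects for unequal family sizes) and the sampler runs over families.
    """
    if families is not None:
        evidence = families.family_evidence(evidence, partition)
    L = evidence.fe
    S, K = L.shape
    rng = np.random.default_rng(seed)
    if K == 1:
        return RfxResult(np.ones(1), np.ones(1), np.array([alpha0 + S]),
                         columns=evidence.columns)
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    r = np.full(K, 1.0 / K)
    kept = n_samples - burn_in
    r_sum = np.zeros(K)
    wins = np.zeros(K)
    samples = np.empty((kept, K)) if keep_samples else None
    if S == 0:
        # no data: posterior equals the Dirichlet prior
        draws = rng.dirichlet(np.full(K, alpha0), size=kept)
        r_mean = draws.mean(axis=0)
        xp = np.bincount(draws.argmax(axis=1), minlength=K) / kept
        return RfxResult(r_mean, xp, np.full(K, alpha0),
                         samples=draws if keep_samples else None,
                         columns=evidence.columns)
    alpha_sum = np.zeros(K)
    for it in range(n_samples):
        # subject-level assignments given frequencies
        logp = L + np.log(r)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(S)
        counts = np.zeros(K)
        cum = p.cumsum(axis=1)
        assign = (u[:, None] > cum).sum(axis=1)
        for a in assign:
            counts[a] += 1
        # population frequencies given assignments
        alpha = alpha0 + counts
        r = rng.dirichlet(alpha)
        if it >= burn_in:
            r_sum += r
            wins[np.argmax(r)] += 1
            alpha_sum += alpha
            if keep_samples:
                samples[it - burn_in] = r
    return RfxResult(
        expected_probability=r_sum / kept,
        exceedance_probability=wins / kept,
        alpha=alpha_sum / kept,
        samples=samples,
        columns=evidence.columns,
    )


# ---------------------------------------------------------------------------
# semantic model families
# ---------------------------------------------------------------------------

_TASK_LEVELS = ("Pictures", "Words", "Both tasks")
_LAT_LEVELS = ("Left", "Right", "Both sides")
_DV_LEVELS = ("Ventral", "Dorsal", "Both levels")

_LAT_REGIONS = {"Left": {"lvF", "ldF"}, "Right": {"rvF", "rdF"},
                "Both sides": set(REGIONS)}
_DV_REGIONS = {"Ventral": {"lvF", "rvF"}, "Dorsal": {"ldF", "rdF"},
               "Both levels": set(REGIONS)}


@dataclass
class BasePattern:
    """One of the 27 base modulation patterns: which conditions modulate
    which regions' self-connections, tagged with its family per partition."""

    name: str
    bits: str  # modulation bits in constraint-spec bit order
    family: dict[str, str]  # partition -> family name


@dataclass
class FamilyScheme:
    """Three 3-way partitions of the base modulation patterns, plus the
    assignment of every full-space model to a family via its modulation
    bits."""

    spec: ConstraintSpec
    patterns: list[BasePattern]
    partitions: list[str] = field(
        default_factory=lambda: ["task", "laterality", "dorsoventral"])

    def families(self, partition: str) -> dict[str, list[BasePattern]]:
        out: dict[str, list[BasePattern]] = {}
        for pat in self.patterns:
            out.setdefault(pat.family[partition], []).append(pat)
        return out

    @property
    def modulation_bit_index(self) -> list[int]:
        return [b for b, key in enumerate(self.spec.bits) if key[0] == "B"]

    def modulation_bits(self, model: "ModelStructure | str") -> str:
        bv = model if isinstance(model, str) else model.bitvector
        return "".join(bv[b] for b in self.modulation_bit_index)

    def assign(self, model: "ModelStructure | str",
               partition: str) -> str | None:
        """Family of a model whose modulation bits exactly match a base
        pattern; None if the model lies outside all base patterns."""
        mb = self.modulation_bits(model)
        for pat in self.patterns:
            if pat.bits == mb:
                return pat.family[partition]
        return None

    def family_evidence(self, evidence: EvidenceMatrix,
                        partition: str | None) -> EvidenceMatrix:
        """Aggregate per-model evidence into per-family evidence:
        log-sum-exp over member models minus log family size (uniform
        within-family model prior)."""
        if partition is None:
            raise ValueError("family comparison requires a partition name")
        fams = self.families(partition)
        cols, L = [], []
        bits_by_fam = {
            name: {p.bits for p in pats} for name, pats in fams.items()}
        mod_bits = [self.modulation_bits(c) for c in evidence.columns]
        for name in fams:
            members = [k for k, mb in enumerate(mod_bits)
                       if mb in bits_by_fam[name]]
            if not members:
                raise ValueError(f"family {name!r} has no models in the "
                                 "evidence matrix")
            cols.append(name)
            L.append(logsumexp(evidence.fe[:, members], axis=1)
                     - np.log(len(members)))
        return EvidenceMatrix(np.column_stack(L), cols)


def build_semantic_families(spec: ConstraintSpec | None = None) -> FamilyScheme:
    """The 27 base modulation patterns of the semantic network and their
    three family partitions.

    A base pattern is the cross of three questions: which task modulates
    (Pictures / Words / both), on which side (left / right / both) and at
    which level (ventral / dorsal / both). The selected conditions modulate
    the self-connections of the regions in the intersection of the side and
    level answers.
    """
    spec = spec or semantic_constraints()
    mod_bit_keys = [key for key in spec.bits if key[0] == "B"]
    cond_names = [c.name for c in spec.modulatory_conditions]
    patterns = []
    for task, lat, dv in product(_TASK_LEVELS, _LAT_LEVELS, _DV_LEVELS):
        conds = {"Pictures"} if task == "Pictures" else (
            {"Words"} if task == "Words" else {"Pictures", "Words"})
        regions = _LAT_REGIONS[lat] & _DV_REGIONS[dv]
        bits = []
        for key in mod_bit_keys:
            _, k, i, j = key
            on = (cond_names[k] in conds and i == j
                  and spec.region_names[i] in regions)
            bits.append("1" if on else "0")
        patterns.append(BasePattern(
            name=f"{task}/{lat}/{dv}",
            bits="".join(bits),
            family={"task": task, "laterality": lat, "dorsoventral": dv},
        ))
    return FamilyScheme(spec=spec, patterns=patterns)


def match_to_families(
    found: "ModelStructure | str", scheme: FamilyScheme
) -> dict[str, dict[str, float]]:
    """Fractional family credit of a found model, per partition.

    Agreement with each base pattern is the fraction of matching modulation
    bits; the base pattern(s) with maximal agreement determine the family,
    ties splitting the credit equally across their (possibly different)
    families. Per partition the credits sum to 1.
    """
    mb = scheme.modulation_bits(found)
    nb = len(mb)
    agreement = np.array(
        [1.0 - hamming_bits(mb, pat.bits) / nb for pat in scheme.patterns])
    best = np.flatnonzero(agreement == agreement.max())
    credit: dict[str, dict[str, float]] = {}
    for partition in scheme.partitions:
        part_credit: dict[str, float] = {
            name: 0.0 for name in scheme.families(partition)}
        for idx in best:
            fam = scheme.patterns[idx].family[partition]
            part_credit[fam] += 1.0 / best.size
        credit[partition] = part_credit
    return credit


def family_match_summary(
    found_models: dict[str, list["ModelStructure | str"]],
    scheme: FamilyScheme,
    partition: str,
) -> pd.DataFrame:
    """Percentage of search results (per method) credited to each family —
    rows are families, columns methods, entries percentages summing to 100
    per column."""
    fams = list(scheme.families(partition))
    data = {}
    for method, models in found_models.items():
        col = np.zeros(len(fams))
        for model in models:
            credit = match_to_families(model, scheme)[partition]
            for f, fam in enumerate(fams):
                col[f] += credit[fam]
        data[method] = 100.0 * col / max(len(models), 1)
    return pd.DataFrame(data, index=fams)
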