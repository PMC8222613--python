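"""Model-space representation for bilinear dynamic causal models.

A DCM network structure is described by three binary pattern matrices:

* ``A`` (n x n) — endogenous, between-region coupling. ``A[i, j] = 1`` means
  region *j* influences region *i* (columns are sources). Self-connections
  (the diagonal) are always present: they encode self-inhibition and are
  always estimated.
* ``B`` (n x n per modulatory condition) — condition-dependent modulation of
  connections.
* ``C`` (n per driving condition) — direct driving effects of stimuli.

A :class:`ConstraintSpec` fixes some entries on or off and leaves the rest
free; the free entries, in a frozen order, form the *bitvector* encoding of a
:class:`ModelStructure`. The set of all valid bit assignments is the model
space. Pre-estimated spaces are kept in a :class:`ModelSpaceTable`, one row
per model, with free energy (Fe), its deficit versus the best model (dFe),
the Hamming distance to the best model (Hd), posterior-mean matrices and
per-parameter posterior probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Condition",
    "ConstraintSpec",
    "ModelStructure",
    "ModelRecord",
    "ModelSpaceTable",
    "count_models",
    "enumerate_space",
    "hamming",
    "annotate_table",
    "read_table",
    "write_table",
]


@dataclass(frozen=True)
class Condition:
    """An experimental condition and its role in the model.

    role is ``"driving"`` (enters through C) or ``"modulatory"`` (enters
    through B).
    """

    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ("driving", "modulatory"):
            raise ValueError(f"unknown condition role {self.role!r}")


class ConstraintError(ValueError):
    """Raised for inconsistent constraint masks or mismatched spaces."""


# bit descriptor: ("A", i, j) | ("B", k, i, j) | ("C", i, k)
BitKey = tuple


@dataclass
class ConstraintSpec:
    """Constraints defining a DCM model space.

    ``fixed_on``/``fixed_off`` masks select entries that are always present /
    always absent; everything else is a free bit. The diagonal of A is forced
    into ``fixed_on`` (self-inhibition is always estimated). With
    ``modulation_requires_connection`` a modulatory bit B[i, j, k] may be 1
    only when the underlying connection A[i, j] is 1.
    """

    n_regions: int
    conditions: Sequence[Condition]
    fixed_on_a: np.ndarray | None = None
    fixed_off_a: np.ndarray | None = None
    fixed_on_b: np.ndarray | None = None
    fixed_off_b: np.ndarray | None = None
    fixed_on_c: np.ndarray | None = None
    fixed_off_c: np.ndarray | None = None
    modulation_requires_connection: bool = False
    region_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        n = int(self.n_regions)
        if n < 1:
            raise ConstraintError("need at least one region")
        self.conditions = [
            c if isinstance(c, Condition) else Condition(*c) for c in self.conditions
        ]
        m, i = self.n_modulatory, self.n_driving
        self.fixed_on_a = self._mask(self.fixed_on_a, (n, n))
        self.fixed_off_a = self._mask(self.fixed_off_a, (n, n))
        self.fixed_on_b = self._mask(self.fixed_on_b, (m, n, n))
        self.fixed_off_b = self._mask(self.fixed_off_b, (m, n, n))
        self.fixed_on_c = self._mask(self.fixed_on_c, (n, i))
        self.fixed_off_c = self._mask(self.fixed_off_c, (n, i))
        # self-connections are always estimated
        np.fill_diagonal(self.fixed_on_a, True)
        if np.any(np.diag(self.fixed_off_a)):
            raise ConstraintError("diagonal of A cannot be fixed off")
        for name, on, off in (
            ("A", self.fixed_on_a, self.fixed_off_a),
            ("B", self.fixed_on_b, self.fixed_off_b),
            ("C", self.fixed_on_c, self.fixed_off_c),
        ):
            if np.any(on & off):
                raise ConstraintError(f"fixed_on and fixed_off overlap in {name}")
        if self.region_names is None:
            self.region_names = [f"R{r + 1}" for r in range(n)]
        self.region_names = list(self.region_names)
        if len(self.region_names) != n:
            raise ConstraintError("region_names length mismatch")
        self._bits: list[BitKey] = self._bit_order()
        self._bit_index = {b: p for p, b in enumerate(self._bits)}

    @staticmethod
    def _mask(m, shape):
        if m is None:
            return np.zeros(shape, dtype=bool)
        m = np.asarray(m, dtype=bool)
        if m.shape != shape:
            raise ConstraintError(f"mask shape {m.shape} != expected {shape}")
        return m.copy()

    # -- condition bookkeeping -------------------------------------------------
    @property
    def n_modulatory(self) -> int:
        return sum(c.role == "modulatory" for c in self.conditions)

    @property
    def n_driving(self) -> int:
        return sum(c.role == "driving" for c in self.conditions)

    @property
    def modulatory_conditions(self) -> list[Condition]:
        return [c for c in self.conditions if c.role == "modulatory"]

    @property
    def driving_conditions(self) -> list[Condition]:
        return [c for c in self.conditions if c.role == "driving"]

    # -- bitvector encoding ----------------------------------------------------
    def _bit_order(self) -> list[BitKey]:
        """Frozen bit order: free off-diagonal A entries row-major, then B per
        modulatory condition row-major, then C per driving condition."""
        n = self.n_regions
        bits: list[BitKey] = []
        for i in range(n):
            for j in range(n):
                if i != j and not self.fixed_on_a[i, j] and not self.fixed_off_a[i, j]:
                    bits.append(("A", i, j))
        for k in range(self.n_modulatory):
            for i in range(n):
                for j in range(n):
                    if not self.fixed_on_b[k, i, j] and not self.fixed_off_b[k, i, j]:
                        bits.append(("B", k, i, j))
        for k in range(self.n_driving):
            for i in range(n):
                if not self.fixed_on_c[i, k] and not self.fixed_off_c[i, k]:
                    bits.append(("C", i, k))
        return bits

    @property
    def bits(self) -> list[BitKey]:
        return list(self._bits)

    @property
    def n_free_bits(self) -> int:
        return len(self._bits)

    def structure(self, bitvector: str | Sequence[int]) -> "ModelStructure":
        """Decode a bitvector into a :class:`ModelStructure`."""
        bits = _as_bits(bitvector, self.n_free_bits)
        n, m, i = self.n_regions, self.n_modulatory, self.n_driving
        A = self.fixed_on_a.astype(np.int8)
        B = self.fixed_on_b.astype(np.int8)
        C = self.fixed_on_c.astype(np.int8)
        for key, val in zip(self._bits, bits):
            if key[0] == "A":
                A[key[1], key[2]] = val
            elif key[0] == "B":
                B[key[1], key[2], key[3]] = val
            else:
                C[key[1], key[2]] = val
        return ModelStructure(A=A, B=B, C=C, spec=self)

    def encode(self, structure: "ModelStructure") -> str:
        out = []
        for key in self._bits:
            if key[0] == "A":
                out.append(structure.A[key[1], key[2]])
            elif key[0] == "B":
                out.append(structure.B[key[1], key[2], key[3]])
            else:
                out.append(structure.C[key[1], key[2]])
        return "".join("1" if v else "0" for v in out)

    def is_valid_bits(self, bitvector: str | Sequence[int]) -> bool:
        """Does this bit assignment satisfy the structural constraints?"""
        if not self.modulation_requires_connection:
            return True
        bits = _as_bits(bitvector, self.n_free_bits)
        a_state = {}
        for key, val in zip(self._bits, bits):
            if key[0] == "A":
                a_state[(key[1], key[2])] = val
        for key, val in zip(self._bits, bits):
            if key[0] == "B" and val:
                i, j = key[2], key[3]
                if self.fixed_on_a[i, j]:
                    continue
                if self.fixed_off_a[i, j] or not a_state.get((i, j), 0):
                    return False
        return True

    def compatible_with(self, other: "ConstraintSpec") -> bool:
        return (
            self.n_regions == other.n_regions
            and self._bits == other._bits
            and [
                (c.name, c.role) for c in self.conditions
            ] == [(c.name, c.role) for c in other.conditions]
        )

    # -- (de)serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "n_regions": self.n_regions,
            "region_names": list(self.region_names),
            "conditions": [{"name": c.name, "role": c.role} for c in self.conditions],
            "modulation_requires_connection": self.modulation_requires_connection,
            "fixed_on_a": self.fixed_on_a.astype(int).tolist(),
            "fixed_off_a": self.fixed_off_a.astype(int).tolist(),
            "fixed_on_b": self.fixed_on_b.astype(int).tolist(),
            "fixed_off_b": self.fixed_off_b.astype(int).tolist(),
            "fixed_on_c": self.fixed_on_c.astype(int).tolist(),
            "fixed_off_c": self.fixed_off_c.astype(int).tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ConstraintSpec":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            n_regions=payload["n_regions"],
            conditions=[Condition(**c) for c in payload["conditions"]],
            fixed_on_a=np.array(payload["fixed_on_a"]),
            fixed_off_a=np.array(payload["fixed_off_a"]),
            fixed_on_b=np.array(payload["fixed_on_b"]),
            fixed_off_b=np.array(payload["fixed_off_b"]),
            fixed_on_c=np.array(payload["fixed_on_c"]),
            fixed_off_c=np.array(payload["fixed_off_c"]),
            modulation_requires_connection=payload.get(
                "modulation_requires_connection", False
            ),
            region_names=payload.get("region_names"),
        )


def _as_bits(bitvector, n: int) -> list[int]:
    if isinstance(bitvector, str):
        if len(bitvector) != n or set(bitvector) - {"0", "1"}:
            raise ValueError(f"malformed bitvector {bitvector!r} (expected {n} bits)")
        return [int(c) for c in bitvector]
    bits = [int(b) for b in bitvector]
    if len(bits) != n or any(b not in (0, 1) for b in bits):
        raise ValueError("malformed bitvector")
    return bits


@dataclass
class ModelStructure:
    """A single binary DCM network structure within a constraint space."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    spec: ConstraintSpec

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        self.B = np.asarray(self.B, dtype=np.int8)
        self.C = np.asarray(self.C, dtype=np.int8)
        if not np.all(np.diag(self.A) == 1):
            raise ValueError("self-connections must be present (diag(A) = 1)")

    @property
    def bitvector(self) -> str:
        return self.spec.encode(self)

    def is_valid(self) -> bool:
        return self.spec.is_valid_bits(self.bitvector)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelStructure)
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.B, other.B)
            and np.array_equal(self.C, other.C)
        )


def count_models(constraints: ConstraintSpec) -> tuple[float, int]:
    """Number of valid models in a constraint space.

    Returns ``(log2_count, exact_count)``. Without
    ``modulation_requires_connection`` this is 2**n_free_bits; with it, free
    modulatory bits are gated by their underlying connection and counting
    proceeds per gating group. For a fully unconstrained space of n regions
    and i inputs (every input both driving and modulating) the log2 count
    equals (n^2 - n) + i*n^2 + i*n.
    """
    spec = constraints
    if not spec.modulation_requires_connection:
        exact = 1 << spec.n_free_bits
        return float(spec.n_free_bits), exact

    # group free B bits by the A entry that gates them
    free_b_by_entry: dict[tuple[int, int], int] = {}
    fixed_on_b_entries: set[tuple[int, int]] = set()
    for key in spec.bits:
        if key[0] == "B":
            free_b_by_entry[(key[2], key[3])] = free_b_by_entry.get((key[2], key[3]), 0) + 1
    for k in range(spec.n_modulatory):
        for i in range(spec.n_regions):
            for j in range(spec.n_regions):
                if spec.fixed_on_b[k, i, j]:
                    if spec.fixed_off_a[i, j]:
                        raise ConstraintError(
                            f"B fixed on at ({i},{j}) but A fixed off there"
                        )
                    fixed_on_b_entries.add((i, j))

    free_a = {(k[1], k[2]) for k in spec.bits if k[0] == "A"}
    exact = 1
    for entry, g in free_b_by_entry.items():
        if spec.fixed_on_a[entry[0], entry[1]]:
            exact *= 1 << g
        elif spec.fixed_off_a[entry[0], entry[1]]:
            pass  # all gated B bits forced to 0: one assignment
        elif entry in fixed_on_b_entries:
            exact *= 1 << g  # A forced on by a fixed-on modulation
        else:
            exact *= (1 << g) + 1  # A on with any B, or A off with B all 0
    # A entries forced on by fixed-on B carry no freedom of their own
    forced_a = {
        e for e in free_a if e in fixed_on_b_entries and not spec.fixed_on_a[e[0], e[1]]
    }
    n_plain_a = len(free_a - set(free_b_by_entry) - forced_a)
    n_free_c = sum(1 for k in spec.bits if k[0] == "C")
    exact <<= n_plain_a + n_free_c
    return float(np.log2(exact)), exact


def unconstrained_log2_count(n: int, i: int) -> int:
    """log2 cardinality of the unconstrained bilinear model space with n
    regions and i inputs (each input both driving and modulatory):
    (n^2 - n) + i*n^2 + i*n."""
    return (n * n - n) + i * n * n + i * n


def enumerate_space(
    constraints: ConstraintSpec, guard: int = 20
) -> Iterator[ModelStructure]:
    """Yield every valid model structure exactly once, in ascending bitvector
    order. Refuses spaces with more than ``guard`` free bits."""
    nb = constraints.n_free_bits
    if nb > guard:
        raise ConstraintError(
            f"space has {nb} free bits (2^{nb} assignments) which exceeds the "
            f"guard of {guard}"
        )
    for code in range(1 << nb):
        bitvector = format(code, f"0{nb}b") if nb else ""
        if constraints.is_valid_bits(bitvector):
            yield constraints.structure(bitvector)


def hamming(m1: ModelStructure, m2: ModelStructure) -> int:
    """Number of differing connectivity edges (free bits) between two models
    of the same space."""
    if not m1.spec.compatible_with(m2.spec):
        raise ConstraintError("models come from different constraint spaces")
    return hamming_bits(m1.bitvector, m2.bitvector)


def hamming_bits(b1: str, b2: str) -> int:
    if len(b1) != len(b2):
        raise ConstraintError("bitvector length mismatch")
    return sum(c1 != c2 for c1, c2 in zip(b1, b2))


# ---------------------------------------------------------------------------
# model-space database
# ---------------------------------------------------------------------------


@dataclass
class ModelRecord:
    """One row of a model-space database (Fe, distances, posterior summary)."""

    id: int
    bitvector: str
    fe: float
    dfe: float | None = None
    hd: int | None = None
    A: np.ndarray | None = None
    B: np.ndarray | None = None  # (m, n, n)
    C: np.ndarray | None = None  # (n, i)
    pA: np.ndarray | None = None
    pB: np.ndarray | None = None
    pC: np.ndarray | None = None


def _matrix_columns(spec: ConstraintSpec) -> list[tuple[str, str, tuple]]:
    """Flattened, 1-indexed column layout for the CSV schema."""
    n, m, i = spec.n_regions, spec.n_modulatory, spec.n_driving
    cols = []
    for prefix, mat in (("A", "A"), ("pA", "pA")):
        for r in range(n):
            for c in range(n):
                cols.append((f"{prefix}_{r + 1}_{c + 1}", mat, (r, c)))
    for k in range(m):
        for prefix, mat in ((f"B{k + 1}", "B"), (f"pB{k + 1}", "pB")):
            for r in range(n):
                for c in range(n):
                    cols.append((f"{prefix}_{r + 1}_{c + 1}", mat, (k, r, c)))
    for prefix, mat in (("C", "C"), ("pC", "pC")):
        for r in range(n):
            for k in range(i):
                cols.append((f"{prefix}_{r + 1}_{k + 1}", mat, (r, k)))
    return cols


class ModelSpaceTable:
    """A collection of estimated models keyed by bitvector.

    Backed by a pandas DataFrame in the flattened CSV schema (ID, Fe, dFe,
    Hd, Bitvector, then per-entry matrix columns such as ``A_1_2``).
    Lookup by bitvector is O(1) after load.
    """

    def __init__(self, spec: ConstraintSpec, df: pd.DataFrame):
        self.spec = spec
        self.df = df.reset_index(drop=True)
        if self.df["Bitvector"].duplicated().any():
            raise ValueError("duplicate bitvectors in model-space table")
        self._pos = {bv: p for p, bv in enumerate(self.df["Bitvector"])}
        self._validate()

    # -- construction ----------------------------------------------------------
    @classmethod
    def from_records(
        cls, spec: ConstraintSpec, records: Sequence[ModelRecord]
    ) -> "ModelSpaceTable":
        if not records:
            raise ValueError("empty model-space table")
        cols = _matrix_columns(spec)
        rows = []
        for rec in records:
            row = {
                "ID": rec.id,
                "Fe": rec.fe,
                "dFe": np.nan if rec.dfe is None else rec.dfe,
                "Hd": np.nan if rec.hd is None else rec.hd,
                "Bitvector": rec.bitvector,
            }
            mats = {"A": rec.A, "B": rec.B, "C": rec.C,
                    "pA": rec.pA, "pB": rec.pB, "pC": rec.pC}
            for name, mat, idx in cols:
                arr = mats[mat]
                row[name] = np.nan if arr is None else float(np.asarray(arr)[idx])
            rows.append(row)
        return cls(spec, pd.DataFrame(rows))

    def _validate(self) -> None:
        nb = self.spec.n_free_bits
        for pos, bv in enumerate(self.df["Bitvector"]):
            if len(bv) != nb or set(bv) - {"0", "1"}:
                raise ValueError(f"row {pos}: malformed bitvector {bv!r}")
            if not self.spec.is_valid_bits(bv):
                raise ValueError(f"row {pos}: bitvector violates constraints")
        for col in self.df.columns:
            if col.startswith("p"):
                vals = self.df[col].to_numpy(dtype=float)
                bad = np.where((vals < -1e-12) | (vals > 1 + 1e-12))[0]
                if bad.size:
                    raise ValueError(
                        f"row {int(bad[0])}: probability outside [0,1] in {col}"
                    )

    # -- access ----------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, bitvector: str) -> bool:
        return bitvector in self._pos

    @property
    def bitvectors(self) -> list[str]:
        return list(self.df["Bitvector"])

    def fe(self, bitvector: str) -> float:
        return float(self.df.at[self._pos[bitvector], "Fe"])

    def record(self, bitvector: str) -> ModelRecord:
        pos = self._pos[bitvector]
        row = self.df.iloc[pos]
        spec = self.spec
        n, m, i = spec.n_regions, spec.n_modulatory, spec.n_driving
        mats = {
            "A": np.zeros((n, n)), "pA": np.zeros((n, n)),
            "B": np.zeros((m, n, n)), "pB": np.zeros((m, n, n)),
            "C": np.zeros((n, i)), "pC": np.zeros((n, i)),
        }
        for name, mat, idx in _matrix_columns(spec):
            mats[mat][idx] = row[name]
        return ModelRecord(
            id=int(row["ID"]),
            bitvector=row["Bitvector"],
            fe=float(row["Fe"]),
            dfe=None if pd.isna(row["dFe"]) else float(row["dFe"]),
            hd=None if pd.isna(row["Hd"]) else int(row["Hd"]),
            A=mats["A"], B=mats["B"], C=mats["C"],
            pA=mats["pA"], pB=mats["pB"], pC=mats["pC"],
        )

    def bit_probabilities(self, bitvector: str) -> np.ndarray:
        """Per-free-bit posterior probabilities for one model, in bit order."""
        pos = self._pos[bitvector]
        row = self.df.iloc[pos]
        out = np.empty(self.spec.n_free_bits)
        for b, key in enumerate(self.spec.bits):
            if key[0] == "A":
                col = f"pA_{key[1] + 1}_{key[2] + 1}"
            elif key[0] == "B":
                col = f"pB{key[1] + 1}_{key[2] + 1}_{key[3] + 1}"
            else:
                col = f"pC_{key[1] + 1}_{key[2] + 1}"
            out[b] = row[col]
        return out

    @property
    def best_bitvector(self) -> str:
        fe = self.df["Fe"].to_numpy(dtype=float)
        top = np.flatnonzero(fe == fe.max())
        if top.size > 1:
            warnings.warn("Fe tie for best model; lowest bitvector wins")
            return min(self.df["Bitvector"].iloc[top])
        return self.df["Bitvector"].iloc[top[0]]

    @property
    def best(self) -> ModelRecord:
        return self.record(self.best_bitvector)


@dataclass
class CorrelationReport:
    """Pearson correlation between dFe and Hd over a model space."""

    r: float
    p_value: float
    n: int


def annotate_table(table: ModelSpaceTable) -> CorrelationReport:
    """Fill dFe and Hd relative to the best (argmax-Fe) model, in place, and
    report the Pearson correlation between them.

    Idempotent: re-annotating an annotated table changes nothing.
    """
    if len(table) == 0:
        raise ValueError("empty model-space table")
    best = table.best_bitvector
    fe0 = table.fe(best)
    fe = table.df["Fe"].to_numpy(dtype=float)
    best_int = int(best, 2) if best else 0
    codes = np.array([int(bv, 2) if bv else 0 for bv in table.df["Bitvector"]])
    hd = np.array([bin(c ^ best_int).count("1") for c in codes])
    table.df["dFe"] = fe0 - fe
    table.df["Hd"] = hd
    if len(table) > 2 and np.ptp(hd) > 0 and np.ptp(fe) > 0:
        r, p = stats.pearsonr(fe0 - fe, hd)
    else:
        r, p = np.nan, np.nan
    return CorrelationReport(r=float(r), p_value=float(p), n=len(table))


def write_table(table: ModelSpaceTable, path) -> None:
    """Write a model-space table as CSV (flattened matrix columns)."""
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, spec: ConstraintSpec) -> ModelSpaceTable:
    """Read a model-space CSV, validating the schema against the space."""
    df = pd.read_csv(path, dtype={"Bitvector": str})
    required = ["ID", "Fe", "dFe", "Hd", "Bitvector"] + [
        c for c, _, _ in _matrix_columns(spec)
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"model-space file missing column(s): {', '.join(missing)}")
    df["Bitvector"] = df["Bitvector"].astype(str).str.zfill(spec.n_free_bits)
    return ModelSpaceTable(spec, df[required])
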