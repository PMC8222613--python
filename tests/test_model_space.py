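import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcmsearch.model_space import (
    Condition,
    ConstraintSpec,
    ConstraintError,
    ModelRecord,
    ModelSpaceTable,
    annotate_table,
    count_models,
    enumerate_space,
    hamming,
    read_table,
    unconstrained_log2_count,
    write_table,
)
from dcmsearch.semantic import semantic_constraints

from conftest import make_spec


class TestCounting:
    def test_unconstrained_formula(self):
        # (n^2 - n) + i n^2 + i n for the full bilinear space
        assert unconstrained_log2_count(4, 3) == 72
        assert unconstrained_log2_count(1, 0) == 0

    def test_semantic_space_has_65536_models(self, semantic_spec):
        log2n, exact = count_models(semantic_spec)
        assert exact == 65536
        assert log2n == pytest.approx(16.0)

    def test_single_region_degenerate_space(self):
        spec = ConstraintSpec(n_regions=1, conditions=[])
        log2n, exact = count_models(spec)
        assert (log2n, exact) == (0.0, 1)
        assert len(list(enumerate_space(spec))) == 1

    def test_count_agrees_with_enumeration_for_gated_modulation(self):
        # one free A bit gating one free B bit: B=1 & A=0 excluded -> 3
        fixed_off_a = np.array([[False, False], [True, False]])
        fixed_off_b = np.ones((1, 2, 2), dtype=bool)
        fixed_off_b[0, 0, 1] = False
        spec = ConstraintSpec(
            n_regions=2,
            conditions=[Condition("m", "modulatory")],
            fixed_off_a=fixed_off_a,
            fixed_off_b=fixed_off_b,
            modulation_requires_connection=True,
        )
        assert spec.n_free_bits == 2
        structures = list(enumerate_space(spec))
        assert len(structures) == 3
        assert count_models(spec)[1] == 3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(2, 3),
        n_mod=st.integers(0, 2),
        require=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    def test_count_equals_enumeration_on_random_specs(self, n, n_mod, require,
                                                      seed):
        rng = np.random.default_rng(seed)
        conditions = [Condition(f"m{k}", "modulatory") for k in range(n_mod)]
        conditions.append(Condition("d", "driving"))
        # random masks keeping the free-bit count enumerable
        fixed_off_a = rng.random((n, n)) < 0.3
        np.fill_diagonal(fixed_off_a, False)
        fixed_off_b = rng.random((n_mod, n, n)) < 0.7
        fixed_on_c = rng.random((n, 1)) < 0.5
        fixed_off_c = ~fixed_on_c & (rng.random((n, 1)) < 0.5)
        spec = ConstraintSpec(
            n_regions=n, conditions=conditions,
            fixed_off_a=fixed_off_a, fixed_off_b=fixed_off_b,
            fixed_on_c=fixed_on_c, fixed_off_c=fixed_off_c,
            modulation_requires_connection=require,
        )
        if spec.n_free_bits > 12:
            return
        assert count_models(spec)[1] == len(list(enumerate_space(spec)))

    def test_overlapping_masks_rejected(self):
        on = np.zeros((2, 2), dtype=bool)
        on[0, 1] = True
        with pytest.raises(ConstraintError):
            ConstraintSpec(n_regions=2, conditions=[],
                           fixed_on_a=on, fixed_off_a=on)

    def test_enumeration_guard(self, semantic_spec):
        with pytest.raises(ConstraintError, match="16"):
            list(enumerate_space(semantic_spec, guard=12))


class TestBitvector:
    def test_decode_encode_roundtrip(self, semantic_spec):
        rng = np.random.default_rng(0)
        for _ in range(20):
            bv = "".join(rng.choice(["0", "1"], size=16))
            assert semantic_spec.structure(bv).bitvector == bv

    def test_enumeration_order_is_ascending(self, spec9):
        bvs = [s.bitvector for s in enumerate_space(spec9, guard=9)]
        assert bvs == sorted(bvs)
        assert len(set(bvs)) == len(bvs)

    def test_constraint_spec_json_roundtrip(self, semantic_spec, tmp_path):
        path = tmp_path / "spec.json"
        semantic_spec.to_json(path)
        loaded = ConstraintSpec.from_json(path)
        assert loaded.compatible_with(semantic_spec)
        assert loaded.structure("1" * 16).bitvector == "1" * 16


class TestHamming:
    def test_identity_and_single_bit(self, spec9):
        m = spec9.structure("101010101")
        assert hamming(m, m) == 0
        m2 = spec9.structure("101010100")  # one modulation bit differs
        assert hamming(m, m2) == 1

    def test_matches_popcount_oracle(self, semantic_spec):
        rng = np.random.default_rng(7)
        for _ in range(50):
            b1 = "".join(rng.choice(["0", "1"], size=16))
            b2 = "".join(rng.choice(["0", "1"], size=16))
            expected = bin(int(b1, 2) ^ int(b2, 2)).count("1")
            assert hamming(semantic_spec.structure(b1),
                           semantic_spec.structure(b2)) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 511)] * 3))
    def test_metric_axioms(self, spec9, codes):
        a, b, c = (spec9.structure(format(x, "09b")) for x in codes)
        dab, dba = hamming(a, b), hamming(b, a)
        assert dab == dba
        assert (dab == 0) == (a.bitvector == b.bitvector)
        assert hamming(a, c) <= dab + hamming(b, c)

    def test_mismatched_spaces_rejected(self, spec9, spec12):
        with pytest.raises(ConstraintError):
            hamming(spec9.structure("0" * 9), spec12.structure("0" * 12))


def _toy_table(spec, fes):
    records = []
    n, m, i = spec.n_regions, spec.n_modulatory, spec.n_driving
    for idx, (bv, fe) in enumerate(fes):
        records.append(ModelRecord(
            id=idx + 1, bitvector=bv, fe=fe,
            A=np.zeros((n, n)), B=np.zeros((m, n, n)), C=np.zeros((n, i)),
            pA=np.zeros((n, n)), pB=np.zeros((m, n, n)), pC=np.zeros((n, i)),
        ))
    return ModelSpaceTable.from_records(spec, records)


class TestAnnotate:
    def test_two_record_arithmetic(self, spec9):
        table = _toy_table(spec9, [("000000000", 10.0), ("000000011", 7.0)])
        annotate_table(table)
        best = table.record("000000000")
        other = table.record("000000011")
        assert best.dfe == 0 and best.hd == 0
        assert other.dfe == pytest.approx(3.0) and other.hd == 2

    def test_additive_landscape_correlates(self, landscape12):
        report = annotate_table(landscape12)
        assert report.r > 0
        assert report.p_value < 1e-6
        best = landscape12.best
        assert best.dfe == 0 and best.hd == 0

    def test_idempotent(self, spec9):
        table = _toy_table(spec9, [("000000000", 1.0), ("100000000", 2.0),
                                   ("110000000", 0.5)])
        r1 = annotate_table(table)
        snapshot = table.df.copy()
        r2 = annotate_table(table)
        pd.testing.assert_frame_equal(table.df, snapshot)
        assert r1.r == r2.r or (np.isnan(r1.r) and np.isnan(r2.r))

    def test_fe_tie_breaks_to_lowest_bitvector(self, spec9):
        table = _toy_table(spec9, [("100000000", 5.0), ("010000000", 5.0)])
        with pytest.warns(UserWarning, match="tie"):
            assert table.best_bitvector == "010000000"

    def test_empty_table_rejected(self, spec9):
        with pytest.raises(ValueError):
            ModelSpaceTable.from_records(spec9, [])


class TestTableIO:
    def test_roundtrip(self, spec9, tmp_path):
        table = _toy_table(spec9, [("000000000", 1.5), ("100000001", -2.25),
                                   ("111111111", 0.125)])
        annotate_table(table)
        path = tmp_path / "space.csv"
        write_table(table, path)
        loaded = read_table(path, spec9)
        pd.testing.assert_frame_equal(loaded.df, table.df[loaded.df.columns],
                                      check_dtype=False)
        assert loaded.best_bitvector == table.best_bitvector

    def test_missing_column_is_named(self, spec9, tmp_path):
        table = _toy_table(spec9, [("000000000", 1.0)])
        annotate_table(table)
        path = tmp_path / "bad.csv"
        table.df.drop(columns=["pA_1_1"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="pA_1_1"):
            read_table(path, spec9)

    def test_probability_out_of_range_names_row(self, spec9, tmp_path):
        table = _toy_table(spec9, [("000000000", 1.0), ("100000000", 2.0)])
        annotate_table(table)
        table.df.loc[1, "pA_1_2"] = 1.7
        path = tmp_path / "bad.csv"
        table.df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_table(path, spec9)

    def test_lookup_scales(self, landscape12):
        # O(1) amortized lookup: many lookups on a 4096-row table are cheap
        import time

        bvs = landscape12.bitvectors[::7]
        t0 = time.time()
        for bv in bvs:
            landscape12.fe(bv)
        assert time.time() - t0 < 1.0

    def test_database_roundtrip_preserves_structures(self, semantic_spec,
                                                     sharp_landscape16,
                                                     tmp_path):
        path = tmp_path / "sem.csv"
        write_table(sharp_landscape16, path)
        loaded = read_table(path, semantic_spec)
        rng = np.random.default_rng(3)
        for bv in rng.choice(loaded.bitvectors, size=10, replace=False):
            rec = loaded.record(bv)
            assert semantic_spec.structure(rec.bitvector).bitvector == bv
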