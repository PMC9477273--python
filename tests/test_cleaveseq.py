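"""Read counting and fold-change statistics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cleavekit as ck
from cleavekit.cleaveseq import CountTable, fold_change_frame
from cleavekit.synthetic import DEFAULT_PREFIX_MAP, DEFAULT_SUFFIX, Condition

counts = st.integers(min_value=0, max_value=10_000)


class TestFoldChange:
    def test_symmetric_counts_give_unity(self):
        rec = ck.fold_change(50, 50, 50, 50)
        assert rec.fc == pytest.approx(1.0)
        assert rec.p_value == pytest.approx(1.0)

    def test_pseudocounted_odds_ratio(self):
        # (80.5 * 80.5) / (20.5 * 20.5) = 15.42 to 2 d.p.
        rec = ck.fold_change(80, 20, 20, 80)
        assert rec.fc == pytest.approx((80.5 * 80.5) / (20.5 * 20.5), rel=1e-12)
        assert rec.fc == pytest.approx(15.42, abs=0.005)
        assert rec.se_log_fc == pytest.approx(
            math.sqrt(2 / 80.5 + 2 / 20.5), rel=1e-12
        )

    def test_zero_reads_give_unity_with_huge_se(self):
        rec = ck.fold_change(0, 0, 0, 0)
        assert rec.fc == pytest.approx(1.0)
        assert rec.se_log_fc == pytest.approx(math.sqrt(4 / 0.5))

    def test_ci_nesting_and_containment(self):
        rec = ck.fold_change(70, 30, 25, 75)
        assert rec.ci95[0] < rec.ci90[0] < rec.fc < rec.ci90[1] < rec.ci95[1]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=counts, b=counts, c=counts, d=counts)
    def test_antisymmetry_under_condition_swap(self, a, b, c, d):
        fwd = ck.fold_change(a, b, c, d)
        rev = ck.fold_change(c, d, a, b)
        assert fwd.fc * rev.fc == pytest.approx(1.0, rel=1e-9)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.integers(1, 1000), b=st.integers(1, 1000),
           c=st.integers(1, 1000), d=st.integers(1, 1000))
    def test_se_strictly_decreases_with_any_count(self, a, b, c, d):
        base = ck.fold_change(a, b, c, d).se_log_fc
        assert ck.fold_change(a + 1, b, c, d).se_log_fc < base
        assert ck.fold_change(a, b, c + 1, d).se_log_fc < base

    def test_normalization_divides_fc(self):
        rec = ck.fold_change(80, 20, 20, 80, k=2.0)
        assert rec.fc == pytest.approx((80.5 * 80.5) / (20.5 * 20.5) / 2.0)

    def test_ci_coverage_at_moderate_depth(self):
        # 95% CI should cover a true fc of 4 in ~95% of simulations
        rng = np.random.default_rng(17)
        n, depth, fc_true = 4000, 200, 4.0
        a_ref = rng.binomial(depth, 0.5, n)
        a_test = rng.binomial(depth, 0.2, n)  # odds 0.25 = 1/fc_true
        f = fold_change_frame(a_ref, depth - a_ref, a_test, depth - a_test)
        cover = ((f["ci95_lo"] <= fc_true) & (fc_true <= f["ci95_hi"])).mean()
        assert 0.93 <= cover <= 0.97

    def test_estimator_consistency_with_depth(self):
        rng = np.random.default_rng(23)
        fc_true, errs = 3.0, []
        for depth in (100, 1000, 10_000):
            a_ref = rng.binomial(depth, 0.6, 500)
            # test odds = 1.5 / 3
            a_test = rng.binomial(depth, 1 / 3, 500)
            f = fold_change_frame(a_ref, depth - a_ref, a_test, depth - a_test)
            errs.append(float(np.mean(np.abs(f["fc"] - fc_true))))
        assert errs[0] > errs[1] > errs[2]


class TestNormalizeByReferences:
    def _frames(self, counts_ref, counts_test, ids):
        mk = lambda cnts: pd.DataFrame(
            {"cleaved": [c[0] for c in cnts], "uncleaved": [c[1] for c in cnts]},
            index=ids,
        )
        return mk(counts_ref), mk(counts_test)

    def test_identical_counts_give_unity(self):
        ref, test = self._frames(
            [(100, 100)] * 4, [(100, 100)] * 4, ["r1", "r2", "r3", "r4"]
        )
        assert ck.normalize_by_references(ref, test, ["r1", "r2", "r3", "r4"]) == 1.0

    def test_injected_odds_bias_recovered(self):
        # bias applied to the no-ligand (reference) run: k should estimate it
        # and dividing corrects reference fold changes back to ~1
        rng = np.random.default_rng(31)
        bias = 1.5
        lib = ck.generate_library(1, n_references=20, seed=5)
        refs = [r for r in lib if r.is_reference]
        models = {r.sensor_id: ck.ResponseModel(r.sensor_id, c0=0.5) for r in lib}
        t_ref = ck.simulate_cleaveseq_counts(
            lib, models, Condition("noligand"), depth=200_000, bias=bias, seed=32
        )
        t_test = ck.simulate_cleaveseq_counts(
            lib, models, Condition("ligand"), depth=200_000, bias=1.0, seed=33
        )
        ref_ids = [r.sensor_id for r in refs]
        k = ck.normalize_by_references(
            t_ref.condition("noligand"), t_test.condition("ligand"), ref_ids
        )
        assert k == pytest.approx(bias, rel=0.1)
        merged = CountTable.concat([t_ref, t_test])
        out = ck.fold_change_table(
            merged, "noligand", "ligand", reference_ids=ref_ids
        )
        ref_fc = out[out["sensor_id"].isin(ref_ids)]["fc"]
        assert np.abs(np.log(ref_fc)).mean() < 0.1

    def test_too_few_references_warn_and_default(self):
        ref, test = self._frames([(100, 100)] * 2, [(150, 50)] * 2, ["r1", "r2"])
        with pytest.warns(UserWarning):
            k = ck.normalize_by_references(ref, test, ["r1", "r2"])
        assert k == 1.0


class TestCountReads:
    def test_trivial_counts(self, tmp_path, small_library):
        table = CountTable(
            pd.DataFrame(
                {
                    "sensor_id": [small_library[0].sensor_id],
                    "condition_id": ["c"],
                    "cleaved": [3],
                    "uncleaved": [2],
                }
            )
        )
        path = ck.emit_reads(table, small_library, tmp_path / "r.fastq")
        res = ck.count_reads(
            path, DEFAULT_PREFIX_MAP, DEFAULT_SUFFIX, library=small_library,
            condition_id="c",
        )
        row = res.table.df.iloc[0]
        assert (row.cleaved, row.uncleaved) == (3, 2)
        assert res.n_unassigned == 0

    def test_round_trip_identity(self, tmp_path, small_library):
        models = {
            r.sensor_id: ck.ResponseModel(r.sensor_id, c0=0.6) for r in small_library
        }
        t = ck.simulate_cleaveseq_counts(
            small_library, models, Condition("c"), depth=20_000, seed=3
        )
        path = ck.emit_reads(t, small_library, tmp_path / "rt.fastq")
        res = ck.count_reads(
            path, DEFAULT_PREFIX_MAP, DEFAULT_SUFFIX, library=small_library,
            condition_id="c",
        )
        want = (
            t.df[t.df[["cleaved", "uncleaved"]].sum(axis=1) > 0]
            .sort_values("sensor_id")
            .reset_index(drop=True)
        )
        got = res.table.df.sort_values("sensor_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(got[want.columns], want)

    def test_mismatch_tolerance(self, tmp_path, small_library):
        rec = small_library[0]
        prefix = DEFAULT_PREFIX_MAP["cleaved"]
        mutated = ("T" if prefix[0] != "T" else "G") + prefix[1:]
        read = mutated + rec.template_seq + DEFAULT_SUFFIX
        path = tmp_path / "m.fasta"
        path.write_text(f">r1\n{read}\n")
        strict = ck.count_reads(
            path, DEFAULT_PREFIX_MAP, DEFAULT_SUFFIX, mismatch_tolerance=0
        )
        loose = ck.count_reads(
            path, DEFAULT_PREFIX_MAP, DEFAULT_SUFFIX, mismatch_tolerance=1
        )
        assert strict.n_unassigned == 1 and len(strict.table.df) == 0
        assert loose.n_unassigned == 0 and loose.table.df.iloc[0].cleaved == 1

    def test_barcoded_conditions_round_trip(self, tmp_path, small_library):
        models = {
            r.sensor_id: ck.ResponseModel(r.sensor_id, c0=0.5) for r in small_library
        }
        tables = [
            ck.simulate_cleaveseq_counts(
                small_library, models, Condition(cond), depth=2000, seed=i
            )
            for i, cond in enumerate(["c1", "c2"])
        ]
        merged = CountTable.concat(tables)
        barcodes = {"c1": "ACGT", "c2": "TGCA"}
        path = ck.emit_reads(
            merged, small_library, tmp_path / "bc.fastq", barcode_map=barcodes
        )
        res = ck.count_reads(
            path,
            DEFAULT_PREFIX_MAP,
            DEFAULT_SUFFIX,
            library=small_library,
            barcode_table={v: k for k, v in barcodes.items()},
        )
        assert set(res.table.df.condition_id) == {"c1", "c2"}
        assert res.table.df[["cleaved", "uncleaved"]].sum().sum() == 4000


class TestCallSignificant:
    def test_bonferroni_threshold(self):
        rec = fold_change_frame(80, 20, 20, 80)
        rec["p_value"] = [2.0 / 100]
        out = ck.call_significant(rec, n_tested=100)
        assert not out["significant"].iloc[0]

    def test_strong_effect_at_depth_is_significant(self):
        rec = fold_change_frame(
            np.array([160]), np.array([40]), np.array([40]), np.array([160])
        )
        out = ck.call_significant(rec, n_tested=10_000, min_reads=100)
        assert out["significant"].iloc[0]

    def test_min_reads_floor(self):
        rec = fold_change_frame(np.array([40]), np.array([10]), np.array([10]), np.array([40]))
        out = ck.call_significant(rec, n_tested=10, min_reads=100)
        assert not out["significant"].iloc[0]

    def test_null_false_positive_rate(self):
        # Bonferroni: expected family false positives ~ Poisson(1)
        rng = np.random.default_rng(41)
        n, depth = 10_000, 1000
        fps = []
        for _ in range(5):
            a1 = rng.binomial(depth, 0.5, n)
            a2 = rng.binomial(depth, 0.5, n)
            f = fold_change_frame(a1, depth - a1, a2, depth - a2)
            out = ck.call_significant(f, n_tested=n, fc_threshold=1.0)
            fps.append(int(out["significant"].sum()))
        assert np.mean(fps) <= 2.0

    def test_zero_n_tested_rejected(self):
        rec = fold_change_frame(10, 10, 10, 10)
        with pytest.raises(ck.InputError):
            ck.call_significant(rec, n_tested=0)
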