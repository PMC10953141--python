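"""Barcode count statistics: clonal reduction, TMM, NB tail test, BH, calls."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mimicry_screen import (
    DispersionParam,
    ExperimentSpec,
    Fraction,
    Group,
    ReadCountMatrix,
    SampleMeta,
    apply_negative_control,
    bh_adjust,
    call_significant,
    clonally_reduce,
    estimate_tcell_frequency,
    nb_tail_pvalue,
    normalized_log2fc,
    run_enrichment,
    simulate_barcode_experiment,
    tmm_factors,
)
from mimicry_screen.barcode_enrichment import write_results_tsv


class TestClonalReduction:
    def test_duplicate_tags_collapse_to_one(self):
        records = [("bc1", "TAG", "s1")] * 5
        m = clonally_reduce(records)
        assert m.reduced.loc["bc1", "s1"] == 1
        assert m.counts.loc["bc1", "s1"] == 5

    def test_three_distinct_tags_give_three(self):
        records = [("bc1", t, "s1") for t in ("A", "B", "C", "A", "B")]
        m = clonally_reduce(records)
        assert m.reduced.loc["bc1", "s1"] == 3

    def test_random_stream_equals_set_cardinality(self, rng):
        barcodes = [f"bc{i}" for i in range(6)]
        samples = ["s1", "s2"]
        records = [
            (rng.choice(barcodes), f"T{rng.integers(8)}", rng.choice(samples))
            for _ in range(300)
        ]
        m = clonally_reduce(records)
        for bc in barcodes:
            for s in samples:
                expected = len(
                    {t for b, t, sm in records if b == bc and sm == s}
                )
                assert m.reduced.loc[bc, s] == expected

    def test_missing_tags_fall_back_to_raw_with_warning(self):
        records = [("bc1", None, "s1")] * 4 + [("bc1", "T1", "s1")]
        with pytest.warns(UserWarning, match="lack a molecule tag"):
            m = clonally_reduce(records)
        assert m.reduced.loc["bc1", "s1"] == 5  # 4 raw + 1 deduplicated


def oracle_tmm(counts, reference, trim_m=0.30, trim_a=0.05):
    """Independent plain-python reimplementation of the trimmed,
    precision-weighted mean of log ratios (doubly trimmed by rank)."""
    totals = {c: float(counts[c].sum()) for c in counts.columns}
    ref = counts[reference]
    log_f = {}
    for c in counts.columns:
        if c == reference:
            log_f[c] = 0.0
            continue
        rows = [
            (float(xk), float(xr))
            for xk, xr in zip(counts[c], ref)
            if xk > 0 and xr > 0
        ]
        ms, as_, ws = [], [], []
        for xk, xr in rows:
            pk, pr = xk / totals[c], xr / totals[reference]
            ms.append(math.log2(pk / pr))
            as_.append(0.5 * math.log2(pk * pr))
            ws.append(
                1.0
                / (
                    (totals[c] - xk) / (totals[c] * xk)
                    + (totals[reference] - xr) / (totals[reference] * xr)
                )
            )
        n = len(ms)
        rank_m = stats.rankdata(ms)
        rank_a = stats.rankdata(as_)
        kept = [
            i
            for i in range(n)
            if n * trim_m < rank_m[i] <= n * (1 - trim_m) + 1e-9
            and n * trim_a < rank_a[i] <= n * (1 - trim_a) + 1e-9
        ]
        if not kept:
            kept = list(range(n))
        log_f[c] = sum(ws[i] * ms[i] for i in kept) / sum(ws[i] for i in kept)
    factors = {c: 2 ** log_f[c] * totals[c] / totals[reference]
               for c in counts.columns}
    g = math.exp(sum(math.log(v) for v in factors.values()) / len(factors))
    return {c: v / g for c, v in factors.items()}


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(tmm_factors(counts), [1.0, 1.0])

    def test_doubled_column_splits_symmetrically(self):
        counts = pd.DataFrame({"a": [10, 25, 40, 5], "b": [20, 50, 80, 10]})
        f = tmm_factors(counts, reference="a")
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_random_matrix_matches_independent_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(60, 4)),
            columns=["s1", "s2", "s3", "s4"],
        )
        counts += 1  # avoid all-zero columns
        got = tmm_factors(counts, reference="s2")
        expected = oracle_tmm(counts, "s2")
        for c in counts.columns:
            assert got[c] == pytest.approx(expected[c], rel=1e-12)

    def test_factors_have_unit_geometric_mean(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(40, 5)),
            columns=list("abcde"),
        )
        f = tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_support_falls_back_to_depth_scaling(self):
        counts = pd.DataFrame({"a": [5, 5, 0, 0], "b": [0, 0, 5, 5]})
        with pytest.warns(UserWarning, match="no nonzero barcodes"):
            f = tmm_factors(counts, reference="a")
        assert np.allclose(f, [1.0, 1.0])  # equal depths, composition 1


class TestLog2FC:
    def test_count_at_baseline_mean_is_zero(self):
        assert normalized_log2fc(10, [10, 10, 10]) == pytest.approx(0.0)

    def test_fourfold_approaches_two_at_large_counts(self):
        small = normalized_log2fc(40, [10, 10, 10])
        large = normalized_log2fc(40000, [10000, 10000, 10000])
        assert small < 2.0
        assert large == pytest.approx(2.0, abs=1e-3)

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            c = int(rng.integers(0, 1000))
            base = list(rng.integers(0, 1000, size=3))
            f = float(rng.uniform(0.5, 2.0))
            bf = list(rng.uniform(0.5, 2.0, size=3))
            expected = math.log2(
                (c / f + 1) / (np.mean([b / g for b, g in zip(base, bf)]) + 1)
            )
            assert normalized_log2fc(c, base, f, bf) == pytest.approx(expected)


class TestNBTail:
    def test_observed_zero_is_exactly_one(self):
        assert nb_tail_pvalue(0, 10.0) == 1.0

    def test_matches_direct_pmf_summation(self):
        mu, alpha = 10.0, 0.1
        r = 1 / alpha
        p = r / (r + mu)
        direct = float(sum(stats.nbinom.pmf(k, r, p) for k in range(40, 5000)))
        assert nb_tail_pvalue(40, mu, alpha) == pytest.approx(
            direct, abs=1e-10
        )

    @pytest.mark.parametrize("mu", [1.0, 5.0, 20.0, 50.0])
    def test_small_dispersion_limit_is_poisson(self, mu):
        for obs in (0, int(mu), int(2 * mu) + 3):
            nb = nb_tail_pvalue(obs, mu, 1e-8)
            poisson = float(stats.poisson.sf(obs - 1, mu))
            assert nb == pytest.approx(poisson, abs=1e-6)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mu"):
            nb_tail_pvalue(3, 0.0)

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError):
            DispersionParam(0.0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_permutation_invariant_in_input_order(self, rng):
        p = rng.uniform(1e-6, 1, size=25)
        perm = rng.permutation(25)
        adjusted = bh_adjust(p)
        assert bh_adjust(p[perm]) == pytest.approx(adjusted[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCalls:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["barcode", "sample_id", "log2fc", "p_value",
                           "fdr", "read_fraction"]
        )

    def test_all_gates_passing_is_significant(self):
        out = call_significant(
            self._frame([("b", "s", 3.0, 1e-5, 0.0005, 0.002)])
        )
        assert out["significant"].tolist() == [True]

    def test_log2fc_gate_is_strict(self):
        out = call_significant(
            self._frame([("b", "s", 1.9, 1e-5, 0.0005, 0.002),
                         ("b2", "s", 2.0, 1e-5, 0.0005, 0.002)])
        )
        assert out["significant"].tolist() == [False, False]

    def test_read_fraction_threshold_is_inclusive(self):
        out = call_significant(
            self._frame([("b", "s", 3.0, 1e-5, 0.0005, 0.001),
                         ("b2", "s", 3.0, 1e-5, 0.0005, 0.0009)])
        )
        assert out["significant"].tolist() == [True, False]

    def test_planted_rows_flagged_against_exhaustive_check(self, rng):
        rows = []
        for i in range(10):
            passing = i in (2, 7)
            rows.append(
                (
                    f"b{i}", "s",
                    3.5 if passing else float(rng.uniform(-1, 1.5)),
                    1e-6 if passing else 0.5,
                    1e-4 if passing else 0.9,
                    0.01 if passing else 0.0001,
                )
            )
        out = call_significant(self._frame(rows))
        expected = [
            fdr < 0.001 and lfc > 2 and frac >= 0.001
            for _, _, lfc, _, fdr, frac in rows
        ]
        assert out["significant"].tolist() == expected
        assert out["significant"].sum() == 2


class TestFrequency:
    def test_direct_product(self):
        assert estimate_tcell_frequency(0.10, 0.5) == pytest.approx(0.05)

    def test_single_barcode_limit(self):
        assert estimate_tcell_frequency(1.0, 0.73) == pytest.approx(0.73)

    def test_missing_percentage_gives_none_not_zero(self):
        assert estimate_tcell_frequency(0.5, None) is None

    def test_fractions_summing_to_one_conserve_the_percentage(self, rng):
        fractions = rng.dirichlet(np.ones(20))
        pct = 1.7
        total = sum(estimate_tcell_frequency(f, pct) for f in fractions)
        assert total == pytest.approx(pct, abs=1e-9)


class TestNegativeControl:
    def _results(self, sig_map):
        rows = []
        for (bc, s), sig in sig_map.items():
            rows.append(
                {"barcode": bc, "sample_id": s, "log2fc": 3.0,
                 "p_value": 1e-6, "fdr": 1e-5, "read_fraction": 0.01,
                 "significant": sig, "est_frequency_pct": 0.1 if sig else None}
            )
        return pd.DataFrame(rows)

    def test_clean_control_changes_nothing(self):
        res = self._results({("b1", "neg"): False, ("b1", "s1"): True})
        out, removed = apply_negative_control(res, control_sample_id="neg")
        assert removed == []
        pd.testing.assert_frame_equal(out, res)

    def test_control_positive_removed_from_all_subjects(self):
        res = self._results(
            {("b1", "neg"): True, ("b1", "s1"): True, ("b1", "s2"): True,
             ("b1", "s3"): True, ("b2", "s1"): True}
        )
        out, removed = apply_negative_control(res, control_sample_id="neg")
        assert removed == ["b1"]
        assert not out.loc[out["barcode"] == "b1", "significant"].any()
        assert out.loc[out["barcode"] == "b2", "significant"].all()

    def test_random_flags_equal_set_difference_oracle(self, rng):
        sig_map = {}
        for bc in [f"b{i}" for i in range(8)]:
            for s in ["neg", "s1", "s2"]:
                sig_map[(bc, s)] = bool(rng.random() < 0.4)
        res = self._results(sig_map)
        out, removed = apply_negative_control(res, control_sample_id="neg")
        control_set = {bc for (bc, s), v in sig_map.items()
                       if s == "neg" and v}
        assert set(removed) == control_set
        for (bc, s), was_sig in sig_map.items():
            now = out.loc[
                (out["barcode"] == bc) & (out["sample_id"] == s),
                "significant",
            ].iloc[0]
            assert now == (was_sig and bc not in control_set)

    def test_missing_control_passes_through_with_warning(self):
        res = self._results({("b1", "s1"): True})
        with pytest.warns(UserWarning, match="no negative-control"):
            out, removed = apply_negative_control(res)
        assert removed == []


class TestPipeline:
    def test_deterministic_output_bytes(self):
        spec = ExperimentSpec(n_barcodes=40, n_samples=2,
                              plants=(("bc0003", "sample-1", 32.0),))
        outputs = []
        for _ in range(2):
            matrix, _ = simulate_barcode_experiment(spec, 123)
            results = run_enrichment(matrix)
            buf = io.StringIO()
            write_results_tsv(results, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_requires_baseline_samples(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [5, 5]},
                              index=["b1", "b2"])
        samples = [
            SampleMeta("s1", Group.HS, "subj1", Fraction.SINGLE_STAINED),
            SampleMeta("s2", Group.HS, "subj1", Fraction.DOUBLE_STAINED),
        ]
        with pytest.raises(ValueError, match="baseline"):
            run_enrichment(ReadCountMatrix(counts=counts, samples=samples))

    def test_per_sample_bh_family_available(self):
        matrix, _ = simulate_barcode_experiment(
            ExperimentSpec(n_barcodes=30, n_samples=3), 9
        )
        res_global = run_enrichment(matrix, bh_family="global")
        res_local = run_enrichment(matrix, bh_family="per_sample")
        assert len(res_global) == len(res_local)
        assert (res_global["p_value"] == res_local["p_value"]).all()
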