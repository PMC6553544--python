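"""Normalization, pair divergence, DE engine, and BH adjustment."""

import math

import numpy as np
import pandas as pd
import pytest

from ohnopipe.genome_model import InheritanceMode
from ohnopipe.ohnolog_calling import OhnologPair
from ohnopipe.expression import (
    PairDivergence,
    annotate_de_with_mode,
    bh_adjust,
    de_test,
    divergence_contrast,
    filter_min_total,
    normalize,
    pair_abs_log2fc,
    seven_contrasts,
    size_factors,
)


def counts_frame(data, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    return df


def meta_frame(sample_ids, crosses, sexes):
    return pd.DataFrame({"sample_id": sample_ids, "cross": crosses, "sex": sexes})


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = counts_frame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_sample_splits_around_geometric_mean(self):
        counts = counts_frame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        factors = size_factors(counts)
        assert factors["s1"] == pytest.approx(1 / math.sqrt(2), abs=1e-4)
        assert factors["s2"] == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_gene_with_zero_excluded_from_reference(self):
        base = counts_frame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        spiked = counts_frame({"s1": [10, 20, 30, 0], "s2": [20, 40, 60, 1000]})
        assert np.allclose(size_factors(base), size_factors(spiked))

    def test_no_universal_gene_errors_unless_pseudo_reference(self):
        counts = counts_frame({"s1": [10, 0], "s2": [0, 10]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        factors = size_factors(counts, pseudo_reference=True)
        assert (factors > 0).all()

    def test_rescaling_one_sample_moves_only_relative_factors(self):
        # factors are defined up to a common scalar: tripling one sample
        # triples its factor relative to the others and leaves the
        # normalized matrix unchanged up to that common scalar
        counts = counts_frame({"s1": [10, 20, 30], "s2": [12, 25, 28]})
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 3
        f0 = size_factors(counts)
        f1 = size_factors(scaled)
        assert f1["s2"] / f1["s1"] == pytest.approx(3 * f0["s2"] / f0["s1"])
        n0 = normalize(counts, f0).to_numpy()
        n1 = normalize(scaled, f1).to_numpy()
        assert np.allclose(n1 / n0, (n1 / n0).flat[0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            size_factors(counts_frame({"s1": [1, -2]}))


class TestFilterMinTotal:
    def test_threshold_is_inclusive_at_five(self):
        counts = pd.DataFrame(
            {"s1": [3, 2, 0], "s2": [2, 2, 0]}, index=["keep", "drop", "zero"]
        )
        kept = filter_min_total(counts, 5)
        assert list(kept.index) == ["keep"]

    def test_zero_threshold_is_identity(self):
        counts = counts_frame({"s1": [0, 1], "s2": [0, 2]})
        assert filter_min_total(counts, 0).equals(counts)


class TestPairAbsLog2fc:
    def setup_method(self):
        # two identical samples -> size factors 1; exact means
        self.counts = pd.DataFrame(
            {"s1": [100, 25, 40, 40], "s2": [100, 25, 40, 40]},
            index=["gA", "gB", "gC", "gD"],
        )
        self.meta = meta_frame(["s1", "s2"], ["AxA", "AxA"], ["F", "F"])
        self.pairs = [
            OhnologPair("gA", "gB", 95.0, InheritanceMode.DISOMIC),
            OhnologPair("gC", "gD", 95.0, InheritanceMode.TETRASOMIC),
        ]

    def test_reference_value_and_equal_means(self):
        divs = pair_abs_log2fc(self.counts, self.meta, self.pairs, "AxA", "F")
        by_pair = {(d.gene_a, d.gene_b): d.abs_log2fc for d in divs}
        assert by_pair[("gA", "gB")] == pytest.approx(math.log2(100.5 / 25.5), abs=1e-9)
        assert by_pair[("gC", "gD")] == pytest.approx(0.0)

    def test_member_swap_and_global_rescaling_invariance(self):
        divs = pair_abs_log2fc(self.counts, self.meta, self.pairs, "AxA", "F")
        swapped_counts = self.counts.loc[["gB", "gA", "gD", "gC"]]
        swapped_counts.index = ["gA", "gB", "gC", "gD"]
        divs_swapped = pair_abs_log2fc(swapped_counts, self.meta, self.pairs, "AxA", "F")
        assert [d.abs_log2fc for d in divs] == pytest.approx(
            [d.abs_log2fc for d in divs_swapped]
        )
        # global rescaling: exactly invariant without the pseudocount (which
        # sets the only absolute scale), and nearly so with it
        divs0 = pair_abs_log2fc(self.counts, self.meta, self.pairs, "AxA", "F",
                                pseudocount=0.0)
        divs_scaled = pair_abs_log2fc(self.counts * 4, self.meta, self.pairs,
                                      "AxA", "F", pseudocount=0.0)
        assert [d.abs_log2fc for d in divs0] == pytest.approx(
            [d.abs_log2fc for d in divs_scaled], abs=1e-9
        )
        divs_scaled_pc = pair_abs_log2fc(self.counts * 4, self.meta, self.pairs,
                                         "AxA", "F")
        assert [d.abs_log2fc for d in divs] == pytest.approx(
            [d.abs_log2fc for d in divs_scaled_pc], abs=0.05
        )

    def test_missing_member_skipped_with_warning(self, caplog):
        import logging
        pairs = self.pairs + [OhnologPair("gX", "gY", 95.0, InheritanceMode.DISOMIC)]
        with caplog.at_level(logging.WARNING):
            divs = pair_abs_log2fc(self.counts, self.meta, pairs, "AxA", "F")
        assert len(divs) == 2
        assert any("absent" in r.message for r in caplog.records)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="selects no samples"):
            pair_abs_log2fc(self.counts, self.meta, self.pairs, "RxR", "M")

    def test_min_read_filter_drops_low_count_pairs(self):
        counts = pd.DataFrame(
            {"s1": [2, 100], "s2": [2, 100]}, index=["gA", "gB"]
        )
        divs = pair_abs_log2fc(
            counts, self.meta,
            [OhnologPair("gA", "gB", 95.0, InheritanceMode.DISOMIC)], "AxA", "F",
        )
        assert divs == []  # gA fails the >= 5 summed-reads filter


class TestDivergenceContrast:
    def test_identical_distributions_give_t_near_zero(self, rng):
        values = rng.exponential(1.0, size=200)
        divs = [
            PairDivergence(f"a{i}", f"b{i}",
                           InheritanceMode.DISOMIC if i % 2 else InheritanceMode.TETRASOMIC,
                           "Both-All", float(v))
            for i, v in enumerate(values)
        ]
        row = divergence_contrast(divs)
        assert abs(row["t"]) < 2.5
        assert row["ci_low"] < 0 < row["ci_high"]

    def test_wider_disomic_divergence_detected_across_seeds(self):
        # folded normal: E|X| = sigma sqrt(2/pi); sigma_d > sigma_t gives a
        # predictable gap
        sigma_d, sigma_t = 2.6, 2.1
        for seed in range(5):
            r = np.random.default_rng(seed)
            divs = [
                PairDivergence(f"a{i}", f"b{i}", InheritanceMode.DISOMIC, "s",
                               abs(float(r.normal(0, sigma_d))))
                for i in range(700)
            ] + [
                PairDivergence(f"c{i}", f"d{i}", InheritanceMode.TETRASOMIC, "s",
                               abs(float(r.normal(0, sigma_t))))
                for i in range(280)
            ]
            row = divergence_contrast(divs)
            assert row["t"] > 0 and row["p"] < 0.05
            assert row["mean_disomic"] == pytest.approx(
                sigma_d * math.sqrt(2 / math.pi), rel=0.15
            )

    def test_single_mode_rejected(self):
        divs = [PairDivergence("a", "b", InheritanceMode.DISOMIC, "s", 1.0)] * 3
        with pytest.raises(ValueError):
            divergence_contrast(divs)

    def test_seven_subsets_emitted(self, small_expression, small_genome):
        table = seven_contrasts(
            small_expression.counts, small_expression.meta, small_genome.truth_pairs
        )
        assert list(zip(table["cross"], table["sex"])) == [
            ("AxA", "F"), ("AxA", "M"), ("AxA", "All"),
            ("RxR", "F"), ("RxR", "M"), ("RxR", "All"),
            ("Both", "All"),
        ]


class TestBHAdjust:
    def test_step_up_reference_example(self):
        adjusted = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(adjusted, [0.02, 0.04, 0.04, 0.02])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert bh_adjust([]).size == 0
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_definition_on_random_vectors(self, rng):
        def brute(p):
            n = len(p)
            order = sorted(range(n), key=lambda i: p[i])
            out = [None] * n
            running_min = 1.0
            for rank_from_top in range(n, 0, -1):
                i = order[rank_from_top - 1]
                running_min = min(running_min, p[i] * n / rank_from_top)
                out[i] = running_min
            return out

        for _ in range(300):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute(list(p)), atol=1e-12)

    def test_adjusted_dominates_raw_and_is_monotone(self, rng):
        p = rng.uniform(0, 1, size=200)
        adjusted = bh_adjust(p)
        assert (adjusted >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-15).all()


class TestDETest:
    def _simulate(self, seed, n_genes=2000, effect_idx=(), effect_fold=1.0,
                  n1=4, n2=4, phi=0.1):
        r = np.random.default_rng(seed)
        means = r.lognormal(4.0, 1.0, size=n_genes)
        cols = {}
        sample_ids, crosses, sexes = [], [], []
        for j in range(n1 + n2):
            cross = "AxA" if j < n1 else "RxR"
            mu = means.copy()
            if len(effect_idx) and cross == "AxA":
                mu[list(effect_idx)] *= effect_fold
            lam = r.gamma(1.0 / phi, mu * phi)
            sid = f"s{j}"
            cols[sid] = r.poisson(lam)
            sample_ids.append(sid)
            crosses.append(cross)
            sexes.append("F" if j % 2 else "M")
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        meta = meta_frame(sample_ids, crosses, sexes)
        return counts, meta

    def test_null_type_one_error_near_nominal(self):
        counts, meta = self._simulate(seed=123, n1=7, n2=8)
        de = de_test(counts, meta, sex_as_cofactor=True)
        rate = float((de["p"] < 0.05).mean())
        # 2,000 null genes: binomial MC error ~0.005
        assert 0.03 < rate < 0.07

    def test_large_effect_detected_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            counts, meta = self._simulate(
                seed=seed, n_genes=300, effect_idx=[0], effect_fold=20.0
            )
            de = de_test(counts, meta, sex_as_cofactor=False)
            hits += bool(de.loc["g0", "significant"])
        assert hits >= 19

    def test_low_count_gene_never_tested(self):
        counts = pd.DataFrame(
            {f"s{j}": [1, 100] for j in range(8)}, index=["low", "high"]
        )
        counts.iloc[0, :] = 0
        counts.iloc[0, 0] = 4  # total 4 < 5
        meta = meta_frame(
            [f"s{j}" for j in range(8)],
            ["AxA"] * 4 + ["RxR"] * 4,
            ["F", "M"] * 4,
        )
        de = de_test(counts, meta, sex_as_cofactor=False)
        assert "low" not in de.index

    def test_small_group_rejected(self):
        counts, meta = self._simulate(seed=0, n_genes=10, n1=1, n2=4)
        with pytest.raises(ValueError, match=">= 2 samples"):
            de_test(counts, meta)

    def test_mode_annotation_joins_pairs(self):
        de = pd.DataFrame(
            {"significant": [True, False]}, index=["gA", "gZ"]
        )
        pairs = [OhnologPair("gA", "gB", 95.0, InheritanceMode.TETRASOMIC)]
        tagged = annotate_de_with_mode(de, pairs)
        assert tagged.loc["gA", "ohnolog_mode"] == "tetrasomic"
        assert tagged.loc["gZ", "ohnolog_mode"] == "non-ohnolog"
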