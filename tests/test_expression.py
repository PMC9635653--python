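"""Responsiveness rules, bins and the statistical toolbox vs exact oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nacfam.errors import ConfigurationError, InputError
from nacfam.expression import (
    baseline_bins,
    classify_responsiveness,
    family_vs_genome_chisq,
    hclust_order,
    kruskal_wallis_stepdown,
    lifestyle_summary,
    moses_test,
    subfamily_enrichment,
)


def de_row(gene, pathogen, lfc, padj, genotype="R", timepoint="T1"):
    return (gene, pathogen, genotype, timepoint, lfc, padj)


def de_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "pathogen", "genotype", "timepoint", "log2fc", "padj"]
    )


class TestClassify:
    def test_fold_change_boundary_is_strict(self):
        de = de_frame([de_row("g1", "Fg", 1.0, 0.01), de_row("g2", "Fg", 1.01, 0.01)])
        p = classify_responsiveness(de)
        assert not p["g1"].responsive_pathogens
        assert p["g2"].responsive_pathogens == {"Fg"}

    def test_p_boundary_is_strict(self):
        de = de_frame([de_row("g1", "Fg", 2.0, 0.05), de_row("g2", "Fg", 2.0, 0.049)])
        p = classify_responsiveness(de)
        assert not p["g1"].responsive_pathogens
        assert p["g2"].responsive_pathogens == {"Fg"}

    def test_hemibiotroph_only_and_universal(self):
        de = de_frame([de_row("g1", "Fg", 2.0, 0.01), de_row("g1", "Zt", -1.5, 0.01),
                       de_row("g1", "Ps", 0.2, 0.01)])
        p = classify_responsiveness(de)["g1"]
        assert p.lifestyle_category == "hemibiotroph-only"
        assert p.universal
        assert p.directions[("Fg", "R", "T1")] == "up"
        assert p.directions[("Zt", "R", "T1")] == "down"

    def test_unknown_pathogen_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_responsiveness(de_frame([de_row("g1", "Unknown", 2.0, 0.01)]))

    def test_matches_brute_force_on_exhaustive_small_table(self):
        """Enumerate all threshold combinations on a 3-gene table and compare
        with a from-scratch reimplementation of the rule."""
        lfcs = [-2.0, -1.0, 0.5, 1.0, 1.5]
        padjs = [0.01, 0.05, 0.2]
        rows, expected = [], {}
        i = 0
        for lfc, padj in itertools.product(lfcs, padjs):
            gene = f"g{i % 3}"
            pathogen = ["Fg", "Ps"][i % 2]
            rows.append(de_row(gene, pathogen, lfc, padj, timepoint=f"T{i}"))
            if abs(lfc) > 1.0 and padj < 0.05:
                expected.setdefault(gene, set()).add(pathogen)
            i += 1
        got = classify_responsiveness(de_frame(rows))
        for gene in ("g0", "g1", "g2"):
            assert got[gene].responsive_pathogens == expected.get(gene, set())


class TestLifestyleSummary:
    def test_planted_counts(self):
        de = []
        for i in range(10):
            de.append(de_row(f"h{i}", "Fg", 2.0, 0.01))
            de.append(de_row(f"h{i}", "Zt", 2.0, 0.01))
        for i in range(5):
            de.append(de_row(f"b{i}", "Fg", 2.0, 0.01))
            de.append(de_row(f"b{i}", "Ps", 2.0, 0.01))
        profiles = classify_responsiveness(de_frame(de))
        s = lifestyle_summary(profiles).set_index("label")
        assert s.loc["hemibiotroph-only", "count"] == 10
        assert s.loc["both", "count"] == 5
        assert s.loc["hemibiotroph-only", "fraction"] == pytest.approx(10 / 15)
        assert s.loc[">=2 pathogens", "count"] == 15

    def test_empty_profiles_all_zero(self):
        s = lifestyle_summary({})
        assert (s["count"] == 0).all()

    def test_category_fractions_sum_to_one_over_responsive(self):
        de = de_frame([de_row("g1", "Fg", 2.0, 0.01), de_row("g2", "Ps", 2.0, 0.01),
                       de_row("g3", "Bg", 3.0, 0.001), de_row("g3", "Zt", 3.0, 0.001)])
        s = lifestyle_summary(classify_responsiveness(de))
        cats = s[(s["kind"] == "category") & (s["label"] != "none")]
        assert cats["fraction"].sum() == pytest.approx(1.0)


class TestBaselineBins:
    def _tpm(self, values):
        return pd.DataFrame(
            [("g", organ, v) for organ, v in values.items()],
            columns=["gene_id", "organ", "tpm"],
        )

    def test_fixed_edges_bin_assignment(self):
        tpm = self._tpm({"grain": 0.2, "leaf": 1.0, "root": 5.0, "spike": 0.05,
                         "stem": 3.7})
        prof = baseline_bins(tpm, bin_edges=(0.3, 3.7))
        bins = prof.table.set_index("organ")["bin"]
        assert bins["grain"] == "low"
        assert bins["leaf"] == "moderate"
        assert bins["root"] == "high"
        assert bins["spike"] == "not-expressed"
        assert bins["stem"] == "moderate"  # boundary belongs to the middle bin

    def test_auto_edges_match_order_statistics(self):
        rng = np.random.default_rng(4)
        vals = 10 ** rng.normal(0, 0.8, size=400)
        tpm = pd.DataFrame(
            [(f"g{i // 5}", ["grain", "leaf", "root", "spike", "stem"][i % 5], v)
             for i, v in enumerate(vals)],
            columns=["gene_id", "organ", "tpm"],
        )
        prof = baseline_bins(tpm, bin_edges="auto")
        expressed = vals[vals >= 0.1]
        assert prof.edges[0] == pytest.approx(np.quantile(expressed, 0.25))
        assert prof.edges[1] == pytest.approx(np.quantile(expressed, 0.75))

    def test_negative_tpm_rejected(self):
        with pytest.raises(InputError):
            baseline_bins(self._tpm({"grain": -1.0}))

    def test_grain_specific_requires_grain_only_expression(self):
        tpm = pd.DataFrame(
            [("g1", "grain", 5.0), ("g1", "leaf", 0.01),
             ("g2", "grain", 5.0), ("g2", "leaf", 2.0)],
            columns=["gene_id", "organ", "tpm"],
        )
        assert baseline_bins(tpm).grain_specific() == {"g1"}


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided exact p."""
    n1, row1, total = a + b, a + c, a + b + c + d

    def pmf(k):
        return comb(n1, k) * comb(total - n1, row1 - k) / comb(total, row1)

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, row1 - (total - n1)), min(n1, row1) + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def test_fisher_p_equals_enumeration(self):
        assignment = {}
        responsive = set()
        # subfamily x: 8/10 responsive; elsewhere 10/90
        for i in range(10):
            assignment[f"x{i}"] = "x"
            if i < 8:
                responsive.add(f"x{i}")
        for i in range(90):
            assignment[f"o{i}"] = "o"
            if i < 10:
                responsive.add(f"o{i}")
        df = subfamily_enrichment(assignment, responsive).set_index("subfamily")
        assert df.loc["x", "p"] == pytest.approx(fisher_two_sided_oracle(8, 2, 10, 80))

    def test_all_genes_responsive_gives_p_one(self):
        assignment = {f"g{i}": ("a" if i < 5 else "b") for i in range(10)}
        df = subfamily_enrichment(assignment, set(assignment))
        assert (df["p"] == 1.0).all()

    def test_planted_enrichment_recovered_and_null_controlled(self):
        """Subfamilies seeded at 80% responders flag BH<0.05 nearly always;
        null subfamilies at background rate rarely do."""
        rng = np.random.default_rng(0)
        hits = nulls = hit_flags = null_flags = 0
        for _ in range(100):
            assignment, responsive = {}, set()
            for i in range(30):
                assignment[f"e{i}"] = "enriched"
                if rng.random() < 0.8:
                    responsive.add(f"e{i}")
            for sf in ("n1", "n2"):
                for i in range(40):
                    g = f"{sf}_{i}"
                    assignment[g] = sf
                    if rng.random() < 0.15:
                        responsive.add(g)
            for i in range(400):
                assignment[f"bg{i}"] = "bg"
                if rng.random() < 0.15:
                    responsive.add(f"bg{i}")
            df = subfamily_enrichment(assignment, responsive).set_index("subfamily")
            hits += 1
            hit_flags += int(df.loc["enriched", "p_bh"] < 0.05)
            for sf in ("n1", "n2"):
                nulls += 1
                null_flags += int(df.loc[sf, "p_bh"] < 0.05)
        assert hit_flags / hits >= 0.95
        assert null_flags / nulls <= 0.10


class TestChisq:
    def test_equal_proportions_zero_statistic(self):
        stat, df, p = family_vs_genome_chisq(10, 100, 100, 1000)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_pearson_formula(self):
        fr, ft, gr, gt = 64, 460, 11000, 110000
        stat, df, p = family_vs_genome_chisq(fr, ft, gr, gt)
        table = np.array([[fr, ft - fr], [gr, gt - gr]], dtype=float)
        rows, cols, n = table.sum(1), table.sum(0), table.sum()
        expect = np.outer(rows, cols) / n
        hand = ((table - expect) ** 2 / expect).sum()
        assert df == 1
        assert stat == pytest.approx(hand)
        assert p == pytest.approx(stats.chi2.sf(hand, 1))

    def test_invariant_to_swapping_rows_and_columns(self):
        s1, _, p1 = family_vs_genome_chisq(14, 100, 10, 1000)
        s2, _, p2 = family_vs_genome_chisq(10, 1000, 14, 100)
        s3, _, p3 = family_vs_genome_chisq(86, 100, 990, 1000)
        assert s1 == pytest.approx(s2) == pytest.approx(s3)
        assert p1 == pytest.approx(p2)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            family_vs_genome_chisq(0, 10, 0, 100)


class TestKruskalWallis:
    def test_identical_groups_share_one_subset(self):
        h, p, subsets = kruskal_wallis_stepdown({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert h == pytest.approx(0.0)
        assert subsets["a"] == subsets["b"] == [1]

    def test_well_separated_groups_get_distinct_subsets(self):
        rng = np.random.default_rng(1)
        groups = {
            "lo": list(rng.normal(0, 1, 20)),
            "mid": list(rng.normal(10, 1, 20)),
            "hi": list(rng.normal(20, 1, 20)),
        }
        _, p, subsets = kruskal_wallis_stepdown(groups)
        assert p < 0.05
        labels = {tuple(v) for v in subsets.values()}
        assert len(labels) == 3

    def test_h_matches_textbook_formula(self):
        groups = {"a": [27.0, 2.0, 4.0, 18.0], "b": [5.0, 8.0, 1.0, 12.0],
                  "c": [13.0, 22.0, 9.0, 30.0]}
        h, p, _ = kruskal_wallis_stepdown(groups)
        pooled = sorted(v for vs in groups.values() for v in vs)
        rank = {v: i + 1 for i, v in enumerate(pooled)}  # distinct values
        n = len(pooled)
        hand = 12 / (n * (n + 1)) * sum(
            sum(rank[v] for v in vs) ** 2 / len(vs) for vs in groups.values()
        ) - 3 * (n + 1)
        assert h == pytest.approx(hand)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis_stepdown({"a": [1, 2]})


def moses_enumeration_oracle(nc, ne, span_obs, trim_h):
    """Exhaustive: place nc control ranks among nc+ne; trimmed span <= obs."""
    n = nc + ne
    count = 0
    for combo in itertools.combinations(range(1, n + 1), nc):
        trimmed = combo[trim_h : nc - trim_h]
        if trimmed[-1] - trimmed[0] + 1 <= span_obs:
            count += 1
    return count / comb(n, nc)


class TestMoses:
    def test_experimental_inside_control_range_large_span(self):
        span, p = moses_test([0, 10, 20, 30, 40, 50], [24, 25, 26, 27], trim_h=1)
        assert span == 8  # trimmed control ranks 2..9
        assert p > 0.9

    def test_separated_samples_match_enumeration(self):
        control = [1.0, 2.0, 3.0, 4.0]
        experimental = [10.0, 11.0, 12.0, 13.0]
        span, p = moses_test(control, experimental, trim_h=0)
        assert span == 4
        assert p == pytest.approx(moses_enumeration_oracle(4, 4, 4, 0))

    @pytest.mark.parametrize("nc,ne,h,seed", [(4, 4, 0, 0), (5, 5, 1, 1),
                                              (6, 6, 1, 2), (6, 5, 0, 3)])
    def test_exact_p_equals_enumeration_for_small_samples(self, nc, ne, h, seed):
        rng = np.random.default_rng(seed)
        control = list(rng.normal(0, 1, nc))
        experimental = list(rng.normal(0.5, 2, ne))
        span, p = moses_test(control, experimental, trim_h=h)
        assert p == pytest.approx(moses_enumeration_oracle(nc, ne, span, h))

    def test_invariant_under_monotone_transform(self):
        control = [1.0, 2.5, 3.0, 4.2, 8.0]
        experimental = [0.5, 2.0, 5.0, 9.0]
        s1, p1 = moses_test(control, experimental)
        s2, p2 = moses_test([np.exp(v) for v in control],
                            [np.exp(v) for v in experimental])
        assert (s1, p1) == (s2, p2)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InputError):
            moses_test([1, 2, 3], [1, 2, 3], trim_h=1)


class TestHclust:
    def test_identical_rows_adjacent(self):
        m = pd.DataFrame(
            [[0, 0, 5], [9, 1, 2], [0, 0, 5], [4, 4, 4]],
            index=["a", "b", "c", "d"],
        )
        order = hclust_order(m)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_merge_sequence_matches_manual_average_linkage(self):
        # distances: ab=1, cd=2, {ab}-{cd} mean pairwise > both
        m = pd.DataFrame(
            [[0.0], [1.0], [10.0], [12.0]], index=["a", "b", "c", "d"]
        )
        order = hclust_order(m)
        assert {tuple(order[:2]), tuple(order[2:])} == {("a", "b"), ("c", "d")}

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(20, 6)),
                         index=[f"g{i}" for i in range(20)])
        assert hclust_order(m) == hclust_order(m.copy())

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError):
            hclust_order(pd.DataFrame())
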