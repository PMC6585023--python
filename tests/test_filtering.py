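"""Variant filtering cascade: rules, boundaries, and set-algebra properties."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rareburden import (
    FilterConfig,
    FilterTrace,
    apply_validation_mask,
    brain_expression_gene_set,
    exclude_control_observed,
    filter_class,
    filter_deleterious,
    filter_rare,
    merge_case_variants,
    restrict_to_genes,
)
from rareburden.filtering import (
    AnnotationError,
    InputConsistencyError,
    annotate_variants,
    normalize_key,
    screen_known_pathogenic,
    variant_keys,
)
from rareburden.simulate import BRAIN_REGIONS


def make_table(**cols) -> pd.DataFrame:
    n = max(len(v) for v in cols.values())
    base = {
        "chrom": ["1"] * n,
        "pos": list(range(100, 100 + n)),
        "ref": ["A"] * n,
        "alt": ["G"] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestMerge:
    def test_shared_variant_single_row(self):
        key = ("1", 100, "A", "G")
        table = merge_case_variants({"s1": [key], "s2": [key]})
        assert len(table) == 1
        assert table["carriers"].iloc[0] == frozenset({"s1", "s2"})

    def test_disjoint_sets_union(self):
        a = {("1", i, "A", "G") for i in range(3)}
        b = {("2", i, "C", "T") for i in range(4)}
        table = merge_case_variants({"s1": a, "s2": b})
        assert len(table) == 7

    def test_key_normalization(self):
        table = merge_case_variants({"s1": [("chr1", "100", "a", "g")]})
        assert variant_keys(table) == {("1", 100, "A", "G")}

    def test_conflicting_ref_rejected(self):
        with pytest.raises(InputConsistencyError):
            merge_case_variants(
                {"s1": [("1", 100, "A", "G")], "s2": [("1", 100, "C", "G")]}
            )

    def test_merged_count_matches_generated(self, small_cohort):
        cases, _, annotations = small_cohort
        table = merge_case_variants(cases)
        case_keys = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in annotations[annotations["cohort"] == "cases"].itertuples(index=False)
        }
        assert variant_keys(table) == case_keys


class TestVariantFilters:
    def test_class_filter(self):
        table = make_table(variant_class=["SNV"] * 5 + ["indel"] * 3)
        assert len(filter_class(table)) == 5
        all_snv = make_table(variant_class=["SNV"] * 4)
        pd.testing.assert_frame_equal(filter_class(all_snv), all_snv)

    def test_rare_filter_rule(self):
        table = make_table(
            af_g1000=[0.005, 0.02, 0.01, np.nan],
            af_exac=[np.nan, np.nan, np.nan, np.nan],
        )
        kept = filter_rare(table)
        # kept: reported rare in one panel / unreported everywhere;
        # dropped: 0.02 (above) and exactly 0.01 (strict <)
        assert list(kept["pos"]) == [100, 103]

    def test_rare_filter_requires_every_panel_rare(self):
        table = make_table(af_g1000=[0.005], af_exac=[0.5])
        assert len(filter_rare(table)) == 0

    def test_rare_filter_bad_frequency(self):
        with pytest.raises(AnnotationError):
            filter_rare(make_table(af_g1000=[1.5]))

    def test_control_exclusion(self):
        table = make_table(extra=[0, 1, 2])
        assert len(exclude_control_observed(table, set())) == 3
        all_keys = variant_keys(table)
        assert len(exclude_control_observed(table, all_keys)) == 0
        one = {("1", 101, "A", "G")}
        assert list(exclude_control_observed(table, one)["pos"]) == [100, 102]

    def test_planted_control_overlap_removed_exactly(self, small_cohort):
        cases, _, annotations = small_cohort
        table = annotate_variants(merge_case_variants(cases), annotations)
        planted = set(itertools.islice(sorted(variant_keys(table)), 5))
        out = exclude_control_observed(table, planted)
        assert len(table) - len(out) == 5
        assert variant_keys(out).isdisjoint(planted)

    def test_cadd_filter_boundary(self):
        table = make_table(cadd_scaled=[25.0, 20.0, 19.9, np.nan])
        kept = filter_deleterious(table)
        assert list(kept["cadd_scaled"]) == [25.0]  # 20.0 dropped: strict >
        kept_keep = filter_deleterious(
            table, FilterConfig(cadd_missing="keep")
        )
        assert len(kept_keep) == 2
        with pytest.raises(AnnotationError):
            filter_deleterious(table, FilterConfig(cadd_missing="error"))

    def test_cadd_survivor_fraction(self, small_cohort, small_config):
        _, _, ann = small_cohort
        table = ann.copy()
        kept = filter_deleterious(table)
        n = len(table)
        p = small_config.cadd_pass_prob
        half = 2.576 * np.sqrt(n * p * (1 - p))
        assert abs(len(kept) - n * p) < half

    def test_validation_mask(self):
        table = make_table(extra=list(range(23)))
        assert len(apply_validation_mask(table, [])) == 23
        mask = set(itertools.islice(variant_keys(table), 7))
        assert len(apply_validation_mask(table, mask)) == 16
        disjoint = {("9", 1, "A", "C")}
        assert len(apply_validation_mask(table, disjoint)) == 23

    def test_known_pathogenic_screen_reports_not_filters(self):
        table = make_table(extra=[0, 1, 2])
        hits = screen_known_pathogenic(table, [("1", 101, "A", "G")])
        assert list(hits["pos"]) == [101]
        assert len(table) == 3  # untouched


class TestExpressionFilter:
    def make_genes(self, summaries: np.ndarray) -> pd.DataFrame:
        genes = pd.DataFrame({
            "symbol": [f"G{i}" for i in range(len(summaries))],
            "cds_length": 1000,
        })
        for region in BRAIN_REGIONS:
            genes[region] = summaries
        return genes

    def test_zero_summary_excluded(self):
        genes = self.make_genes(np.array([0.0, 1.0, 2.0]))
        kept = brain_expression_gene_set(genes)
        assert "G0" not in kept and {"G1", "G2"} <= kept

    def test_negative_rpkm_rejected(self):
        with pytest.raises(AnnotationError):
            brain_expression_gene_set(self.make_genes(np.array([-1.0, 1.0])))

    def test_zscore_semantics_match_independent_computation(self, rng):
        summaries = 10.0 ** rng.normal(0.5, 0.8, 400)
        genes = self.make_genes(summaries)
        kept = brain_expression_gene_set(genes)
        logs = np.log10(summaries)
        z = (logs - logs.mean()) / logs.std(ddof=0)
        expected = {f"G{i}" for i in np.flatnonzero(z > -1.96)}
        assert kept == expected

    def test_boundary_gene_at_cutoff_excluded(self, rng):
        # a gene whose z-score exactly equals the cutoff must be excluded
        summaries = 10.0 ** rng.normal(0.5, 0.8, 200)
        genes = self.make_genes(summaries)
        logs = np.log10(genes[list(BRAIN_REGIONS)].to_numpy().mean(axis=1))
        z = (logs - logs.mean()) / logs.std(ddof=0)
        target = int(np.argmin(z))
        kept = brain_expression_gene_set(
            genes, FilterConfig(zscore_cutoff=float(z[target]))
        )
        assert f"G{target}" not in kept

    def test_boundary_margins_around_default_cutoff(self):
        # construct summaries with mean 0 and population SD 1 on the log10
        # scale (paired +-d values), then plant genes at z = -1.90 and -2.00
        d = np.sqrt((100 - 1.90**2 - 2.00**2 - 1.90**2 - 2.00**2) / 96)
        logs = np.concatenate([
            [-1.90, 1.90, -2.00, 2.00],
            np.tile([d, -d], 48),
        ])
        genes = self.make_genes(10.0**logs)
        kept = brain_expression_gene_set(genes)
        assert "G0" in kept      # z = -1.90 kept
        assert "G2" not in kept  # z = -2.00 excluded

    def test_tail_fraction_excluded(self, rng):
        # normal log-expression: about Phi(-1.96) ~ 2.5% of expressed genes fall
        summaries = 10.0 ** rng.normal(0.8, 0.7, 10000)
        genes = self.make_genes(summaries)
        kept = brain_expression_gene_set(genes)
        excluded = len(summaries) - len(kept)
        p = 0.025
        half = 2.576 * np.sqrt(10000 * p * (1 - p))
        assert abs(excluded - 10000 * p) < half

    def test_restrict_to_genes(self):
        table = make_table(gene=["A", "B", "C", None])
        assert len(restrict_to_genes(table, {"A", "B", "C"})) == 3
        assert len(restrict_to_genes(table, set())) == 0
        assert list(restrict_to_genes(table, {"B"})["gene"]) == ["B"]


class TestFilterAlgebra:
    """Monotonicity, idempotence and commutation on randomized fixtures."""

    @pytest.fixture()
    def random_table(self, small_cohort):
        _, _, ann = small_cohort
        return ann.copy()

    def filters(self):
        cfg = FilterConfig()
        return {
            "class": lambda t: filter_class(t),
            "rare": lambda t: filter_rare(t, cfg),
            "cadd": lambda t: filter_deleterious(t, cfg),
        }

    def test_monotone_subsets(self, random_table):
        for name, f in self.filters().items():
            out = f(random_table)
            assert variant_keys(out) <= variant_keys(random_table), name

    def test_idempotent(self, random_table):
        for name, f in self.filters().items():
            once = f(random_table)
            twice = f(once)
            pd.testing.assert_frame_equal(once, twice), name

    def test_filters_commute(self, random_table):
        results = []
        for perm in itertools.permutations(self.filters().values()):
            out = random_table
            for f in perm:
                out = f(out)
            results.append(variant_keys(out))
        assert all(r == results[0] for r in results)

    def test_trace_counts_non_increasing(self, random_table):
        trace = FilterTrace()
        table = random_table.copy()
        table["carriers"] = [frozenset({"s"})] * len(table)
        trace.record("input", table)
        for f in self.filters().values():
            table = f(table)
            trace.record("stage", table)
        counts = trace.variant_counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
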