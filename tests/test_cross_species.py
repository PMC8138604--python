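import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossmeth.cross_species import (
    GeneDMSummary,
    annotate_loci_to_genes,
    direction_concordance,
    enrichment_test,
    major_relevance_genes,
    pearson_chi2,
    risk_concordance,
    summarize_genes,
)
from crossmeth.dm_cpg import DMResult, ModerationHyperparams
from crossmeth.io_formats import GeneAnnotation
from crossmeth.orthology import OrthologMap


def chi2_closed_form(a, b, c, d):
    """Pearson chi-squared on [[a,b],[c,d]] by the textbook formula."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def binomial_tail_oracle(k, n):
    """Exact one-sided tail: sum_{j>=k} C(n,j) / 2^n by enumeration."""
    from math import comb

    return sum(comb(n, j) for j in range(k, n + 1)) / 2**n


def _dm_result(rows, fdr_threshold=0.10):
    """rows: list of (chrom, pos, delta_beta, fdr, significant)."""
    idx = pd.MultiIndex.from_arrays(
        [[r[0] for r in rows], [r[1] for r in rows]], names=["chrom", "pos"]
    )
    delta = np.array([r[2] for r in rows], dtype=float)
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "coef_m": delta,
            "s2": 1.0,
            "df": 4,
            "t": 0.0,
            "p_value": [r[3] for r in rows],
            "fdr": [r[3] for r in rows],
            "significant": [r[4] for r in rows],
            "direction": np.where(delta > 0, "hyper", np.where(delta < 0, "hypo", "none")),
            "testable": True,
        },
        index=idx,
    )
    return DMResult(
        table=table, fdr_threshold=fdr_threshold,
        hyperparams=ModerationHyperparams(d0=0, s0_sq=1.0),
        control="control", case="tumour",
    )


def _summary(rows, clear_threshold=0.30):
    """rows: gene -> (has_dm, max_abs_delta, direction)."""
    recs = []
    for gene, (has_dm, max_abs, direction) in rows.items():
        recs.append(
            {
                "gene": gene,
                "n_tested_loci": 5,
                "n_significant_loci": int(has_dm),
                "max_abs_delta_beta": max_abs if has_dm else float("nan"),
                "direction": direction if has_dm else "none",
                "has_dm": has_dm,
                "has_clear_dm": has_dm and max_abs >= clear_threshold,
            }
        )
    cols = [
        "gene", "n_tested_loci", "n_significant_loci", "max_abs_delta_beta",
        "direction", "has_dm", "has_clear_dm",
    ]
    return GeneDMSummary(pd.DataFrame(recs, columns=cols).set_index("gene"), clear_threshold)


def _map(pairs):
    return OrthologMap(
        pairs=pd.DataFrame(
            [
                {"mouse_gene": m, "human_gene": h, "confidence": "high",
                 "homology_pct": 90.0, "resolution_rule": "high-conf-max-homology"}
                for m, h in pairs
            ]
        )
    )


ANNOT = GeneAnnotation(
    genes=pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [10000, 10500, 50000],
            "end": [12000, 11500, 60000],
            "strand": ["+", "-", "+"],
            "symbol": ["Filip1l", "Cmss1", "Far1"],
        }
    )
)


class TestAnnotateLoci:
    def test_locus_in_gene_body_assigned(self):
        dm = _dm_result([("chr1", 55000, 0.1, 0.5, False)])
        out = annotate_loci_to_genes(dm, ANNOT)
        assert list(out["gene"]) == ["Far1"]

    def test_locus_upstream_within_promoter_window_assigned(self):
        dm = _dm_result([("chr1", 49000, 0.1, 0.5, False)])  # 1000 bp upstream
        out = annotate_loci_to_genes(dm, ANNOT)
        assert list(out["gene"]) == ["Far1"]
        far = annotate_loci_to_genes(
            _dm_result([("chr1", 48000, 0.1, 0.5, False)]), ANNOT
        )
        assert len(far) == 0  # 2000 bp upstream: outside the window

    def test_locus_overlapping_two_opposite_strand_genes_assigned_to_both(self):
        dm = _dm_result([("chr1", 11000, 0.4, 0.01, True)])
        out = annotate_loci_to_genes(dm, ANNOT)
        assert sorted(out["gene"]) == ["Cmss1", "Filip1l"]

    def test_intergenic_locus_absent(self):
        dm = _dm_result([("chr1", 30000, 0.1, 0.5, False)])
        assert len(annotate_loci_to_genes(dm, ANNOT)) == 0


class TestSummarizeGenes:
    def _run(self, rows):
        dm = _dm_result(rows)
        assignments = annotate_loci_to_genes(dm, ANNOT)
        return summarize_genes(dm, assignments)

    def test_clear_dm_gene(self):
        s = self._run([("chr1", 11000, 0.3987, 0.01, True)])
        row = s.table.loc["Filip1l"]
        assert row["has_dm"] and row["has_clear_dm"]
        assert row["direction"] == "hyper"
        assert row["max_abs_delta_beta"] == pytest.approx(0.3987)

    def test_significant_but_below_threshold_not_clear(self):
        s = self._run([("chr1", 55000, 0.29, 0.01, True)])
        row = s.table.loc["Far1"]
        assert row["has_dm"] and not row["has_clear_dm"]

    def test_no_significant_loci_not_dm(self):
        s = self._run([("chr1", 55000, 0.5, 0.9, False)])
        assert not s.table.loc["Far1", "has_dm"]

    def test_direction_taken_at_strongest_significant_locus(self):
        s = self._run(
            [("chr1", 55000, -0.45, 0.01, True), ("chr1", 55500, 0.35, 0.01, True)]
        )
        row = s.table.loc["Far1"]
        assert row["direction"] == "hypo"
        assert row["max_abs_delta_beta"] == pytest.approx(0.45)


class TestChiSquared:
    def test_hand_computed_2x2(self):
        tab = np.array([[40, 10], [400, 400]])
        stat, p = pearson_chi2(tab)
        assert stat == pytest.approx(chi2_closed_form(40, 10, 400, 400))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    def test_matches_closed_form_on_random_tables(self, a, b, c, d):
        stat, p = pearson_chi2(np.array([[a, b], [c, d]]))
        expected = chi2_closed_form(a, b, c, d)
        assert stat == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-10)


class TestEnrichment:
    def test_identical_fractions_give_null_result(self):
        mouse = _summary({"Ma": (True, 0.4, "hyper"), "Mb": (True, 0.4, "hyper")})
        human = _summary(
            {"HA": (True, 0.4, "hyper"), "HB": (False, 0, "none"),
             "HC": (True, 0.4, "hyper"), "HD": (False, 0, "none")}
        )
        rep = enrichment_test(
            mouse, {"sub": human}, _map([("Ma", "HA"), ("Mb", "HB")])
        )
        row = rep.enrichment.iloc[0]
        assert row["set_fraction"] == row["baseline_fraction"]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert row["p_value"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_raw_p(self):
        mouse = _summary({f"M{i}": (True, 0.4, "hyper") for i in range(40)})
        human_rows = {f"H{i}": (i < 38, 0.4, "hyper") for i in range(40)}
        human_rows.update({f"X{i}": (i < 10, 0.4, "hyper") for i in range(40)})
        human = _summary(human_rows)
        omap = _map([(f"M{i}", f"H{i}") for i in range(40)])
        rep = enrichment_test(mouse, {"a": human, "b": human}, omap)
        for _, row in rep.enrichment.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_value"] * 2))


class TestDirectionConcordance:
    def _setup(self, conc_a, n_a, conc_b, n_b):
        mouse = _summary({f"M{i}": (True, 0.4, "hyper") for i in range(max(n_a, n_b))})
        hum_a = _summary(
            {f"H{i}": (True, 0.4, "hyper" if i < conc_a else "hypo") for i in range(n_a)}
        )
        hum_b = _summary(
            {f"H{i}": (True, 0.4, "hyper" if i < conc_b else "hypo") for i in range(n_b)}
        )
        omap = _map([(f"M{i}", f"H{i}") for i in range(max(n_a, n_b))])
        return mouse, {"a": hum_a, "b": hum_b}, omap

    def test_full_concordance_both_subtypes(self):
        mouse, humans, omap = self._setup(10, 10, 10, 10)
        rep = direction_concordance(mouse, humans, omap)
        assert list(rep.direction["fraction"]) == [1.0, 1.0]
        assert rep.direction_p == pytest.approx(1.0)

    def test_chi2_matches_hand_computation(self):
        mouse, humans, omap = self._setup(198, 240, 163, 248)
        rep = direction_concordance(mouse, humans, omap)
        expected = chi2_closed_form(198, 240 - 198, 163, 248 - 163)
        assert rep.direction_chi2 == pytest.approx(expected, rel=1e-10)
        assert rep.direction_testable

    def test_single_shared_gene_not_testable(self):
        mouse, humans, omap = self._setup(1, 1, 0, 0)
        rep = direction_concordance(mouse, humans, omap)
        assert not rep.direction_testable


class TestMajorRelevance:
    def test_both_species_clear_included(self):
        mouse = _summary({"Filip1l": (True, 0.3987, "hyper")})
        human = _summary({"FILIP1L": (True, 0.42, "hyper")})
        out = major_relevance_genes(mouse, human, _map([("Filip1l", "FILIP1L")]))
        assert list(out["mouse_gene"]) == ["Filip1l"]

    def test_human_below_threshold_excluded(self):
        mouse = _summary({"Ga": (True, 0.40, "hyper")})
        human = _summary({"HA": (True, 0.25, "hyper")})
        assert len(major_relevance_genes(mouse, human, _map([("Ga", "HA")]))) == 0

    def test_nonsignificant_mouse_excluded(self):
        mouse = _summary({"Ga": (False, 0.40, "hyper")})
        human = _summary({"HA": (True, 0.40, "hyper")})
        assert len(major_relevance_genes(mouse, human, _map([("Ga", "HA")]))) == 0

    def test_sorted_by_min_effect_descending(self):
        mouse = _summary({"Ga": (True, 0.5, "hyper"), "Gb": (True, 0.9, "hyper")})
        human = _summary({"HA": (True, 0.8, "hyper"), "HB": (True, 0.6, "hyper")})
        out = major_relevance_genes(mouse, human, _map([("Ga", "HA"), ("Gb", "HB")]))
        assert list(out["mouse_gene"]) == ["Gb", "Ga"]  # min 0.6 > min 0.5

    def test_symmetric_under_species_swap(self):
        mouse = _summary({"Ga": (True, 0.5, "hyper"), "Gb": (True, 0.2, "hyper")})
        human = _summary({"HA": (True, 0.8, "hyper"), "HB": (True, 0.9, "hyper")})
        omap = _map([("Ga", "HA"), ("Gb", "HB")])
        fwd = major_relevance_genes(mouse, human, omap)
        inv = OrthologMap(
            pairs=omap.pairs.rename(
                columns={"mouse_gene": "human_gene", "human_gene": "mouse_gene"}
            )
        )
        rev = major_relevance_genes(human, mouse, inv)
        assert set(zip(fwd["mouse_gene"], fwd["human_gene"])) == set(
            zip(rev["human_gene"], rev["mouse_gene"])
        )


class TestRiskConcordance:
    def _inputs(self, signs_risk, signs_tumour):
        n = len(signs_risk)
        pos = [1000 + 10 * i for i in range(n)]
        risk = _dm_result(
            [("chr3", p, 0.35 * s, 0.01, True) for p, s in zip(pos, signs_risk)],
            fdr_threshold=0.05,
        )
        tum = _dm_result(
            [("chr3", p, 0.45 * s, 0.01, True) for p, s in zip(pos, signs_tumour)]
        )
        return risk, tum, risk.table.index

    @pytest.mark.parametrize(
        "k,n", [(8, 9), (9, 9), (5, 9), (3, 5), (12, 20)]
    )
    def test_exact_tail_matches_enumeration(self, k, n):
        signs_t = [1] * n
        signs_r = [1] * k + [-1] * (n - k)
        risk, tum, loci = self._inputs(signs_r, signs_t)
        res = risk_concordance(risk, tum, loci)
        assert res.n_shared == n and res.n_concordant == k
        assert res.p_value == pytest.approx(binomial_tail_oracle(k, n), rel=1e-12)

    def test_eight_of_nine_is_significant(self):
        risk, tum, loci = self._inputs([1] * 8 + [-1], [1] * 9)
        res = risk_concordance(risk, tum, loci)
        assert res.p_value == pytest.approx(10 / 512)
        assert res.p_value < 0.05

    def test_no_shared_loci_not_testable(self):
        risk, tum, _ = self._inputs([1], [1])
        empty = pd.MultiIndex.from_arrays([[], []], names=["chrom", "pos"])
        res = risk_concordance(risk, tum, empty)
        assert not res.testable

    def test_tumour_loci_below_clear_threshold_excluded(self):
        n = 3
        pos = [1000, 1010, 1020]
        risk = _dm_result([("chr3", p, 0.35, 0.01, True) for p in pos], 0.05)
        tum = _dm_result([("chr3", p, 0.20, 0.01, True) for p in pos])  # |d| < 0.30
        res = risk_concordance(risk, tum, risk.table.index)
        assert not res.testable
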