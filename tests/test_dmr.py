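import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import make_matrix
from crossmeth.dmr import (
    CandidateRegion,
    DMRegion,
    beta_binomial_region_test,
    find_candidate_regions,
    rank_and_fdr_regions,
    summarize_region,
)
from crossmeth.io_formats import GeneAnnotation

DESIGN = ("control", "tumour")


def greedy_window_oracle(positions, min_cpgs, max_span):
    """Exhaustive enumeration oracle: for each anchor compute the maximal
    window by scanning all positions, then apply the greedy no-overlap rule."""
    positions = sorted(positions)
    out = []
    i = 0
    while i < len(positions):
        members = [q for q in positions if positions[i] <= q <= positions[i] + max_span - 1]
        if len(members) >= min_cpgs:
            out.append(tuple(members))
            i = positions.index(members[-1]) + 1
        else:
            i += 1
    return out


def _count_matrix(positions, n_samples=4, coverage=10, chrom="chr1"):
    n = len(positions)
    cov = np.full((n, n_samples), coverage)
    meth = (cov * 0.5).astype(int)
    beta = meth / np.maximum(cov, 1)
    groups = {f"s{i}": ("control" if i < n_samples // 2 else "tumour") for i in range(n_samples)}
    return make_matrix(beta, groups, coverage=cov, meth=meth, positions=positions, chrom=chrom)


class TestFindCandidateRegions:
    def test_fifteen_cpgs_within_span_form_one_candidate(self):
        positions = [100 + 13 * i for i in range(15)]  # span 183 <= 200
        cands = find_candidate_regions(_count_matrix(positions))
        assert len(cands) == 1
        assert cands[0].n_cpgs == 15
        assert cands[0].width == positions[-1] - positions[0] + 1

    def test_fourteen_cpgs_insufficient(self):
        positions = [100 + 3 * i for i in range(14)]
        assert find_candidate_regions(_count_matrix(positions)) == []

    def test_presence_rule_excludes_sparsely_covered_cpgs(self):
        positions = [100 + 10 * i for i in range(15)]
        m = _count_matrix(positions)
        cov = m.coverage.to_numpy().copy()
        cov[0, :2] = 0  # first CpG covered in 2/4 samples < 75%
        m.coverage.iloc[:, :] = cov
        cands = find_candidate_regions(m)
        assert all(positions[0] not in c.positions for c in cands)

    @pytest.mark.parametrize("spacing,n", [(13, 30), (7, 60), (25, 40)])
    def test_matches_exhaustive_window_oracle(self, spacing, n):
        positions = [1000 + spacing * i for i in range(n)]
        cands = find_candidate_regions(_count_matrix(positions))
        expected = greedy_window_oracle(positions, 15, 200)
        assert [tuple(c.positions) for c in cands] == expected

    def test_random_positions_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            positions = sorted(
                set(rng.integers(1, 2000, size=150).tolist())
            )
            cands = find_candidate_regions(_count_matrix(positions))
            expected = greedy_window_oracle(positions, 15, 200)
            assert [tuple(c.positions) for c in cands] == expected

    def test_regions_never_overlap_nor_exceed_span(self):
        rng = np.random.default_rng(1)
        positions = sorted(set(rng.integers(1, 5000, size=400).tolist()))
        cands = find_candidate_regions(_count_matrix(positions))
        for c in cands:
            assert c.width <= 200
        for a, b in zip(cands, cands[1:]):
            assert a.end < b.start


class TestBetaBinomialTest:
    def _counts(self, y, n, n_per_group):
        total = 2 * n_per_group
        samples = [f"s{i}" for i in range(total)]
        rows = []
        for cpg in range(len(y) // total):
            for j in range(total):
                k = cpg * total + j
                rows.append({"sample": samples[j], "n_meth": y[k], "n_total": n[k]})
        groups = pd.Series(
            {s: ("control" if i < n_per_group else "tumour") for i, s in enumerate(samples)}
        )
        return pd.DataFrame(rows), groups

    def test_zero_dispersion_limit_matches_binomial_glm(self):
        rng = np.random.default_rng(7)
        n_per_group, n_cpgs = 10, 2
        total = 2 * n_per_group * n_cpgs
        n = rng.poisson(30, size=total) + 1
        g = np.tile(np.repeat([0, 1], n_per_group), n_cpgs)
        y = rng.binomial(n, np.where(g == 1, 0.45, 0.30))
        counts, groups = self._counts(y, n, n_per_group)
        p_bb, ok = beta_binomial_region_test(counts, DESIGN, groups)
        assert ok
        X = sm.add_constant(g.astype(float))
        full = sm.GLM(np.c_[y, n - y], X, family=sm.families.Binomial()).fit()
        null = sm.GLM(
            np.c_[y, n - y], np.ones((total, 1)), family=sm.families.Binomial()
        ).fit()
        p_glm = stats.chi2.sf(2 * (full.llf - null.llf), 1)
        assert abs(p_bb - p_glm) < 1e-3

    def test_identical_pooled_counts_give_large_p(self):
        y = np.array([5, 5, 5, 5, 5, 5, 5, 5] * 3)
        n = np.full_like(y, 10)
        counts, groups = self._counts(y, n, 4)
        p, ok = beta_binomial_region_test(counts, DESIGN, groups)
        assert ok and p > 0.5

    def test_planted_effect_detected_across_seeds(self):
        # 20 CpGs, 6 vs 6 samples, 30x coverage, delta beta = 0.4
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for cpg in range(20):
                for i in range(12):
                    grp = "control" if i < 6 else "tumour"
                    p_true = 0.25 if grp == "control" else 0.65
                    cov = rng.poisson(30) + 1
                    p_i = rng.beta(p_true * 49, (1 - p_true) * 49)  # rho ~ 0.02
                    rows.append(
                        {"sample": f"s{i}", "n_meth": rng.binomial(cov, p_i), "n_total": cov}
                    )
            counts = pd.DataFrame(rows)
            groups = pd.Series(
                {f"s{i}": ("control" if i < 6 else "tumour") for i in range(12)}
            )
            p, ok = beta_binomial_region_test(counts, DESIGN, groups)
            detected += int(ok and p < 0.01)
        assert detected >= 0.95 * n_seeds


class TestSummarizeRegion:
    def _region_and_matrix(self, ctrl_means, tum_means, start=100, spacing=10):
        positions = [start + spacing * i for i in range(len(ctrl_means))]
        beta = np.column_stack(
            [np.repeat([[c] for c in ctrl_means], 2, axis=1),
             np.repeat([[t] for t in tum_means], 2, axis=1)]
        )
        groups = {"c1": "control", "c2": "control", "t1": "tumour", "t2": "tumour"}
        m = make_matrix(beta, groups, positions=positions)
        region = CandidateRegion(
            chrom="chr1", start=positions[0], end=positions[-1], positions=positions
        )
        return region, m

    def test_median_of_differences(self):
        region, m = self._region_and_matrix([0.1, 0.2, 0.3], [0.2, 0.4, 0.6])
        res = summarize_region(region, m, DESIGN)
        assert res.median_difference == pytest.approx(0.2)

    def test_constant_levels_reproduce_both_medians_and_difference(self):
        region, m = self._region_and_matrix([0.3423] * 3, [0.7602] * 3)
        res = summarize_region(region, m, DESIGN)
        assert res.control_median == pytest.approx(0.3423)
        assert res.tumour_median == pytest.approx(0.7602)
        assert res.median_difference == pytest.approx(0.4179)

    def test_heterogeneous_cpgs_median_difference_differs_from_median_gap(self):
        # fixture built so group medians are 34.23%/76.02% while the median
        # per-CpG difference is 39.87% — the top-DMR pattern where
        # median-of-differences != difference-of-medians
        ctrl = [0.30, 0.3423, 0.60]
        tum = [0.6987, 0.7602, 0.90]
        region, m = self._region_and_matrix(ctrl, tum)
        res = summarize_region(region, m, DESIGN)
        assert res.control_median == pytest.approx(0.3423)
        assert res.tumour_median == pytest.approx(0.7602)
        assert res.median_difference == pytest.approx(0.3987)
        assert res.median_difference != pytest.approx(
            res.tumour_median - res.control_median
        )

    def test_gene_context_assignment(self):
        genes = GeneAnnotation(
            genes=pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "start": [90, 5000],
                    "end": [200, 6000],
                    "strand": ["+", "+"],
                    "symbol": ["GENIC", "DOWNSTREAM"],
                }
            )
        )
        region, m = self._region_and_matrix([0.2] * 3, [0.6] * 3, start=100)
        res = summarize_region(region, m, DESIGN, annotation=genes)
        assert res.gene_context == "genic" and "GENIC" in res.gene_symbols
        # same region against a gene starting 1 kb downstream -> promoter
        promoter_genes = GeneAnnotation(
            genes=pd.DataFrame(
                {"chrom": ["chr1"], "start": [1000], "end": [2000],
                 "strand": ["+"], "symbol": ["PROM"]}
            )
        )
        res2 = summarize_region(region, m, DESIGN, annotation=promoter_genes)
        assert res2.gene_context == "promoter"


class TestRankAndFdr:
    def _mk(self, chrom, start, diff, p):
        return DMRegion(
            chrom=chrom, start=start, end=start + 100, n_cpgs=15,
            control_median=0.3, tumour_median=0.3 + diff,
            median_difference=diff, median_p=p,
        )

    def test_bh_by_hand_on_two_regions(self):
        regions = [self._mk("chr1", 1, 0.1, 0.001), self._mk("chr1", 500, 0.2, 0.5)]
        out = rank_and_fdr_regions(regions)
        by_start = {r.start: r for r in out}
        assert by_start[1].fdr == pytest.approx(0.002)
        assert by_start[500].fdr == pytest.approx(0.5)

    def test_sorted_by_absolute_difference_descending(self):
        regions = [
            self._mk("chr1", 1, 0.1, 0.01),
            self._mk("chr2", 1, -0.4, 0.01),
            self._mk("chr3", 1, 0.2, 0.01),
        ]
        out = rank_and_fdr_regions(regions)
        assert [abs(r.median_difference) for r in out] == [0.4, 0.2, 0.1]

    def test_all_hyper_means_zero_hypo(self):
        regions = [self._mk("chr1", s, 0.1 * k, 0.01) for k, s in enumerate([1, 500], 1)]
        out = rank_and_fdr_regions(regions)
        assert all(r.direction == "hyper" for r in out)

    def test_ties_break_by_chrom_then_start(self):
        regions = [
            self._mk("chr2", 10, 0.3, 0.01),
            self._mk("chr1", 99, 0.3, 0.01),
            self._mk("chr1", 5, 0.3, 0.01),
        ]
        out = rank_and_fdr_regions(regions)
        assert [(r.chrom, r.start) for r in out] == [("chr1", 5), ("chr1", 99), ("chr2", 10)]

    def test_nonconverged_regions_excluded_from_fdr(self):
        regions = [
            self._mk("chr1", 1, 0.3, 0.02),
            self._mk("chr1", 500, 0.2, float("nan")),
        ]
        out = rank_and_fdr_regions(regions)
        good = [r for r in out if np.isfinite(r.median_p)][0]
        bad = [r for r in out if not np.isfinite(r.median_p)][0]
        assert good.fdr == pytest.approx(0.02)
        assert np.isnan(bad.fdr) and not bad.significant

    def test_width_always_inclusive(self):
        r = self._mk("chr1", 57391482, 0.4, 0.001)
        r.end = 57391657
        assert r.width == 176
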