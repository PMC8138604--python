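"""Differentially methylated region (DMR) detection.

CpGs are agglomerated into candidate regions by a deterministic greedy
scan (a cluster needs at least ``min_cpgs`` CpGs within ``max_span_bp``
base pairs, each CpG covered in at least ``min_presence`` of the samples),
and each candidate is tested with a beta-binomial regression: methylated
read counts follow a beta-binomial with a logit-linear mean
(intercept + group) and one region-level dispersion, fitted by maximum
likelihood; the p-value comes from the likelihood-ratio test of the group
coefficient against chi-squared(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dm_cpg import bh_fdr
from .io_formats import GeneAnnotation
from .methylation import MethMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRegion",
    "DMRegion",
    "find_candidate_regions",
    "beta_binomial_region_test",
    "summarize_region",
    "rank_and_fdr_regions",
    "call_dmrs",
]


@dataclass
class CandidateRegion:
    """A maximal cluster of nearby CpGs eligible for regional testing."""

    chrom: str
    start: int  # 1-based inclusive, position of first member CpG
    end: int  # position of last member CpG
    positions: list[int] = field(default_factory=list)

    @property
    def n_cpgs(self) -> int:
        return len(self.positions)

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class DMRegion:
    """Tested region with Table-style summary statistics.

    ``median_p`` is the regional beta-binomial LRT p-value (used for FDR);
    ``median_cpg_p`` additionally carries the median of per-CpG p-values
    when a per-CpG DMResult was supplied. Medians are over member CpGs of
    the per-CpG group-mean beta; ``median_difference`` is the median over
    member CpGs of the per-CpG (case mean - control mean), which is not in
    general the difference of the two median columns.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    control_median: float
    tumour_median: float
    median_difference: float
    median_p: float
    fdr: float = float("nan")
    gene_symbols: str = ""
    gene_context: str = "intergenic"
    median_cpg_p: float = float("nan")
    converged: bool = True
    significant: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> str:
        if self.median_difference > 0:
            return "hyper"
        if self.median_difference < 0:
            return "hypo"
        return "none"


def find_candidate_regions(
    matrix: MethMatrix,
    min_cpgs: int = 15,
    max_span_bp: int = 200,
    min_presence: float = 0.75,
) -> list[CandidateRegion]:
    """Greedy left-to-right agglomeration of CpGs into candidate regions.

    Per chromosome, CpGs covered (>= 1 read) in at least ``min_presence``
    of samples are scanned in position order; from each anchor the window
    is grown to the rightmost CpG within ``max_span_bp`` (1-based inclusive
    width). A maximal window with >= ``min_cpgs`` members is emitted and
    the scan resumes after it, so emitted regions never overlap.
    """
    if matrix.coverage is not None:
        present = (matrix.coverage >= 1).mean(axis=1) >= min_presence
    else:
        present = matrix.beta.notna().mean(axis=1) >= min_presence
    loci = matrix.beta.index[present]
    out: list[CandidateRegion] = []
    df = pd.DataFrame({"chrom": loci.get_level_values(0), "pos": loci.get_level_values(1)})
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy())
        i = 0
        n = len(pos)
        while i < n:
            # rightmost j with inclusive width pos[j]-pos[i]+1 <= max_span_bp
            j = int(np.searchsorted(pos, pos[i] + max_span_bp - 1, side="right")) - 1
            if j - i + 1 >= min_cpgs:
                members = [int(p) for p in pos[i : j + 1]]
                out.append(
                    CandidateRegion(
                        chrom=str(chrom), start=members[0], end=members[-1], positions=members
                    )
                )
                i = j + 1
            else:
                i += 1
    logger.info("find_candidate_regions: %d candidates", len(out))
    return out


def _betabinom_negll(params: np.ndarray, y, n, group, lchoose) -> float:
    b0, b1, theta = params
    rho = 1.0 / (1.0 + np.exp(-theta))
    rho = min(max(rho, 1e-9), 1.0 - 1e-9)
    eta = np.clip(b0 + b1 * group, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    conc = (1.0 - rho) / rho
    a = p * conc
    b = (1.0 - p) * conc
    ll = (
        lchoose
        + special.betaln(y + a, n - y + b)
        - special.betaln(a, b)
    )
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(np.sum(ll))


def _fit_betabinom(y, n, group, free_slope: bool):
    """Maximise the beta-binomial likelihood; returns (negll, params, ok)."""
    lchoose = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    pooled = np.clip(y.sum() / n.sum(), 1e-4, 1 - 1e-4)
    b0_pool = float(np.log(pooled / (1 - pooled)))
    starts = [np.array([b0_pool, 0.0, -4.0])]
    if free_slope:
        g1 = group == 1
        p1 = np.clip(y[g1].sum() / max(n[g1].sum(), 1), 1e-4, 1 - 1e-4)
        p0 = np.clip(y[~g1].sum() / max(n[~g1].sum(), 1), 1e-4, 1 - 1e-4)
        b1_init = float(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)))
        starts.insert(0, np.array([float(np.log(p0 / (1 - p0))), b1_init, -4.0]))

    def obj(x):
        if free_slope:
            return _betabinom_negll(x, y, n, group, lchoose)
        return _betabinom_negll(np.array([x[0], 0.0, x[1]]), y, n, group, lchoose)

    best = None
    for s in starts:
        x0 = s if free_slope else np.array([s[0], s[2]])
        res = optimize.minimize(obj, x0, method="L-BFGS-B", options={"maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    ok = best is not None and np.isfinite(best.fun) and best.fun < 1e11
    return best.fun, best.x, ok


def beta_binomial_region_test(
    region_counts: pd.DataFrame, design: tuple[str, str], groups: pd.Series
) -> tuple[float, bool]:
    """Likelihood-ratio test of the group effect in a beta-binomial model.

    ``region_counts`` has one row per (CpG, sample) observation with
    columns n_meth, n_total, sample. Returns (p_value, converged); the
    p-value is NaN when the optimiser fails.
    """
    control, case = design
    y = region_counts["n_meth"].to_numpy(dtype=float)
    n = region_counts["n_total"].to_numpy(dtype=float)
    grp = groups.loc[region_counts["sample"]].to_numpy()
    g = np.where(grp == case, 1.0, 0.0)
    keep = n > 0
    y, n, g = y[keep], n[keep], g[keep]
    if len(y) == 0 or len(np.unique(g)) < 2:
        return float("nan"), False
    try:
        ll_full, _, ok_full = _fit_betabinom(y, n, g, free_slope=True)
        ll_null, _, ok_null = _fit_betabinom(y, n, g, free_slope=False)
    except Exception:
        return float("nan"), False
    if not (ok_full and ok_null):
        return float("nan"), False
    lrt = max(0.0, 2.0 * (ll_null - ll_full))
    p = float(stats.chi2.sf(lrt, df=1))
    return p, True


def summarize_region(
    region: CandidateRegion,
    matrix: MethMatrix,
    design: tuple[str, str],
    annotation: GeneAnnotation | None = None,
    promoter_window_bp: int = 1500,
    p_value: float = float("nan"),
    cpg_p_values: pd.Series | None = None,
) -> DMRegion:
    """Table-style summary of one region.

    Group medians are medians over member CpGs of the per-CpG group-mean
    beta; median_difference is the median over member CpGs of the per-CpG
    (case mean - control mean). Gene context comes from annotation
    overlap: 'promoter' when the region overlaps the configured upstream
    window of a TSS, 'genic' when it overlaps a gene body, else
    'intergenic'.
    """
    control, case = design
    idx = pd.MultiIndex.from_product([[region.chrom], region.positions], names=["chrom", "pos"])
    idx = idx.intersection(matrix.beta.index)
    ctrl = matrix.beta.loc[idx, matrix.group_samples(control)].mean(axis=1, skipna=True)
    tum = matrix.beta.loc[idx, matrix.group_samples(case)].mean(axis=1, skipna=True)
    diffs = tum - ctrl

    gene_symbols = ""
    context = "intergenic"
    if annotation is not None and len(annotation):
        genes = annotation.genes
        same = genes[genes["chrom"] == region.chrom]
        genic_hits = []
        promoter_hits = []
        for row in same.itertuples(index=False):
            if region.start <= row.end and region.end >= row.start:
                genic_hits.append(row.symbol)
            else:
                if row.strand == "-":
                    win_lo, win_hi = row.end + 1, row.end + promoter_window_bp
                else:
                    win_lo, win_hi = row.start - promoter_window_bp, row.start - 1
                if region.start <= win_hi and region.end >= win_lo:
                    promoter_hits.append(row.symbol)
        if genic_hits:
            context = "genic"
            gene_symbols = ", ".join(sorted(set(genic_hits)))
        elif promoter_hits:
            context = "promoter"
            gene_symbols = ", ".join(sorted(set(promoter_hits)))

    median_cpg_p = float("nan")
    if cpg_p_values is not None:
        shared = idx.intersection(cpg_p_values.index)
        if len(shared):
            median_cpg_p = float(np.nanmedian(cpg_p_values.loc[shared]))

    return DMRegion(
        chrom=region.chrom,
        start=region.start,
        end=region.end,
        n_cpgs=region.n_cpgs,
        control_median=float(np.nanmedian(ctrl)),
        tumour_median=float(np.nanmedian(tum)),
        median_difference=float(np.nanmedian(diffs)),
        median_p=p_value,
        gene_symbols=gene_symbols,
        gene_context=context,
        median_cpg_p=median_cpg_p,
        converged=np.isfinite(p_value),
    )


def rank_and_fdr_regions(
    regions: list[DMRegion], fdr_threshold: float = 0.10
) -> list[DMRegion]:
    """BH-FDR over tested regions, then rank by |median_difference| descending.

    Regions whose test failed to converge keep fdr = NaN and are excluded
    from the BH denominator. Ties in |median_difference| break by
    (chrom, start).
    """
    tested = [r for r in regions if np.isfinite(r.median_p)]
    skipped = len(regions) - len(tested)
    if skipped:
        logger.warning("rank_and_fdr_regions: %d non-converged regions excluded from FDR", skipped)
    if tested:
        qs = bh_fdr([r.median_p for r in tested])
        for r, q in zip(tested, qs):
            r.fdr = float(q)
            r.significant = bool(q < fdr_threshold)
    return sorted(regions, key=lambda r: (-abs(r.median_difference), r.chrom, r.start))


def call_dmrs(
    matrix: MethMatrix,
    design: tuple[str, str],
    annotation: GeneAnnotation | None = None,
    min_cpgs: int = 15,
    max_span_bp: int = 200,
    min_presence: float = 0.75,
    fdr_threshold: float = 0.10,
    promoter_window_bp: int = 1500,
    cpg_p_values: pd.Series | None = None,
) -> list[DMRegion]:
    """End-to-end DMR calling: agglomerate, test, summarise, rank."""
    if matrix.coverage is None or matrix.meth is None:
        raise ValueError("DMR calling needs read counts (sequencing-mode matrix)")
    candidates = find_candidate_regions(matrix, min_cpgs, max_span_bp, min_presence)
    out: list[DMRegion] = []
    for cand in candidates:
        idx = pd.MultiIndex.from_product(
            [[cand.chrom], cand.positions], names=["chrom", "pos"]
        ).intersection(matrix.beta.index)
        meth = matrix.meth.loc[idx]
        cov = matrix.coverage.loc[idx]
        long = pd.DataFrame(
            {
                "sample": np.tile(meth.columns, len(idx)),
                "n_meth": meth.to_numpy().ravel(),
                "n_total": cov.to_numpy().ravel(),
            }
        )
        p, _converged = beta_binomial_region_test(long, design, matrix.groups)
        out.append(
            summarize_region(
                cand,
                matrix,
                design,
                annotation=annotation,
                promoter_window_bp=promoter_window_bp,
                p_value=p,
                cpg_p_values=cpg_p_values,
            )
        )
    return rank_and_fdr_regions(out, fdr_threshold=fdr_threshold)
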