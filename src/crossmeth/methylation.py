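"""Core methylation quantities: beta/M values, filtering, replicate merging,
sample-level methylation summaries and the BS-vs-oxBS (5hmC) noise check.

The beta value of a CpG is the methylated read fraction

    beta = n_meth / n_total

and the M value is the logit-like transform used for linear modelling,

    M = log2((beta + c) / (1 - beta + c)),   c = 0.01,

whose stabilising constant keeps M finite at beta = 0 and beta = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ArrayDataset, CpGCountTable

logger = logging.getLogger(__name__)

M_CONSTANT = 0.01

__all__ = [
    "M_CONSTANT",
    "MethMatrix",
    "GroupMeanSummary",
    "compute_beta",
    "compute_m",
    "m_to_beta",
    "merge_technical_replicates",
    "build_meth_matrix",
    "array_to_meth_matrix",
    "filter_loci",
    "filter_array_probes",
    "average_methylation",
    "pearson_correlation",
    "assess_hydroxymethylation",
]


def compute_beta(n_meth, n_total):
    """Methylation fraction n_meth / n_total; errors on zero coverage."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if np.any(n_total < 1):
        raise ValueError("n_total must be >= 1 to compute a beta value")
    out = n_meth / n_total
    return out.item() if out.ndim == 0 else out


def compute_m(beta, cte: float = M_CONSTANT):
    """M value log2((beta + cte) / (1 - beta + cte)); finite on [0, 1]."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta outside [0, 1]")
    out = np.log2((b + cte) / (1.0 - b + cte))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m, cte: float = M_CONSTANT):
    """Invert the M transform: beta = (r(1 + cte) - cte) / (1 + r), r = 2**M."""
    r = np.exp2(np.asarray(m, dtype=float))
    out = (r * (1.0 + cte) - cte) / (1.0 + r)
    return out.item() if out.ndim == 0 else out


@dataclass
class MethMatrix:
    """Loci x samples methylation matrices with group labels.

    ``beta`` and ``m`` share the same index (a (chrom, pos) MultiIndex for
    sequencing data, probe ids for arrays) and sample columns. ``coverage``
    and ``meth`` hold read counts and are None in array mode. ``groups``
    maps sample -> group label.
    """

    beta: pd.DataFrame
    m: pd.DataFrame
    groups: pd.Series
    coverage: pd.DataFrame | None = None
    meth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(self.m.columns):
            raise ValueError("beta and m sample columns differ")
        if not self.beta.index.equals(self.m.index):
            raise ValueError("beta and m locus indices differ")
        missing = [s for s in self.beta.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[list(self.beta.columns)]

    @property
    def is_array(self) -> bool:
        return self.coverage is None

    @property
    def n_loci(self) -> int:
        return self.beta.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_loci(self, index) -> "MethMatrix":
        return MethMatrix(
            beta=self.beta.loc[index],
            m=self.m.loc[index],
            groups=self.groups,
            coverage=None if self.coverage is None else self.coverage.loc[index],
            meth=None if self.meth is None else self.meth.loc[index],
        )


def merge_technical_replicates(
    tables: Sequence[CpGCountTable], replicate_map: Mapping[str, str]
) -> list[CpGCountTable]:
    """Sum counts of technical replicates into one table per biological sample.

    ``replicate_map`` maps each input sample_id to the merged sample_id.
    Loci present in only a subset of a group's replicates keep their counts.
    """
    by_id = {t.sample_id: t for t in tables}
    unknown = [s for s in replicate_map if s not in by_id]
    if unknown:
        raise ValueError(f"replicate_map references unknown samples: {unknown}")
    full_map = {t.sample_id: replicate_map.get(t.sample_id, t.sample_id) for t in tables}
    merged: dict[str, list[pd.DataFrame]] = {}
    for t in tables:
        merged.setdefault(full_map[t.sample_id], []).append(t.records)
    out = []
    for new_id, frames in merged.items():
        if len(frames) == 1:
            combined = frames[0].copy()
        else:
            combined = (
                pd.concat(frames)
                .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_total"]]
                .sum()
            )
        combined = combined.sort_values(["chrom", "pos"]).reset_index(drop=True)
        out.append(CpGCountTable(sample_id=new_id, records=combined))
    return out


def build_meth_matrix(
    tables: Sequence[CpGCountTable],
    groups: Mapping[str, str],
    cte: float = M_CONSTANT,
) -> MethMatrix:
    """Assemble per-sample count tables into a loci x samples MethMatrix.

    The locus index is the union over samples; coverage is 0 and beta/M are
    NaN where a sample lacks the locus.
    """
    sample_ids = [t.sample_id for t in tables]
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ValueError(f"no group label for samples: {missing}")
    meth_cols = {}
    cov_cols = {}
    for t in tables:
        idx = pd.MultiIndex.from_frame(t.records[["chrom", "pos"]])
        meth_cols[t.sample_id] = pd.Series(t.records["n_meth"].to_numpy(), index=idx)
        cov_cols[t.sample_id] = pd.Series(t.records["n_total"].to_numpy(), index=idx)
    meth = pd.DataFrame(meth_cols).sort_index()
    cov = pd.DataFrame(cov_cols).sort_index()
    meth.index.names = ["chrom", "pos"]
    cov.index.names = ["chrom", "pos"]
    covv = cov.to_numpy(dtype=float)
    methv = meth.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(covv > 0, methv / covv, np.nan)
    betadf = pd.DataFrame(beta, index=cov.index, columns=cov.columns)
    mdf = pd.DataFrame(
        np.log2((beta + cte) / (1.0 - beta + cte)), index=cov.index, columns=cov.columns
    )
    cov = cov.fillna(0).astype(np.int64)
    meth = meth.fillna(0).astype(np.int64)
    return MethMatrix(
        beta=betadf,
        m=mdf,
        groups=pd.Series(dict(groups)),
        coverage=cov,
        meth=meth,
    )


def array_to_meth_matrix(
    ds: ArrayDataset, groups: Mapping[str, str], cte: float = M_CONSTANT
) -> MethMatrix:
    """Wrap an ArrayDataset's beta matrix as a coverage-free MethMatrix."""
    beta = ds.beta
    m = pd.DataFrame(
        np.log2((beta.to_numpy(dtype=float) + cte) / (1.0 - beta.to_numpy(dtype=float) + cte)),
        index=beta.index,
        columns=beta.columns,
    )
    return MethMatrix(beta=beta, m=m, groups=pd.Series(dict(groups)))


def filter_loci(
    matrix: MethMatrix, min_coverage: int = 8, min_meth_reads_total: int = 6
) -> MethMatrix:
    """Quality filter for sequencing data.

    Keeps loci where (i) the minimum coverage across samples is at least
    ``min_coverage`` (every sample contributes an informative beta) and
    (ii) the methylated reads summed over all samples reach
    ``min_meth_reads_total`` (at least some methylation present). Counts
    removed by each rule are logged.
    """
    if matrix.coverage is None or matrix.meth is None:
        raise ValueError(
            "matrix has no read counts (array mode); use filter_array_probes instead"
        )
    min_cov = matrix.coverage.min(axis=1)
    meth_sum = matrix.meth.sum(axis=1)
    rule_cov = min_cov >= min_coverage
    rule_meth = meth_sum >= min_meth_reads_total
    keep = rule_cov & rule_meth
    logger.info(
        "filter_loci: %d/%d retained (%d failed coverage >= %dx, %d failed >= %d methylated reads)",
        int(keep.sum()),
        len(keep),
        int((~rule_cov).sum()),
        min_coverage,
        int((~rule_meth).sum()),
        min_meth_reads_total,
    )
    return matrix.subset_loci(keep[keep].index)


def filter_array_probes(ds: ArrayDataset, max_detection_p: float = 0.01) -> ArrayDataset:
    """Drop probes whose detection p exceeds the threshold in any sample."""
    bad = (ds.detection_p > max_detection_p).any(axis=1)
    logger.info(
        "filter_array_probes: removed %d/%d probes at detection p > %g",
        int(bad.sum()),
        len(bad),
        max_detection_p,
    )
    keep = ~bad
    return ArrayDataset(
        beta=ds.beta.loc[keep],
        detection_p=ds.detection_p.loc[keep],
        probe_annotation=ds.probe_annotation.loc[keep],
    )


@dataclass
class GroupMeanSummary:
    """Sample-level mean methylation with group contrasts.

    ``sample_means``: mean beta per sample over retained loci.
    ``group_means``: mean of sample means per group.
    ``anova_f``/``anova_p``: one-way ANOVA across groups (equals the pooled
    two-sided t-test when there are exactly two groups).
    ``contrasts``: per group pair — difference of group means, p-value
    (Tukey HSD when >2 groups, pooled t-test for 2) and testability flag.
    """

    sample_means: pd.Series
    group_means: pd.Series
    anova_f: float
    anova_p: float
    contrasts: pd.DataFrame


def average_methylation(matrix: MethMatrix) -> GroupMeanSummary:
    """Per-sample mean methylation and ANOVA/Tukey group comparison.

    Operates on one number per sample (the sample's mean beta over loci),
    mirroring how global methylation levels are compared between tumour
    and control groups.
    """
    sample_means = matrix.beta.mean(axis=0, skipna=True)
    groups = matrix.groups
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups to compare average methylation")
    by_group = {g: sample_means[groups.index[groups == g]].to_numpy() for g in labels}
    group_means = pd.Series({g: float(np.mean(v)) for g, v in by_group.items()})

    testable_groups = [g for g in labels if len(by_group[g]) >= 2]
    if len(testable_groups) >= 2:
        arrays = [by_group[g] for g in testable_groups]
        if np.ptp(np.concatenate(arrays)) == 0:
            anova_f, anova_p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*arrays)
            anova_f, anova_p = float(f), float(p)
    else:
        anova_f, anova_p = float("nan"), float("nan")

    rows = []
    if len(labels) == 2:
        g1, g2 = labels
        testable = len(by_group[g1]) >= 2 and len(by_group[g2]) >= 2
        if testable:
            _, p = stats.ttest_ind(by_group[g2], by_group[g1], equal_var=True)
            p = float(p) if np.isfinite(p) else 1.0
        else:
            p = float("nan")
        rows.append(
            {
                "group_a": g1,
                "group_b": g2,
                "difference": group_means[g2] - group_means[g1],
                "p_value": p,
                "testable": testable,
            }
        )
    else:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        testable_mask = {g: len(by_group[g]) >= 2 for g in labels}
        usable = [g for g in labels if testable_mask[g]]
        tukey_p: dict[frozenset, float] = {}
        if len(usable) >= 2 and sum(len(by_group[g]) for g in usable) > len(usable):
            values = np.concatenate([by_group[g] for g in usable])
            labs = np.concatenate([[g] * len(by_group[g]) for g in usable])
            if np.ptp(values) > 0:
                res = pairwise_tukeyhsd(values, labs)
                summ = pd.DataFrame(
                    res._results_table.data[1:], columns=res._results_table.data[0]
                )
                for _, r in summ.iterrows():
                    tukey_p[frozenset((r["group1"], r["group2"]))] = float(r["p-adj"])
            else:
                for i, a in enumerate(usable):
                    for b in usable[i + 1 :]:
                        tukey_p[frozenset((a, b))] = 1.0
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                testable = testable_mask[a] and testable_mask[b]
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "difference": group_means[b] - group_means[a],
                        "p_value": tukey_p.get(frozenset((a, b)), float("nan")),
                        "testable": testable,
                    }
                )
    contrasts = pd.DataFrame(rows)
    return GroupMeanSummary(
        sample_means=sample_means,
        group_means=group_means,
        anova_f=anova_f,
        anova_p=anova_p,
        contrasts=contrasts,
    )


def pearson_correlation(x, y) -> float:
    """Pearson correlation coefficient; errors on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class HydroxymethylationAssessment:
    """Per-locus/sample 5hmC estimates (beta_BS - beta_oxBS) plus a verdict."""

    estimates: pd.DataFrame
    mean_estimate: float
    standard_error: float
    z: float
    verdict: str  # "noise" or "signal"


def assess_hydroxymethylation(
    bs: MethMatrix, oxbs: MethMatrix, se_multiple: float = 2.0
) -> HydroxymethylationAssessment:
    """Estimate 5hmC as the BS - oxBS beta contrast and classify it as noise
    or signal.

    Standard bisulfite conversion reads 5mC + 5hmC while the oxidative
    protocol reads 5mC only, so the per-locus difference estimates the
    hydroxymethylation level (and may go negative through noise). The
    dataset-level verdict is "noise" when |mean| <= se_multiple standard
    errors of the mean over all locus/sample estimates.
    """
    if not bs.beta.index.equals(oxbs.beta.index) or bs.samples != oxbs.samples:
        raise ValueError("BS and oxBS matrices must share loci and samples")
    est = bs.beta - oxbs.beta
    flat = est.to_numpy(dtype=float).ravel()
    flat = flat[~np.isnan(flat)]
    if len(flat) < 2:
        raise ValueError("not enough paired observations")
    mean = float(np.mean(flat))
    se = float(np.std(flat, ddof=1) / np.sqrt(len(flat)))
    z = mean / se if se > 0 else (0.0 if mean == 0 else np.inf)
    verdict = "noise" if abs(z) <= se_multiple else "signal"
    return HydroxymethylationAssessment(
        estimates=est, mean_estimate=mean, standard_error=se, z=float(z), verdict=verdict
    )
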