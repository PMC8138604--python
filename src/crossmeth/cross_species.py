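"""Gene-level cross-species comparison of differential methylation.

Loci are assigned to genes (gene body plus a promoter window upstream of
the TSS), per-gene differential-methylation summaries are built for each
species, and three questions are asked across the ortholog map:

* enrichment — are human orthologs of mouse-DM genes more often DM than
  the remaining tested human genes? (Pearson chi-squared on the 2x2
  table, Bonferroni across subtypes);
* direction concordance — among genes DM in both species, how often do
  the directions agree, and does the concordance differ between human
  subtypes? (chi-squared on concordant/discordant counts);
* major relevance — genes with at least one significant locus with
  |delta beta| >= 30% in BOTH species through the ortholog map.

A clinical concordance check compares direction of change between a
high-vs-low-risk contrast and the tumour-vs-control contrast at shared
loci of a target gene, with a one-sided exact binomial test at null 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .dm_cpg import DMResult
from .io_formats import GeneAnnotation
from .orthology import OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDMSummary",
    "ConcordanceReport",
    "RiskConcordance",
    "annotate_loci_to_genes",
    "summarize_genes",
    "enrichment_test",
    "direction_concordance",
    "major_relevance_genes",
    "risk_concordance",
    "pearson_chi2",
]


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0:
        return 0.0, 1.0
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    expected = np.outer(rows, cols) / table.sum()
    if np.any(expected == 0):
        return 0.0, 1.0
    if np.any(expected < 5):
        logger.warning("pearson_chi2: expected cell count < 5; asymptotic p may be inaccurate")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def annotate_loci_to_genes(
    dm: DMResult | pd.DataFrame,
    annotation: GeneAnnotation,
    promoter_window_bp: int = 1500,
) -> pd.DataFrame:
    """Assign each locus to every gene whose body or promoter window
    contains it.

    The promoter window is ``promoter_window_bp`` upstream of the TSS
    (strand-aware). Input loci come from the DMResult's (chrom, pos) index
    or a frame with chrom/pos columns. Returns long-format rows
    (chrom, pos, gene); intergenic loci are absent. A locus overlapping
    several genes (for example two genes on opposite strands) yields one
    row per gene.
    """
    table = dm.table if isinstance(dm, DMResult) else dm
    if isinstance(table.index, pd.MultiIndex):
        loci = pd.DataFrame(
            {
                "Chromosome": table.index.get_level_values(0),
                "pos": table.index.get_level_values(1),
            }
        )
    else:
        loci = table[["chrom", "pos"]].rename(columns={"chrom": "Chromosome"}).copy()
    loci = loci.drop_duplicates()
    # 1-based inclusive position -> 0-based half-open single-base interval
    loci["Start"] = loci["pos"] - 1
    loci["End"] = loci["pos"]

    genes = annotation.genes
    minus = genes["strand"] == "-"
    ext_start = np.where(minus, genes["start"], genes["start"] - promoter_window_bp)
    ext_end = np.where(minus, genes["end"] + promoter_window_bp, genes["end"])
    gene_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes["chrom"].to_numpy(),
                "Start": np.maximum(ext_start - 1, 0),  # to 0-based half-open
                "End": ext_end,
                "gene": genes["symbol"].to_numpy(),
            }
        )
    )
    hits = pr.PyRanges(loci).join(gene_gr, apply_strand_suffix=False)
    if hits.empty:
        return pd.DataFrame(columns=["chrom", "pos", "gene"])
    out = hits.df[["Chromosome", "pos", "gene"]].rename(columns={"Chromosome": "chrom"})
    out["chrom"] = out["chrom"].astype(str)
    return out.sort_values(["chrom", "pos", "gene"]).reset_index(drop=True)


@dataclass
class GeneDMSummary:
    """Per-gene differential-methylation status for one dataset.

    ``table`` is indexed by gene with columns n_tested_loci,
    n_significant_loci, max_abs_delta_beta (among significant loci, NaN if
    none), direction (at the max-|delta| significant locus), has_dm,
    has_clear_dm (has_dm and max |delta beta| >= clear_threshold).
    """

    table: pd.DataFrame
    clear_threshold: float = 0.30

    def genes_with_dm(self) -> set[str]:
        return set(self.table.index[self.table["has_dm"]])

    def genes_with_clear_dm(self) -> set[str]:
        return set(self.table.index[self.table["has_clear_dm"]])


def summarize_genes(
    dm: DMResult, assignments: pd.DataFrame, clear_threshold: float = 0.30
) -> GeneDMSummary:
    """Aggregate per-locus calls to per-gene flags and maxima."""
    table = dm.table
    if isinstance(table.index, pd.MultiIndex):
        keyed = table.reset_index()
        keyed.columns = ["chrom", "pos"] + list(table.columns)
    else:
        keyed = table.reset_index(drop=True)
    merged = assignments.merge(keyed, on=["chrom", "pos"], how="inner")
    merged = merged[merged["testable"]]
    rows = []
    for gene, sub in merged.groupby("gene", sort=True):
        sig = sub[sub["significant"]]
        if len(sig):
            imax = sig["delta_beta"].abs().idxmax()
            max_abs = float(abs(sig.loc[imax, "delta_beta"]))
            direction = str(sig.loc[imax, "direction"])
        else:
            max_abs = float("nan")
            direction = "none"
        rows.append(
            {
                "gene": gene,
                "n_tested_loci": int(len(sub)),
                "n_significant_loci": int(len(sig)),
                "max_abs_delta_beta": max_abs,
                "direction": direction,
                "has_dm": bool(len(sig)),
                "has_clear_dm": bool(len(sig)) and max_abs >= clear_threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_tested_loci",
            "n_significant_loci",
            "max_abs_delta_beta",
            "direction",
            "has_dm",
            "has_clear_dm",
        ],
    ).set_index("gene")
    return GeneDMSummary(table=df, clear_threshold=clear_threshold)


@dataclass
class ConcordanceReport:
    """Cross-species enrichment / direction-concordance results.

    ``enrichment`` rows per human subtype: counts, set fraction, baseline
    fraction, chi2, raw and Bonferroni-adjusted p. ``direction`` rows per
    subtype: concordant/discordant counts and fraction; ``direction_chi2``
    and ``direction_p`` compare the subtypes.
    """

    enrichment: pd.DataFrame = field(default_factory=pd.DataFrame)
    direction: pd.DataFrame = field(default_factory=pd.DataFrame)
    direction_chi2: float = float("nan")
    direction_p: float = float("nan")
    direction_testable: bool = False


def _ortholog_targets(mouse_genes: set[str], ortholog_map: OrthologMap) -> set[str]:
    pairs = ortholog_map.pairs
    return set(pairs.loc[pairs["mouse_gene"].isin(mouse_genes), "human_gene"])


def enrichment_test(
    mouse_summary: GeneDMSummary,
    human_summaries: dict[str, GeneDMSummary],
    ortholog_map: OrthologMap,
) -> ConcordanceReport:
    """Are human orthologs of mouse-DM genes enriched for human DM?

    For each human subtype: 2x2 Pearson chi-squared (no continuity
    correction) of has_dm among the ortholog set versus all other tested
    human genes, Bonferroni-adjusted across the subtypes tested.
    """
    mouse_dm = mouse_summary.genes_with_dm()
    targets = _ortholog_targets(mouse_dm, ortholog_map)
    n_tests = len(human_summaries)
    rows = []
    for subtype, hsum in human_summaries.items():
        tested = hsum.table
        in_set = tested.index.isin(targets)
        set_dm = int(tested.loc[in_set, "has_dm"].sum())
        set_not = int(in_set.sum() - set_dm)
        base_dm = int(tested.loc[~in_set, "has_dm"].sum())
        base_not = int((~in_set).sum() - base_dm)
        tab = np.array([[set_dm, set_not], [base_dm, base_not]], dtype=float)
        set_total = set_dm + set_not
        base_total = base_dm + base_not
        set_frac = set_dm / set_total if set_total else float("nan")
        base_frac = base_dm / base_total if base_total else float("nan")
        if set_total and base_total and set_frac == base_frac:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = pearson_chi2(tab)
        rows.append(
            {
                "subtype": subtype,
                "set_dm": set_dm,
                "set_total": set_total,
                "set_fraction": set_frac,
                "baseline_dm": base_dm,
                "baseline_total": base_total,
                "baseline_fraction": base_frac,
                "chi2": chi2,
                "p_value": p,
                "p_adjusted": min(1.0, p * n_tests),
            }
        )
    return ConcordanceReport(enrichment=pd.DataFrame(rows))


def direction_concordance(
    mouse_summary: GeneDMSummary,
    human_summaries: dict[str, GeneDMSummary],
    ortholog_map: OrthologMap,
) -> ConcordanceReport:
    """Direction agreement between species, compared across human subtypes.

    Per subtype, over genes DM in both species (through the ortholog
    map), counts mouse/human direction agreement. When exactly two
    subtypes each have >= 2 genes, a 2x2 chi-squared compares their
    concordant/discordant counts.
    """
    pairs = ortholog_map.pairs
    mouse_tab = mouse_summary.table
    rows = []
    for subtype, hsum in human_summaries.items():
        htab = hsum.table
        conc = disc = 0
        for r in pairs.itertuples(index=False):
            if r.mouse_gene not in mouse_tab.index or r.human_gene not in htab.index:
                continue
            mrow = mouse_tab.loc[r.mouse_gene]
            hrow = htab.loc[r.human_gene]
            if not (mrow["has_dm"] and hrow["has_dm"]):
                continue
            if mrow["direction"] == "none" or hrow["direction"] == "none":
                continue
            if mrow["direction"] == hrow["direction"]:
                conc += 1
            else:
                disc += 1
        total = conc + disc
        rows.append(
            {
                "subtype": subtype,
                "concordant": conc,
                "discordant": disc,
                "fraction": conc / total if total else float("nan"),
            }
        )
    direction = pd.DataFrame(rows)
    report = ConcordanceReport(direction=direction)
    if len(direction) == 2 and (direction["concordant"] + direction["discordant"] >= 2).all():
        tab = direction[["concordant", "discordant"]].to_numpy(dtype=float)
        if tab.sum(axis=1).min() > 0:
            fr = direction["fraction"].to_numpy()
            if np.isclose(fr[0], fr[1]):
                report.direction_chi2, report.direction_p = 0.0, 1.0
            else:
                report.direction_chi2, report.direction_p = pearson_chi2(tab)
            report.direction_testable = True
    return report


def major_relevance_genes(
    mouse_summary: GeneDMSummary,
    human_summary: GeneDMSummary,
    ortholog_map: OrthologMap,
) -> pd.DataFrame:
    """Genes clearly DM in BOTH species: at least one significant locus
    with |delta beta| >= the clear threshold (default 30%) in the mouse
    gene and in its human ortholog.

    Returns one row per qualifying (mouse_gene, human_gene) pair, sorted
    by min(mouse, human max |delta beta|) descending.
    """
    mtab = mouse_summary.table
    htab = human_summary.table
    rows = []
    for r in ortholog_map.pairs.itertuples(index=False):
        if r.mouse_gene not in mtab.index or r.human_gene not in htab.index:
            continue
        mrow = mtab.loc[r.mouse_gene]
        hrow = htab.loc[r.human_gene]
        if mrow["has_clear_dm"] and hrow["has_clear_dm"]:
            rows.append(
                {
                    "mouse_gene": r.mouse_gene,
                    "human_gene": r.human_gene,
                    "mouse_max_abs_delta_beta": float(mrow["max_abs_delta_beta"]),
                    "human_max_abs_delta_beta": float(hrow["max_abs_delta_beta"]),
                    "min_max_abs_delta_beta": float(
                        min(mrow["max_abs_delta_beta"], hrow["max_abs_delta_beta"])
                    ),
                    "mouse_direction": mrow["direction"],
                    "human_direction": hrow["direction"],
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mouse_gene",
            "human_gene",
            "mouse_max_abs_delta_beta",
            "human_max_abs_delta_beta",
            "min_max_abs_delta_beta",
            "mouse_direction",
            "human_direction",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["min_max_abs_delta_beta", "mouse_gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


@dataclass
class RiskConcordance:
    """Direction agreement between a risk contrast and the tumour contrast."""

    n_shared: int
    n_concordant: int
    p_value: float
    testable: bool
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)


def risk_concordance(
    risk_dm: DMResult,
    tumour_dm: DMResult,
    gene_loci: pd.Index,
    risk_fdr: float = 0.05,
    clear_threshold: float = 0.30,
) -> RiskConcordance:
    """Does high-vs-low-risk methylation move the same way as tumour-vs-control?

    Restricted to ``gene_loci`` (the target gene's loci): risk loci must be
    significant at FDR < ``risk_fdr``; tumour loci must be significant with
    |delta beta| > ``clear_threshold``. Over the k of n shared loci whose
    delta-beta signs agree, the one-sided exact binomial p-value is the
    tail sum P(X >= k), X ~ Binomial(n, 1/2).
    """
    r = risk_dm.table.loc[risk_dm.table.index.isin(gene_loci)]
    t = tumour_dm.table.loc[tumour_dm.table.index.isin(gene_loci)]
    r_sig = r[(r["fdr"] < risk_fdr) & r["testable"]]
    t_clear = t[t["significant"] & (t["delta_beta"].abs() > clear_threshold)]
    shared = r_sig.index.intersection(t_clear.index)
    n = len(shared)
    if n == 0:
        return RiskConcordance(n_shared=0, n_concordant=0, p_value=float("nan"), testable=False)
    agree = (
        np.sign(r_sig.loc[shared, "delta_beta"].to_numpy())
        == np.sign(t_clear.loc[shared, "delta_beta"].to_numpy())
    )
    k = int(agree.sum())
    p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    loci = pd.DataFrame(
        {
            "risk_delta_beta": r_sig.loc[shared, "delta_beta"],
            "tumour_delta_beta": t_clear.loc[shared, "delta_beta"],
            "concordant": agree,
        }
    )
    return RiskConcordance(n_shared=n, n_concordant=k, p_value=p, testable=True, loci=loci)
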