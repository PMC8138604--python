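"""Synthetic bisulfite-sequencing and array data with known truth.

The generator emulates the statistical structure of an RRBS tumour/control
study and a companion human array comparison:

* per-CpG baseline methylation from a bimodal (low/high) mixture, the
  hallmark of CpG-dense bisulfite data;
* read coverage from a negative binomial, methylated counts from a
  beta-binomial with intra-class correlation rho (biological
  overdispersion between samples);
* planted DMRs in a configurable fraction of genes: dense CpG clusters
  whose tumour methylation is shifted on the logit scale so that the
  expected beta-scale difference equals the configured effect exactly;
* an optional global hypermethylation shift of the tumour group (the
  stem-cell-like subtype signature), again injected per locus on the
  logit scale to a target mean beta increase;
* array beta values as logit-normal noise around group means with
  detection p-values, including a configurable fraction of failing
  probes;
* an ortholog candidate table with controlled ambiguity.

Everything is deterministic under the configured seed, and outputs are
emitted in exactly the formats the readers consume, so synthetic runs
exercise the real I/O paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CpGCountTable, GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "RRBSSimulation",
    "ArraySimulation",
    "CallEvaluation",
    "simulate_rrbs",
    "simulate_array",
    "simulate_ortholog_candidates",
    "evaluate_calls",
]

_CHROMS = [f"chr{i}" for i in range(1, 20)]


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic datasets.

    Defaults are sized for a desk-scale study: 500 genes with ~20-CpG
    clusters (10,000 loci), 6 control + 6 tumour samples at mean coverage
    30x, beta-binomial intra-class correlation 0.02, DMRs planted in 5% of
    genes with a +0.40 beta-scale effect.
    """

    n_genes: int = 500
    cpgs_per_gene: int = 20
    cpg_spacing_bp: int = 9
    gene_length_bp: int = 2000
    gene_gap_bp: int = 8000
    n_control: int = 6
    n_tumour: int = 6
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0  # negative-binomial size parameter
    low_mode_weight: float = 0.6
    low_mode_ab: tuple[float, float] = (2.0, 18.0)
    high_mode_ab: tuple[float, float] = (18.0, 2.0)
    rho: float = 0.02  # within-group beta-binomial intra-class correlation
    dmr_gene_fraction: float = 0.05
    dmr_delta_beta: float = 0.40
    dmr_baseline_range: tuple[float, float] = (0.15, 0.45)
    global_shift_beta: float = 0.0
    shared_fraction: float = 0.8  # planted genes also DM in the human data
    # array side
    array_n_control: int = 8
    array_n_tumour: int = 8
    probes_per_gene: int = 5
    array_noise_sd: float = 0.25
    bad_probe_fraction: float = 0.05
    array_delta_beta: float = 0.40
    concordance_probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("low_mode_weight", "rho", "dmr_gene_fraction", "shared_fraction",
                     "bad_probe_fraction", "concordance_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        cluster_span = (self.cpgs_per_gene - 1) * self.cpg_spacing_bp + 1
        if cluster_span > self.gene_length_bp:
            raise ValueError(
                f"CpG cluster span {cluster_span} bp exceeds gene length {self.gene_length_bp} bp"
            )


@dataclass
class SimulationTruth:
    """Ground truth of a simulated RRBS study.

    ``regions``: one row per planted DMR (gene, chrom, start, end,
    true_delta_beta, direction, shared). ``baseline``: per-locus baseline
    beta (control-group mean), indexed by (chrom, pos). ``locus_delta``:
    per-locus true tumour-control beta difference (0 outside planted
    regions, before any global shift).
    """

    regions: pd.DataFrame
    baseline: pd.Series
    locus_delta: pd.Series

    def planted_genes(self) -> set[str]:
        return set(self.regions["gene"])

    def shared_genes(self) -> set[str]:
        return set(self.regions.loc[self.regions["shared"], "gene"])


@dataclass
class RRBSSimulation:
    tables: list[CpGCountTable]
    annotation: GeneAnnotation
    truth: SimulationTruth
    groups: dict[str, str]


@dataclass
class ArraySimulation:
    dataset: "ArrayDataset"
    groups: dict[str, str]
    truth: pd.DataFrame  # per human gene: shifted, direction, true_delta_beta


def _gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic gene coordinates: genes laid out round-robin across
    chromosomes with fixed spacing."""
    rows = []
    per_chrom_count = {c: 0 for c in _CHROMS}
    for i in range(config.n_genes):
        chrom = _CHROMS[i % len(_CHROMS)]
        k = per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        start = 10_000 + k * (config.gene_length_bp + config.gene_gap_bp)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + config.gene_length_bp - 1,
                "strand": "+" if i % 2 == 0 else "-",
                "symbol": f"Gene{i:04d}",
            }
        )
    return pd.DataFrame(rows)


def simulate_rrbs(config: SimulationConfig) -> RRBSSimulation:
    """Simulate per-sample Bismark-style count tables with known truth.

    Each gene carries one dense CpG cluster (``cpgs_per_gene`` CpGs at
    ``cpg_spacing_bp`` spacing). In planted genes the tumour group's
    cluster methylation is shifted by the per-CpG logit offset that maps
    the baseline beta to baseline + ``dmr_delta_beta``; a global tumour
    shift of ``global_shift_beta`` (mean beta scale) is applied the same
    way at every locus.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_layout(config)

    n_dmr = int(round(config.dmr_gene_fraction * config.n_genes))
    dmr_gene_idx = np.sort(rng.choice(config.n_genes, size=n_dmr, replace=False))
    dmr_set = set(int(i) for i in dmr_gene_idx)
    shared_mask = rng.random(n_dmr) < config.shared_fraction

    chroms: list[str] = []
    positions: list[int] = []
    baseline = []
    delta = []
    region_rows = []
    for gi, grow in enumerate(genes.itertuples(index=False)):
        offset = (config.gene_length_bp - (config.cpgs_per_gene - 1) * config.cpg_spacing_bp) // 2
        pos = grow.start + offset + config.cpg_spacing_bp * np.arange(config.cpgs_per_gene)
        chroms.extend([grow.chrom] * config.cpgs_per_gene)
        positions.extend(int(p) for p in pos)
        if gi in dmr_set:
            b0 = rng.uniform(*config.dmr_baseline_range)
            base = np.clip(b0 + rng.normal(0.0, 0.03, size=config.cpgs_per_gene), 0.05, 0.50)
            d = np.full(config.cpgs_per_gene, config.dmr_delta_beta)
            k = int(np.searchsorted(dmr_gene_idx, gi))
            region_rows.append(
                {
                    "gene": grow.symbol,
                    "chrom": grow.chrom,
                    "start": int(pos[0]),
                    "end": int(pos[-1]),
                    "true_delta_beta": config.dmr_delta_beta,
                    "direction": "hyper",
                    "shared": bool(shared_mask[k]),
                }
            )
        else:
            low = rng.random(config.cpgs_per_gene) < config.low_mode_weight
            base = np.where(
                low,
                rng.beta(*config.low_mode_ab, size=config.cpgs_per_gene),
                rng.beta(*config.high_mode_ab, size=config.cpgs_per_gene),
            )
            base = np.clip(base, 1e-4, 1 - 1e-4)
            d = np.zeros(config.cpgs_per_gene)
        baseline.append(base)
        delta.append(d)

    base = np.concatenate(baseline)
    delta = np.concatenate(delta)
    idx = pd.MultiIndex.from_arrays([chroms, positions], names=["chrom", "pos"])

    tumour_target = np.clip(base + delta + config.global_shift_beta, 1e-4, 1 - 1e-4)
    mu_control = base
    mu_tumour = tumour_target

    sample_ids = [f"C{i + 1}" for i in range(config.n_control)] + [
        f"T{i + 1}" for i in range(config.n_tumour)
    ]
    groups = {
        s: ("control" if s.startswith("C") else "tumour") for s in sample_ids
    }

    nb_p = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    tables = []
    n_loci = len(base)
    for s in sample_ids:
        mu = mu_control if groups[s] == "control" else mu_tumour
        cov = rng.negative_binomial(config.coverage_dispersion, nb_p, size=n_loci)
        if config.rho > 0:
            conc = (1.0 - config.rho) / config.rho
            p_i = rng.beta(np.clip(mu * conc, 1e-8, None), np.clip((1.0 - mu) * conc, 1e-8, None))
        else:
            p_i = mu
        y = rng.binomial(cov, p_i)
        records = pd.DataFrame(
            {"chrom": chroms, "pos": positions, "n_meth": y, "n_total": cov}
        )
        records = records[records["n_total"] > 0].reset_index(drop=True)
        records = records.sort_values(["chrom", "pos"]).reset_index(drop=True)
        tables.append(CpGCountTable(sample_id=s, records=records))

    truth = SimulationTruth(
        regions=pd.DataFrame(
            region_rows,
            columns=["gene", "chrom", "start", "end", "true_delta_beta", "direction", "shared"],
        ),
        baseline=pd.Series(base, index=idx, name="baseline"),
        locus_delta=pd.Series(delta, index=idx, name="true_delta_beta"),
    )
    annotation = GeneAnnotation(genes=genes)
    return RRBSSimulation(tables=tables, annotation=annotation, truth=truth, groups=groups)


def simulate_ortholog_candidates(
    annotation: GeneAnnotation,
    seed: int = 0,
    ambiguous_fraction: float = 0.2,
) -> pd.DataFrame:
    """Fabricate an ortholog candidate table for the simulated genes.

    Every mouse gene gets a correct human candidate (its upper-cased
    symbol, high confidence, highest homology). A configurable fraction
    additionally receives decoy candidates — lower-homology paralogs and,
    for some, an equal-homology tie that the symbol-match rule must break —
    so resolution is genuinely exercised.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sym in annotation.genes["symbol"]:
        human = sym.upper()
        hom = float(rng.uniform(85, 99))
        rows.append(
            {"mouse_gene": sym, "human_gene": human, "confidence": "high", "homology_pct": round(hom, 2)}
        )
        u = rng.random()
        if u < ambiguous_fraction / 2:
            rows.append(
                {
                    "mouse_gene": sym,
                    "human_gene": human + "B",
                    "confidence": "high",
                    "homology_pct": round(hom - float(rng.uniform(1, 10)), 2),
                }
            )
        elif u < ambiguous_fraction:
            # equal-homology tie: symbol match must decide
            rows.append(
                {
                    "mouse_gene": sym,
                    "human_gene": human + "L",
                    "confidence": "high",
                    "homology_pct": round(hom, 2),
                }
            )
    return pd.DataFrame(rows)


def simulate_array(
    config: SimulationConfig,
    shared_truth: SimulationTruth,
    ortholog_map,
) -> ArraySimulation:
    """Simulate a human array dataset linked to the mouse truth.

    Human genes are the ortholog-map targets of the simulated mouse genes;
    each gets ``probes_per_gene`` probes. Genes whose mouse counterpart is
    a shared planted DMR gene receive a tumour-group shift of
    ``array_delta_beta`` whose direction agrees with the mouse direction
    with probability ``concordance_probability``. Observed beta values are
    logit-normal noise around the group mean; a ``bad_probe_fraction`` of
    probes gets a large detection p-value in one sample.
    """
    from .io_formats import ArrayDataset

    rng = np.random.default_rng(config.seed + 1)
    pairs = ortholog_map.pairs
    mouse_for_human = dict(zip(pairs["human_gene"], pairs["mouse_gene"]))
    human_genes = sorted(set(pairs["human_gene"]))
    shared = shared_truth.shared_genes()
    direction_by_gene = dict(zip(shared_truth.regions["gene"], shared_truth.regions["direction"]))

    sample_ids = [f"HC{i + 1}" for i in range(config.array_n_control)] + [
        f"HT{i + 1}" for i in range(config.array_n_tumour)
    ]
    groups = {s: ("control" if s.startswith("HC") else "tumour") for s in sample_ids}
    is_tumour = np.array([groups[s] == "tumour" for s in sample_ids])

    probe_ids = []
    probe_rows = []
    mu_control = []
    mu_tumour = []
    truth_rows = []
    for hg in human_genes:
        mg = mouse_for_human[hg]
        shifted = mg in shared
        if shifted:
            concordant = rng.random() < config.concordance_probability
            mouse_dir = direction_by_gene.get(mg, "hyper")
            sign = 1.0 if mouse_dir == "hyper" else -1.0
            if not concordant:
                sign = -sign
            direction = "hyper" if sign > 0 else "hypo"
            delta = sign * config.array_delta_beta
        else:
            direction = "none"
            delta = 0.0
        truth_rows.append(
            {"human_gene": hg, "shifted": shifted, "direction": direction, "true_delta_beta": delta}
        )
        for j in range(config.probes_per_gene):
            probe_ids.append(f"cg_{hg}_{j}")
            probe_rows.append({"probe": f"cg_{hg}_{j}", "chrom": "chrH1", "pos": 0, "gene": hg})
            if shifted:
                b0 = float(rng.uniform(*config.dmr_baseline_range))
                if delta < 0:
                    b0 = 1.0 - b0  # leave room for a downward shift
                b1 = float(np.clip(b0 + delta, 1e-3, 1 - 1e-3))
            else:
                if rng.random() < config.low_mode_weight:
                    b0 = float(rng.beta(*config.low_mode_ab))
                else:
                    b0 = float(rng.beta(*config.high_mode_ab))
                b0 = float(np.clip(b0, 1e-3, 1 - 1e-3))
                b1 = b0
            mu_control.append(b0)
            mu_tumour.append(b1)

    n_probes = len(probe_ids)
    mu_c = np.array(mu_control)
    mu_t = np.array(mu_tumour)
    beta = np.empty((n_probes, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        mu = mu_t if is_tumour[j] else mu_c
        noisy = _expit(_logit(np.clip(mu, 1e-4, 1 - 1e-4)) + rng.normal(0, config.array_noise_sd, n_probes))
        beta[:, j] = noisy
    detp = rng.uniform(0.0, 1e-4, size=(n_probes, len(sample_ids)))
    bad = rng.random(n_probes) < config.bad_probe_fraction
    bad_sample = rng.integers(0, len(sample_ids), size=n_probes)
    for i in np.where(bad)[0]:
        detp[i, bad_sample[i]] = rng.uniform(0.05, 1.0)

    # assign probes positions along a synthetic human chromosome so the
    # annotation is a valid coordinate table
    pos = 1000 + 100 * np.arange(n_probes)
    annot = pd.DataFrame(probe_rows).set_index("probe")
    annot["pos"] = pos

    ds = ArrayDataset(
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        detection_p=pd.DataFrame(detp, index=probe_ids, columns=sample_ids),
        probe_annotation=annot,
    )
    return ArraySimulation(dataset=ds, groups=groups, truth=pd.DataFrame(truth_rows))


@dataclass
class CallEvaluation:
    """Confusion-matrix metrics of calls against the planted truth."""

    level: str  # "locus" or "region"
    n_true: int
    n_called: int
    n_true_positive: int
    power: float
    observed_fdr: float | None  # None when nothing was called
    delta_beta_bias: float = float("nan")
    delta_beta_rmse: float = float("nan")


def evaluate_calls(calls, truth: SimulationTruth) -> CallEvaluation:
    """Score per-locus (DMResult) or per-region (list of DMRegion) calls.

    Locus level: a tested locus is a true positive when it lies inside a
    planted region and is called significant; delta-beta bias/RMSE are
    computed over true positives against the planted effect. Region
    level: a called-significant region is a true positive when it
    overlaps a planted region; power is the fraction of planted regions
    recovered.
    """
    from .dm_cpg import DMResult

    if isinstance(calls, DMResult):
        table = calls.table[calls.table["testable"]]
        true_delta = truth.locus_delta.reindex(table.index).fillna(0.0)
        is_true = true_delta.to_numpy() != 0.0
        called = table["significant"].to_numpy()
        tp = called & is_true
        n_called = int(called.sum())
        power = float(tp.sum() / is_true.sum()) if is_true.any() else float("nan")
        fdr = float((called & ~is_true).sum() / n_called) if n_called else None
        if tp.any():
            err = table.loc[tp, "delta_beta"].to_numpy() - true_delta.to_numpy()[tp]
            bias = float(np.mean(err))
            rmse = float(np.sqrt(np.mean(err**2)))
        else:
            bias = rmse = float("nan")
        return CallEvaluation(
            level="locus",
            n_true=int(is_true.sum()),
            n_called=n_called,
            n_true_positive=int(tp.sum()),
            power=power,
            observed_fdr=fdr,
            delta_beta_bias=bias,
            delta_beta_rmse=rmse,
        )

    regions = list(calls)
    tr = truth.regions
    called = [r for r in regions if getattr(r, "significant", False)]

    def overlaps_truth(r) -> bool:
        sub = tr[(tr["chrom"] == r.chrom) & (tr["start"] <= r.end) & (tr["end"] >= r.start)]
        return len(sub) > 0

    tp_regions = [r for r in called if overlaps_truth(r)]
    recovered = 0
    for t in tr.itertuples(index=False):
        if any(
            r.chrom == t.chrom and r.start <= t.end and r.end >= t.start for r in called
        ):
            recovered += 1
    power = recovered / len(tr) if len(tr) else float("nan")
    fdr = (len(called) - len(tp_regions)) / len(called) if called else None
    return CallEvaluation(
        level="region",
        n_true=int(len(tr)),
        n_called=len(called),
        n_true_positive=len(tp_regions),
        power=float(power),
        observed_fdr=fdr,
    )
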