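"""Per-CpG differential methylation on a synthetic RRBS study.

Simulates 6 control vs 6 tumour samples (10,000 CpGs at ~30x coverage,
DMRs planted in 5% of genes at +0.40 beta), applies the coverage and
methylated-read filters, and calls differentially methylated CpGs with
the moderated-t pipeline at FDR < 10%.
"""

from crossmeth import (
    SimulationConfig, simulate_rrbs, build_meth_matrix, filter_loci,
    call_dm_cpgs, evaluate_calls,
)

sim = simulate_rrbs(SimulationConfig(seed=1))
matrix = build_meth_matrix(sim.tables, sim.groups)
filtered = filter_loci(matrix, min_coverage=8, min_meth_reads_total=6)
print(f"loci: {matrix.n_loci} simulated, {filtered.n_loci} pass the 8x / 6-read filters")

dm = call_dm_cpgs(filtered, ("control", "tumour"), fdr_threshold=0.10)
print(f"significant CpGs at FDR<10%: {dm.n_significant} "
      f"(prior df d0={dm.hyperparams.d0:.1f}, prior variance s0^2={dm.hyperparams.s0_sq:.2f})")

top = dm.significant_loci().reindex(
    dm.significant_loci()["delta_beta"].abs().sort_values(ascending=False).index
).head(3)
print("strongest calls (delta beta = tumour - control methylation fraction):")
for (chrom, pos), row in top.iterrows():
    print(f"  {chrom}:{pos}  delta_beta={row['delta_beta']:+.3f}  fdr={row['fdr']:.2e}")

ev = evaluate_calls(dm, sim.truth)
print(f"against the planted truth: power={ev.power:.3f}, observed FDR={ev.observed_fdr:.3f}, "
      f"delta-beta bias={ev.delta_beta_bias:+.4f}")
print("(power near 1 and observed FDR below the nominal 0.10 show the caller "
      "finds the planted effects without overcalling)")
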