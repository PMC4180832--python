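"""Simulate a small diploid MEI dataset and run the full detector.

Plants 15 homozygous AluY-like insertions (full-length consensus +
15 bp poly-A tail + 15 bp target-site duplication) into a 500 kb
synthetic genome, draws 20X of 106 bp paired-end reads (insert
500 +/- 100 bp) as idealized tagged alignments, and runs detection,
filtering and genotyping.

The printed report gives detection sensitivity split by signal class
(read-pair, split-read, their union), the false discovery rate, genotype
accuracy, and how far reported breakpoints sit from the planted ones —
on clean simulations expect full sensitivity, zero false calls and
mostly base-exact breakpoints.
"""

from meicall import (
    MEFamily,
    MEIndex,
    SimulationConfig,
    detect,
    evaluate,
    simulate_dataset,
    synthetic_me_library,
)

cfg = SimulationConfig(
    genome_length=500_000,
    n_insertions=15,
    family=MEFamily.ALU,
    read_length=106,
    coverage=20,
    ploidy="HOM",
    seed=42,
)
genome, truths, pairs = simulate_dataset(cfg)
print(f"simulated {len(pairs)} read pairs over {len(genome)/1e3:.0f} kb, "
      f"{len(truths)} planted insertions")

consensus, families = synthetic_me_library()
calls, insert_models = detect(pairs, genome, cfg.chrom, MEIndex(consensus, families))
fld = insert_models["lib0"]
print(f"insert-size model: median {fld.median} bp, sd {fld.sd:.0f} bp "
      f"(simulated as 500 +/- 100)")

report = evaluate(calls, truths)
print(f"calls: {len(calls)}")
print(f"sensitivity  union {report.sensitivity_union:.3f}  "
      f"RP {report.sensitivity_rp:.3f}  SR {report.sensitivity_sr:.3f}")
print(f"FDR {report.fdr:.3f}   genotype accuracy (hom) "
      f"{report.genotype_accuracy_hom:.3f}")
print(f"breakpoints: {report.breakpoint_exact_fraction:.0%} exact, "
      f"{report.breakpoint_within15_fraction:.0%} within 15 bp "
      f"(the 15 bp TSD bounds the ambiguity)")
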