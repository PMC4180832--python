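"""The binomial genotype model on a few evidence configurations.

At a candidate locus, N_ref fragments support the reference allele and
N_alt support the insertion.  The likelihood of each genotype is the
binomial probability of observing N_alt of N_ref+N_alt MEI fragments at
the genotype's expected MEI fraction (0, 0.5 or 1); a flat 1/3 prior
gives the posterior, and the call is the posterior mode.

Note the model's decisiveness: with any mixture of evidence only the
heterozygote has non-zero likelihood, and with one-sided evidence the
posterior odds grow as 2^N against the heterozygote.
"""

from meicall import GenotypeEvidence, call_genotype, genotype_likelihoods

cases = [
    (10, 0),   # only reference fragments
    (0, 10),   # only MEI fragments
    (5, 5),    # balanced
    (12, 3),   # skewed mixture: still REF/MEI, the only non-zero option
    (0, 0),    # no data: flat posterior, tie broken to REF/REF
]

print(f"{'N_ref':>5} {'N_alt':>5} | {'P(REF/REF)':>10} {'P(REF/MEI)':>10} "
      f"{'P(MEI/MEI)':>10} | call")
for n_ref, n_alt in cases:
    ev = GenotypeEvidence(n_ref, n_alt)
    call = call_genotype(genotype_likelihoods(ev), evidence=ev)
    p = call.posteriors
    print(f"{n_ref:>5} {n_alt:>5} | {p[0]:>10.4g} {p[1]:>10.4g} {p[2]:>10.4g} "
          f"| {call.genotype}")

print("\n(0,10): posterior(MEI/MEI) = 1/(1 + 2^-10) = 1024/1025 — ten MEI "
      "fragments leave odds of one in a thousand for the heterozygote.")
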