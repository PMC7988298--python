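"""Compute per-codon SDAw for one synthetic sample and classify codons.

SDAw(c) = supply fraction / demand fraction: the tRNA decoding capacity
for codon c relative to how much the transcriptome asks for it.  SDAw = 1
is perfectly balanced; > 2 is favored, < 0.5 disfavored.
"""

import sdatools as st

cohort = st.generate_cohort(st.SimConfig(seed=1, n_samples_per_condition=2))
rules = st.build_pairing_rules()

trna, expr = cohort.trna[0], cohort.expression[0]
supply = st.supply_weights(trna, rules)
demand = st.demand_weights(expr, cohort.cds)
profile = st.sda_weights(supply, demand, sample_id=trna.sample_id)

classes = {c: st.classify_codon(v) for c, v in profile.sdaw.items()}
n_fav = sum(k is st.CodonClass.FAVORED for k in classes.values())
n_dis = sum(k is st.CodonClass.DISFAVORED for k in classes.values())
print(f"sample {trna.sample_id}: {len(profile.sdaw)} codons with SDAw")
print(f"  favored (SDAw > 2):    {n_fav}")
print(f"  disfavored (SDAw < 0.5): {n_dis}")

extremes = sorted(profile.sdaw.items(), key=lambda kv: kv[1])
print("  most disfavored:", ", ".join(f"{c}={v:.2f}" for c, v in extremes[:3]))
print("  most favored:   ", ", ".join(f"{c}={v:.2f}" for c, v in extremes[-3:]))

# gene-level SDA = geometric mean of SDAw over the gene's codons
gene = cohort.cds.genes[1]
score = st.gene_sda(cohort.cds, gene, profile)
print(f"  gene SDA of {gene}: {score.score:.3f} "
      "(1 = codon usage matches the tRNA repertoire)")
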