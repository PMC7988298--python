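"""Build the codon–anticodon wobble pairing table and inspect decoders.

Every rule is keyed by (codon, anticodon) strings — there is no
positional codon list anywhere, so a misplaced stop codon cannot
scramble the table.
"""

import sdatools as st

rules = st.build_pairing_rules()
print(f"{len(rules)} pairing rules over {len(st.SENSE_CODONS)} sense codons\n")

for codon in ("AGA", "TTT", "ATG"):
    print(f"decoders of {codon} ({st.amino_acid(codon)}):")
    for anticodon, efficiency in st.decoders_of(codon, rules):
        print(f"  anticodon {anticodon}  efficiency {efficiency:.4f}")

# Watson-Crick pairs decode at efficiency 1; wobble pairs are discounted
# by 1 - s (e.g. G34:U3 at 1 - 0.41 = 0.59). ATG keeps only its cognate
# decoder because U34:G3 wobble would cross into another amino acid family.

st.rules_to_tsv(rules, "rules.tsv")
print("\nrule table exported to rules.tsv (codon, anticodon, pair_class, s)")
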