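"""Fold changes and epistasis (synergy) between mutator alleles.

The synergy index compares a double mutant's relative rate to the sum of
the single mutants' relative rates: an index near 1 means the two gene
products act additively (independent error pools); an index well above 1
means they act on overlapping pools of replication errors.
"""

from fluctspec import fold_change, synergy_index
from fluctspec._util import round_sig

# total rates at the heterochromatic reporter (per cell division)
mu_wt, mu_msh2 = 60e-8, 500e-8
print(f"msh2 vs wild type fold change: {round_sig(fold_change(mu_msh2, mu_wt))}")

# a proofreading-deficient polymerase allele and an MMR deletion showing
# strong synergy (illustrative rates with an 11x super-additive double)
mu_a, mu_b = 180e-8, 300e-8
mu_ab = 11 * (mu_a + mu_b)
res = synergy_index(mu_wt, mu_a, mu_b, mu_ab)
print(f"relative rates: a={res.rel_a:.1f}, b={res.rel_b:.1f}, "
      f"double={res.rel_ab:.0f}")
print(f"synergy index : {res.index:.1f}")
# index >> 1: proofreading and mismatch repair correct the same errors, so
# losing both multiplies rather than adds their effects.
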