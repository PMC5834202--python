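"""Semi-quantitative RT-PCR fold estimation.

A reference transcript whose amplification appears 5 cycles earlier than the
target's is 2^5 = 32-fold more abundant by signal; if the reference amplicon
is 200 bp and the target amplicon 3 kb, equal mass signal means a further
15-fold molar excess of the reference.  Combined, the reference is ~480-fold
more abundant, i.e. the target is ~0.21% of the reference.
"""

from ty1kit.assays import combined_abundance

est = combined_abundance(delta_cycles=5, efficiency=2, ref_len=200, target_len=3000)
print(f"cycle-offset fold:        {est.cycle_fold:.0f}")
print(f"amplicon molar correction: {est.molar_correction:.0f}")
print(f"combined fold:             {est.combined_fold:.0f}")
print(f"target as % of reference:  {est.percent_of_reference:.3f}%")
print("conservative per-cycle efficiency of 2 (perfect doubling) means the "
      "combined fold is a lower bound on the true abundance ratio")
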