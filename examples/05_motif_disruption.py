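"""Allele-specific motif disruption at a regulatory variant.

A PWM whose central column strongly prefers the reference base loses
log2-odds score when the alternative allele replaces it: delta < 0 means
the alternative allele weakens predicted TF binding.
"""

import numpy as np

from pfvcat import PWM, Variant, VariantContext, motif_break

# central column prefers A (0.9) and depletes C (0.025)
matrix = np.array([
    [0.25, 0.25, 0.25, 0.25],
    [0.10, 0.40, 0.40, 0.10],
    [0.90, 0.025, 0.05, 0.025],
    [0.10, 0.40, 0.40, 0.10],
    [0.25, 0.25, 0.25, 0.25],
])
pwm = PWM(motif_id="TF_example", matrix=matrix)

variant = Variant("rs_example", "chr12", 56_750_204, "A", "C", 0.12)
ctx = VariantContext(variant=variant,
                     ref_seq="CCGCCACGCCC", alt_seq="CCGCCCCGCCC")

res = motif_break(pwm, ctx, strong_threshold=1.0)
print(f"{res.motif_id} at {res.rsid}:")
print(f"  ref allele {variant.ref}: best log2-odds {res.ref_score:+.2f}")
print(f"  alt allele {variant.alt}: best log2-odds {res.alt_score:+.2f} "
      f"(offset {res.best_offset}, strand {res.best_strand})")
print(f"  delta = {res.delta:+.2f} -> effect: {res.effect}")
print("delta < 0: the alternative allele lowers predicted binding affinity.")
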