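"""Do prioritized variants overlap known causal variants more than background?

Builds a synthetic causal list that covers 50% of the PFV arm but only 10%
of the background arm, then compares the two proportions with a pooled z
test and a label-permutation test.
"""

from pfvcat import overlap_test, permutation_overlap_test
from pfvcat.simulate import simulate_causal_list

pfv_ids = [f"pfv{i}" for i in range(300)]
bg_ids = [f"bg{i}" for i in range(450)]
causal = simulate_causal_list(pfv_ids, bg_ids,
                              overlap_frac_pfv=0.5, overlap_frac_bg=0.1, seed=8)

res = overlap_test(pfv_ids, bg_ids, causal)
p_perm = permutation_overlap_test(res.k_pfv, res.n_pfv, res.k_bg, res.n_bg,
                                  n_perm=20_000, seed=9)
print(f"PFV arm:        {res.k_pfv}/{res.n_pfv} overlap the causal list")
print(f"background arm: {res.k_bg}/{res.n_bg}")
print(f"two-proportion z = {res.z:.2f}, normal p = {res.p:.3g}, "
      f"permutation p = {p_perm:.3g}")
print("A large positive z: PFVs are enriched for known causal variants.")
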