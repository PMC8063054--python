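"""Relative qPCR quantification with the 2^-ddCT method.

Simulates CT tables for an LPS-stimulation experiment where the true
target ΔCT drops by two cycles (a 4-fold induction), computes
per-replicate fold changes, and compares stimulated vs unstimulated
groups with a t-test.
"""

import imglia as ig

# noiseless table first: arithmetic is exact
clean = ig.generate_ct_table(
    3, {"unstimulated": 5.0, "LPS": 3.0}, noise_sd=0.0, seed=0
)
fc = ig.ddct_fold_change(clean, treated="LPS", control="unstimulated")
print(f"noiseless 2-cycle shift: fold change = {fc.mean:.2f} (expected 4.00)")

# realistic replicate noise
noisy = ig.generate_ct_table(
    6, {"unstimulated": 5.0, "LPS": 3.0}, noise_sd=0.3, seed=8
)
fc_lps = ig.ddct_fold_change(noisy, treated="LPS", control="unstimulated")
fc_ctl = ig.ddct_fold_change(noisy, treated="unstimulated", control="unstimulated")
print(f"with 0.3-cycle noise:   fold change = {fc_lps.mean:.2f} +/- {fc_lps.sd:.2f}")

p = ig.group_compare({
    "LPS": fc_lps.folds.tolist(),
    "unstimulated": fc_ctl.folds.tolist(),
})
print(f"t-test LPS vs unstimulated folds: p = {p:.4f}")
print("-> the control folds center on 1 by construction; a small p confirms")
print("   the induction survives replicate-level CT noise.")
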