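"""Descriptive prevalence statistics: Wilson intervals, a homogeneity test
with a compact letter display, and rebuilding a joint distribution from
subset-union ("pain in any of these sites") probabilities.
"""

import numpy as np

import painlca as pl

# --- prevalence with a Wilson score interval -----------------------------
est, lo, hi = pl.prevalence_with_ci(437, 1565, level=0.95)
print(f"neck pain: {100 * est:.1f}%  (95% CI {100 * lo:.1f}-{100 * hi:.1f}%)")

# --- homogeneity across four strata with a letter display ----------------
counts = pl.GroupCounts(
    group_names=("girls <=13", "girls >=14", "boys <=13", "boys >=14"),
    successes=np.array([136, 99, 112, 90]),
    totals=np.array([470, 364, 361, 381]),
)
stat, p = pl.homogeneity_test(counts)
letters = pl.pairwise_letter_display(counts, alpha=0.05).formatted()
print(f"\nhomogeneity: chi2 = {stat:.2f}, p = {p:.3f}")
for name, s, t, letter in zip(counts.group_names, counts.successes,
                              counts.totals, letters):
    print(f"  {name:12s} {s:>3}/{t}  ({100 * s / t:.1f}%)^{letter}")

# --- joint distribution from subset unions -------------------------------
# published tables often report P(pain in any site of S) for subsets S;
# inclusion-exclusion (Mobius inversion) recovers the full joint table
rng = np.random.default_rng(0)
joint = rng.dirichlet(np.ones(8))  # three items -> 8 response patterns
unions = pl.unions_from_joint(joint)
rebuilt = pl.joint_from_subset_unions(unions)
print(f"\nMobius round trip, max abs error: "
      f"{np.abs(rebuilt - joint).max():.2e}")
print(f"P(any of 3 sites) = {unions[frozenset({0, 1, 2})]:.3f}")
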