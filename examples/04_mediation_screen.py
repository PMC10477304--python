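"""Bootstrap mediation with the two-path rule.

A planted chain X -> M -> Y (a=0.6, b=0.7) is detected; breaking the second
path (b=0) leaves a significant M ~ X but a negative mediation verdict,
because the rule requires both paths.
"""

import microdyn as md
from microdyn.mediation import fit_mediation

cohort = md.generate_cohort(n_per_arm=100, seed=8)

X, M, Y, cov = md.generate_mediation_data(
    cohort, a=0.6, b=0.7, c_prime=0.0, sigma=0.5, seed=9
)
res = fit_mediation(X, M, Y, cov, n_boot=500, seed=42)
print(f"planted chain: a={res.a:.3f} (p={res.p_a:.3f}), "
      f"b={res.b:.3f} (p={res.p_b:.3f}), indirect a*b={res.indirect:.3f}, "
      f"significant={res.significant}")
print("  -> the indirect effect ~0.42 is the planted a*b = 0.6*0.7")

X, M, Y, cov = md.generate_mediation_data(
    cohort, a=0.6, b=0.0, c_prime=0.3, sigma=0.5, seed=10
)
res = fit_mediation(X, M, Y, cov, n_boot=500, seed=42)
print(f"broken chain:  a={res.a:.3f} (p={res.p_a:.3f}), "
      f"b={res.b:.3f} (p={res.p_b:.3f}), significant={res.significant}")
print("  -> one significant path is not enough for a mediation verdict")
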