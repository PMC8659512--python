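"""End-to-end correlation analysis on a small synthetic cohort.

Generates paired samples across the breathiness range, extracts the full
feature set (PD, CPPS, DOQ, HOQ, ABI, CDH, CDH+ABI), simulates two
raters, and prints Pearson/Spearman correlations of each feature with
the averaged perceptual rating.  Expect CPPS negative and the open
quotients and composite indices positive, with the composite indices
among the strongest.  (~1 minute; raise n_samples for tighter values.)
"""

from breathvoice import analyze, gen_cohort

features, ratings = gen_cohort(n_samples=80, seed=11)
result = analyze(features, ratings)

print(result["correlations"][["feature", "r", "rho", "n"]].round(3).to_string(index=False))
print()
print("refit CDH-style index on this cohort:")
for name, coef in result["model"].coefficients.items():
    print(f"  {name}: {coef:+.4f}")
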