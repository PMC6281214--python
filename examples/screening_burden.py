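"""Expected harm of a one-Z-test screening programme at population scale.

One million screened pregnancies at 1% trisomy prevalence with the
legacy single-Z caller (sensitivity 97.9%, specificity 99.7%): every
false positive is referred to amniocentesis, which itself loses about
1 in 250 pregnancies.
"""

from niptcall import screening_burden

b = screening_burden(n_screened=1_000_000, prevalence=0.01,
                     sensitivity=0.979, specificity=0.997,
                     procedure_loss_rate=1 / 250)

print(f"screened:                  {b.n_screened:,.0f}")
print(f"expected false negatives:  {b.expected_fn}")
print(f"expected false positives:  {b.expected_fp}")
print(f"expected procedure losses: {b.expected_procedure_losses}")
print()
print("Each false negative is an undetected trisomy; each false positive")
print("an unnecessary invasive procedure, a fraction of which miscarry --")
print("the motivation for squeezing more accuracy out of the same reads.")
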