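"""Random-effects Bayesian model selection at the group level.

Two populations of 32 subjects are simulated under a 'full' (four-factor)
or 'reduced' (two-factor) GLM at SNR = 0 dB; per-subject free energies feed
the Dirichlet random-effects scheme, which returns expected model
frequencies, exceedance probabilities and per-subject attributions.
"""

from vbss.demos import run_demo

res = run_demo("bmc4glm", seed=1)

for grp in ("full", "reduced"):
    exc = res[f"exceedance_{grp}"]
    freq = res[f"expected_freq_{grp}"]
    print(f"group simulated under the {grp} model:")
    print(f"  expected frequencies (full, reduced): "
          f"{freq[0]:.3f}, {freq[1]:.3f}")
    print(f"  exceedance probabilities:             "
          f"{exc[0]:.3f}, {exc[1]:.3f}")
    print(f"  subjects attributed correctly:        "
          f"{100 * res[f'attribution_accuracy_{grp}']:.0f}%")
print()
print("Exceedance ~1 for the generating model in each group: the scheme")
print("identifies which model prevails in each population, subject by")
print("subject, despite overlapping log-Bayes-factor histograms.")
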