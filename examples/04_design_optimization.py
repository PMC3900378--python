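"""Experimental design optimization, offline and online.

Offline: the Laplace-Chernoff risk approximates the model-selection error
rate of a design, and A-optimality scores designs for parameter estimation.
Online: before each fMRI block, the design (attention on or off) with the
lower risk for discriminating 'attention modulates V1->V5' from 'no
modulation' is played, both models are re-inverted, and the cycle repeats.
"""

import numpy as np

from vbss.demos import run_demo

res = run_demo("dcm_online", seed=1, n_blocks=10)

print("chosen block types (A = attention, - = photic only):")
print("  " + "".join("A" if a else "-" for a in res["attention_chosen"]))
print("design efficiency (-risk) per block:")
print("  " + " ".join(f"{e:.3f}" for e in res["efficiency_trace"]))
print("log Bayes factor (true vs reduced model) after each block:")
print("  " + " ".join(f"{b:.0f}" for b in res["log_bf_trace"]))
print(f"correlation between the two input regressors: "
      f"{res['input_correlation']:.3f} (~0.6)")
print(f"recovered modulation strength: {res['modulation_estimate']:.3f} "
      "(simulated with 0.4)")
print()
print("The procedure settles into attention on alternate blocks -- the")
print("maximally orthogonal design under 'photic always on' -- while the")
print("efficiency trace rises and the evidence for the true model grows.")
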