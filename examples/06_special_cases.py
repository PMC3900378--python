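"""Special cases mapped into the canonical state-space form.

Delay embedding (a delayed recursion becomes Markovian on an augmented
state), AR(1) state-noise augmentation, and microtime refinement of a
continuous-time system.
"""

import numpy as np

import vbss
from vbss.transforms import augment_ar1, embed_delays, with_microtime

# --- delays: the two-term recursion x_{t+1} = x_t + x_{t-1}
spec = vbss.ModelSpec(
    f=lambda X, th, u, ex: np.atleast_1d(X[0] + X[1]),
    g=lambda x, ph, u, ex: x.copy(),
    n=1, n_theta=0, n_phi=0,
    delay_matrix=np.array([1]), f_takes_history=True,
)
emb = embed_delays(spec)
_, traj = vbss.simulate(emb, [], [], np.array([1.0, 1.0]), None, T=5)
print("delay embedding, x' = x + x(delayed), history (1, 1):",
      traj.x[0].astype(int), "(the Fibonacci numbers)")

# --- AR(1) state noise: the carrier z drives the original state
base = vbss.ModelSpec(
    f=lambda x, th, u, ex: 0.5 * x, g=lambda x, ph, u, ex: x.copy(),
    n=1, n_theta=0, n_phi=0,
)
aug, Q = augment_ar1(base, decay=0.8)
_, traj = vbss.simulate(aug, [], [], np.zeros(2), None, T=4096,
                        state_precision=1.0, seed=0, cov_structure=Q)
z = traj.x[1] - traj.x[1].mean()
print(f"AR(1) augmentation: lag-1 autocorrelation of the noise carrier = "
      f"{(z[1:] @ z[:-1]) / (z @ z):.3f} (decay 0.8)")

# --- microtime: Euler refinement of dx/dt = -x over one sample
spec = vbss.ModelSpec(
    f=lambda x, th, u, ex: x - ex.get("step", 1.0) * x,
    g=lambda x, ph, u, ex: x.copy(),
    n=1, n_theta=0, n_phi=0, dt=1.0, extras={"dt": 1.0},
)
print("microtime refinement of dx/dt = -x, error vs exp(-1):")
for n_micro in (1, 4, 16, 64):
    s = with_microtime(spec, n_micro)
    _, t = vbss.simulate(s, [], [], np.ones(1), None, T=1)
    print(f"  {n_micro:3d} sub-steps: |error| = "
          f"{abs(t.x[0, 0] - np.exp(-1)):.2e}")
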