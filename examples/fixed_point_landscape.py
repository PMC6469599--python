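"""Enumerate and classify every equilibrium of a small BCM system.

For N = K = 4 von Mises stimuli, each of the 2^4 subsets S of stimuli
defines one equilibrium: the neuron responds with y = K/|S| to the stimuli
in S and is silent for the rest (weights w = X^{-1} y).  Classifying each
equilibrium by the eigenvalues of the numerical Jacobian of the learning
drift shows that exactly the 4 selective equilibria (|S| = 1) are stable —
the neuron always ends up selective to a single stimulus.
"""

import numpy as np

import bcmring as b

ens = b.build_ensemble("von_mises", 4, 4, 0.5)
fps = b.enumerate_fixed_points(ens)

print(f"{'active set':>12} {'theta*':>7} {'stability':>10}   weights")
for fp in fps:
    label = "{" + ",".join(map(str, sorted(fp.active_set))) + "}"
    print(f"{label:>12} {fp.theta_star:>7.2f} {fp.stability:>10}   "
          + np.array2string(fp.weights, precision=2, suppress_small=True))

stable = [fp for fp in fps if fp.stability == "stable"]
print(f"\n{len(stable)} of {len(fps)} equilibria are stable; "
      f"all have a single active stimulus: "
      f"{sorted(tuple(fp.active_set) for fp in stable)}")
print("theta* = K/|S| at each equilibrium (= N = 4 for the selective ones).")
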