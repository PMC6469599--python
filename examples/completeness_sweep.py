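"""Does the slowdown survive when the stimulus count differs from N?

Runs the convergence sweep at N = 8 and 12 with K = N/2 (under-complete),
K = N (complete), and K = 2N (over-complete) equi-spaced von Mises stimuli.
For K != N there is no closed-form fixed point, so runs start from a seeded
random weight vector and convergence is the first step from which the angle
to the final state stays below 0.05 rad.  The slowdown with N is present
whenever the stimuli span the full input space (K >= N) and absent when
they do not (K = N/2).
"""

import bcmring as b

print(f"{'k_ratio':>8} {'N':>3} {'K':>3} {'init':>7} {'conv steps':>14} {'winner':>6}")
growth = {}
for ratio in ("half", "equal", "double"):
    cfg = b.ExperimentConfig(
        n_values=(8, 12), k_ratio=ratio, steps_per_tau=3.5,
        max_steps=300_000_000, seed=0,
    )
    table = b.run_completeness_experiment(cfg).table
    for _, row in table.iterrows():
        print(f"{ratio:>8} {row['N']:>3} {row['K']:>3} {row['init']:>7} "
              f"{row['conv_steps']:>14,.0f} {row['winner']:>6}")
    growth[ratio] = table["conv_steps"].iloc[1] / table["conv_steps"].iloc[0]

print()
for ratio, g in growth.items():
    print(f"growth factor N=8 -> 12, k_ratio={ratio:>6}: {g:8.1f}x")
print()
print("Convergence cost explodes with N for K = N and K = 2N but changes by")
print("only a small factor for K = N/2: the slowdown requires the stimuli to")
print("span (or over-span) the N-dimensional input space.")
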