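"""JIT-compiled inner loop for long presentation-by-presentation runs.

The slowdown under study is exponential in the synapse count, so faithful
runs at N = 12 already need ~1e8 stimulus presentations; the per-presentation
update is far too cheap to survive Python-loop overhead.  The kernel keeps
the response vector ``r = X^T w`` incrementally up to date (``r += c G[:, k]``
with ``G = X^T X``), refreshing it from ``w`` at every epoch boundary to kill
floating-point drift, so one presentation costs O(N + K) instead of O(N K).

All randomness stays outside: the caller passes an explicit presentation
schedule generated from a seeded numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by the kernel
OK = 0
DIVERGED = 1

# averaged mode recomputes theta from all K responses each presentation;
# online mode integrates d(theta)/dt = (-theta + y^2)/tau_theta instead.
MODE_AVERAGED = 0
MODE_ONLINE = 1


@njit(cache=False)
def run_schedule(
    x,
    gram,
    w,
    r,
    tau_w,
    schedule,
    mode,
    theta,
    tau_theta,
    record_every,
    step_offset,
    rec_times,
    rec_weights,
    rec_theta,
    rec_index,
    diverge_norm2,
):
    """Advance the state through one schedule chunk (epoch-aligned).

    Mutates ``w``, ``r`` and the record arrays in place.  Returns
    ``(rec_index, status, failed_step, theta)``.
    """
    n, k_stimuli = x.shape
    n_steps = schedule.shape[0]
    ri = rec_index
    for s in range(n_steps):
        if s % k_stimuli == 0:
            # refresh responses from scratch at epoch boundaries
            for j in range(k_stimuli):
                acc = 0.0
                for i in range(n):
                    acc += x[i, j] * w[i]
                r[j] = acc
            nrm2 = 0.0
            for i in range(n):
                nrm2 += w[i] * w[i]
            if not (nrm2 <= diverge_norm2):  # also catches NaN/inf overflow
                return ri, DIVERGED, step_offset + s, theta
        k = schedule[s]
        y = r[k]
        if mode == MODE_AVERAGED:
            th = 0.0
            for j in range(k_stimuli):
                th += r[j] * r[j]
            th /= k_stimuli
        else:
            theta += (-theta + y * y) / tau_theta
            th = theta
        c = y * (y - th) / tau_w
        for i in range(n):
            w[i] += c * x[i, k]
        for j in range(k_stimuli):
            r[j] += c * gram[j, k]
        step = step_offset + s + 1
        if step % record_every == 0:
            rec_times[ri] = step
            for i in range(n):
                rec_weights[ri, i] = w[i]
            if mode == MODE_AVERAGED:
                th_rec = 0.0
                for j in range(k_stimuli):
                    th_rec += r[j] * r[j]
                rec_theta[ri] = th_rec / k_stimuli
            else:
                rec_theta[ri] = theta
            ri += 1
    return ri, OK, -1, theta


def schedule_chunks(rng: np.random.Generator, k: int, n_steps: int, chunk_steps: int = 4_000_000):
    """Yield epoch-aligned permuted presentation schedules totalling ``n_steps``.

    Every epoch of ``k`` presentations contains each stimulus exactly once;
    only the final epoch may be truncated.  Chunks are epoch-aligned so the
    kernel's epoch-boundary refresh stays correct across chunk joins.
    """
    chunk_epochs = max(1, chunk_steps // k)
    done = 0
    while done < n_steps:
        n_ep = min(chunk_epochs, (n_steps - done + k - 1) // k)
        sched = rng.permuted(np.tile(np.arange(k), (n_ep, 1)), axis=1).ravel()
        take = min(sched.size, n_steps - done)
        yield np.ascontiguousarray(sched[:take], dtype=np.int64)
        done += take
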