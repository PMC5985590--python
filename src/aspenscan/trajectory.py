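"""Wright-Fisher frequency trajectories conditioned on fixation.

The beneficial (derived) allele has genotype fitnesses 1, 1 + s/2 and
1 + s for the ancestral homozygote, heterozygote and derived homozygote —
additive selection on the allele. Paths start from a single copy and are
accepted only if they reach fixation; the accepted path is returned
reversed (fixation -> origin) for use by the backward-in-time sweep
coalescent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import Trajectory


class TrajectoryError(RuntimeError):
    pass


@njit(cache=True)
def _wf_forward(N: int, s: float, max_tries: int, seed: int):
    """Simulate conditioned-on-fixation WF paths; returns (path, tries).

    path is the forward frequency sequence from 1/(2N) to 1.0 inclusive;
    an empty array signals that the rejection budget was exhausted.
    """
    np.random.seed(seed)
    two_n = 2 * N
    buf = np.empty(200 * N + 1000, dtype=np.float64)
    for attempt in range(max_tries):
        x = 1.0 / two_n
        buf[0] = x
        t = 1
        while 0.0 < x < 1.0:
            # deterministic selection step, then binomial drift
            wbar = x * x * (1.0 + s) + 2.0 * x * (1.0 - x) * (1.0 + 0.5 * s) \
                + (1.0 - x) * (1.0 - x)
            xsel = (x * x * (1.0 + s) + x * (1.0 - x) * (1.0 + 0.5 * s)) / wbar
            k = np.random.binomial(two_n, xsel)
            x = k / two_n
            if t >= buf.size:
                # extremely long excursion: treat as failed attempt
                x = 0.0
                break
            buf[t] = x
            t += 1
        if x >= 1.0:
            return buf[:t].copy(), attempt + 1
    return np.empty(0, dtype=np.float64), max_tries


def simulate_wf_trajectory(
    N_sim: int,
    s: float,
    seed: int,
    max_tries: int = 200_000,
) -> Trajectory:
    """Simulate one fixation-conditioned Wright-Fisher trajectory.

    Parameters
    ----------
    N_sim : int
        Diploid population size of the (possibly rescaled) simulation.
    s : float
        Selection coefficient of the derived homozygote. Values > 1 are
        permitted here to support population-size rescaling that
        preserves 4*N*s.
    seed : int
        RNG seed; identical seeds give identical paths.
    max_tries : int
        Rejection budget: number of forward paths attempted before
        giving up.

    Returns
    -------
    Trajectory
        Backward path: freqs[0] = 1.0, last nonzero = 1/(2*N_sim),
        final entry 0.
    """
    if N_sim < 2:
        raise ValueError("N_sim must be >= 2")
    if s <= 0:
        raise ValueError("s must be > 0 (use a neutral simulator for s = 0)")
    path, tries = _wf_forward(int(N_sim), float(s), int(max_tries),
                              int(seed) % 2**32)
    if path.size == 0:
        raise TrajectoryError(
            f"no fixation in {max_tries} attempted paths "
            f"(N_sim={N_sim}, s={s}); increase max_tries"
        )
    back = path[::-1].copy()
    back[0] = 1.0
    freqs = np.append(back, 0.0)
    return Trajectory(freqs=freqs, N_sim=int(N_sim))
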