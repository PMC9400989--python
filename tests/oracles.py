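"""Independent oracles used by the test suite.

These deliberately avoid the package's closed forms: stochastic
simulations of the underlying spin physics (Brownian phase accumulation,
two-state jump processes) against which the analytic attenuation factors
and propagators are checked.
"""

from __future__ import annotations

import numpy as np


def gillespie_two_state(k_ab: float, k_ba: float, tau: float, n_particles: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Empirical transition matrix of a two-state jump process.

    Simulates ``n_particles`` per start state with exact exponential waiting
    times (rates ``k_ab``: a->b, ``k_ba``: b->a) and returns the 2x2 matrix
    of end-state fractions, column j = start state j.
    """
    P = np.zeros((2, 2))
    rates = (k_ab, k_ba)
    for start in range(2):
        state = np.full(n_particles, start)
        t = np.zeros(n_particles)
        active = np.ones(n_particles, dtype=bool)
        while active.any():
            idx = np.flatnonzero(active)
            r = np.array([rates[s] for s in state[idx]])
            with np.errstate(divide="ignore"):
                dt = rng.exponential(1.0 / np.where(r > 0, r, np.inf))
            t[idx] += dt
            jumped = t[idx] <= tau
            state[idx[jumped]] = 1 - state[idx[jumped]]
            active[idx[~jumped]] = False
        P[0, start] = np.mean(state == 0)
        P[1, start] = np.mean(state == 1)
    return P


def brownian_stimulated_echo(D: float, deltas: np.ndarray, Delta: float,
                             G: float, gammabar: float, n_walkers: int,
                             rng: np.random.Generator, dt: float = 2e-6
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Stimulated-echo attenuation by Brownian phase accumulation.

    Each walker diffuses in 1D; its phase is gamma G times the difference
    of the position integrals over the two encoding windows [0, delta] and
    [Delta, Delta + delta].  Returns (mean cos(phase), standard error) per
    requested ``delta``.  One trajectory set serves all deltas via the
    cumulative position integral.
    """
    deltas = np.asarray(deltas, dtype=float)
    checkpoints = np.unique(np.concatenate([deltas, [Delta], Delta + deltas]))
    steps_at = np.rint(checkpoints / dt).astype(int)
    if not np.allclose(steps_at * dt, checkpoints, rtol=0, atol=dt * 1e-6):
        raise ValueError("deltas and Delta must be integer multiples of dt")
    n_steps = int(steps_at.max())
    gamma = 2.0 * np.pi * gammabar

    # stream the walk: keep only z and the running integral of z dt,
    # snapshotting the integral at each checkpoint (O(n_walkers) memory)
    z = np.zeros(n_walkers)
    running = np.zeros(n_walkers)
    snaps = {0: running.copy()}
    want = set(steps_at.tolist())
    sigma_step = np.sqrt(2.0 * D * dt)
    for m in range(1, n_steps + 1):
        z_new = z + rng.normal(0.0, sigma_step, n_walkers)
        running = running + 0.5 * (z + z_new) * dt
        z = z_new
        if m in want:
            snaps[m] = running.copy()

    def integral_at(t: float) -> np.ndarray:
        return snaps[int(round(t / dt))]

    att = np.empty_like(deltas)
    err = np.empty_like(deltas)
    for i, d in enumerate(deltas):
        phase = gamma * G * (
            integral_at(d) - (integral_at(Delta + d) - integral_at(Delta)))
        c = np.cos(phase)
        att[i] = c.mean()
        err[i] = c.std(ddof=1) / np.sqrt(n_walkers)
    return att, err


def brownian_cpmg(D: float, echo_time: float, n_echoes: int, G: float,
                  gammabar: float, n_walkers: int, rng: np.random.Generator,
                  steps_per_half: int = 24) -> tuple[np.ndarray, np.ndarray]:
    """CPMG echo amplitudes under a constant gradient by random walk.

    The refocusing pulses at (n - 1/2) * tE flip the sign of the
    accumulated phase; echoes form at n * tE.  Returns (mean cos(phase),
    standard error) at each echo top.
    """
    dt = echo_time / (2 * steps_per_half)
    gamma = 2.0 * np.pi * gammabar
    phase = np.zeros(n_walkers)
    z = np.zeros(n_walkers)
    amps = np.empty(n_echoes)
    errs = np.empty(n_echoes)
    sigma_step = np.sqrt(2.0 * D * dt)
    for n in range(n_echoes):
        for half in range(2):
            for _ in range(steps_per_half):
                z_new = z + rng.normal(0.0, sigma_step, n_walkers)
                phase += gamma * G * 0.5 * (z + z_new) * dt
                z = z_new
            if half == 0:
                phase = -phase  # pi pulse
        c = np.cos(phase)
        amps[n] = c.mean()
        errs[n] = c.std(ddof=1) / np.sqrt(n_walkers)
    return amps, errs
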