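"""Batched differential evolution for many independent small problems.

Grid-cell calibrations are thousands of independent 2-6 parameter bound-
constrained minimizations sharing one vectorizable objective.  This module
runs a classic DE/rand/1/bin population per problem, with all populations
evaluated in a single vectorized objective call per generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DEResult:
    x: np.ndarray          # (n_problems, ndim) best parameters
    fun: np.ndarray        # (n_problems,) best objective values
    n_gen: int
    converged: np.ndarray  # (n_problems,) population-spread convergence flag
    degenerate: np.ndarray  # objective flat but parameters unresolved


def de_minimize(
    objective,
    bounds,
    n_problems: int = 1,
    seed: int = 0,
    popsize: int = 20,
    maxiter: int = 150,
    mutation: float = 0.7,
    recombination: float = 0.9,
    tol: float = 1e-10,
    x0=None,
) -> DEResult:
    """Minimize ``objective`` independently for each of ``n_problems``.

    Parameters
    ----------
    objective : callable
        Maps a parameter array of shape (n_problems, n_pop, ndim) to
        objective values of shape (n_problems, n_pop).
    bounds : sequence of (lo, hi)
        Box constraints shared by all problems.
    x0 : array-like, optional
        (n_problems, ndim) initial guesses seeded into each population.

    Notes
    -----
    Deterministic under ``seed``.  A problem is flagged ``degenerate``
    when its objective spread has collapsed while the population still
    disagrees on the parameters (flat objective valley).
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    ndim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    pop = lo + rng.random((n_problems, popsize, ndim)) * span
    if x0 is not None:
        pop[:, 0, :] = np.clip(np.asarray(x0, dtype=float).reshape(n_problems, ndim), lo, hi)
    fit = objective(pop)
    if fit.shape != (n_problems, popsize):
        raise ValueError("objective returned a wrong shape")

    n_gen = 0
    for n_gen in range(1, maxiter + 1):
        # DE/rand/1: three mutually distinct partners per member
        idx = np.arange(popsize)
        r = np.empty((3, n_problems, popsize), dtype=int)
        for i in range(3):
            r[i] = rng.integers(0, popsize - 1, size=(n_problems, popsize))
            r[i][r[i] >= idx] += 1  # exclude self; collisions among r are tolerable
        p_idx = np.arange(n_problems)[:, None]
        a, b, c = pop[p_idx, r[0]], pop[p_idx, r[1]], pop[p_idx, r[2]]
        mutant = a + mutation * (b - c)
        # binomial crossover with a guaranteed mutant coordinate
        cross = rng.random((n_problems, popsize, ndim)) < recombination
        force = rng.integers(0, ndim, size=(n_problems, popsize))
        cross[p_idx, idx[None, :], force] = True
        trial = np.where(cross, mutant, pop)
        # reflect out-of-bounds coordinates back into the box
        trial = np.where(trial < lo, 2 * lo - trial, trial)
        trial = np.where(trial > hi, 2 * hi - trial, trial)
        trial = np.clip(trial, lo, hi)

        f_trial = objective(trial)
        better = f_trial <= fit
        pop = np.where(better[:, :, None], trial, pop)
        fit = np.where(better, f_trial, fit)

        f_spread = fit.max(axis=1) - fit.min(axis=1)
        f_scale = np.abs(fit.min(axis=1)) + 1e-30
        if np.all(f_spread <= tol * (1.0 + f_scale)):
            break

    best = np.argmin(fit, axis=1)
    p_idx = np.arange(n_problems)
    x_best = pop[p_idx, best]
    f_best = fit[p_idx, best]
    x_spread = (pop.max(axis=1) - pop.min(axis=1)) / span  # (n_problems, ndim)
    f_spread = fit.max(axis=1) - fit.min(axis=1)
    converged = f_spread <= 1e3 * tol * (1.0 + np.abs(f_best))
    degenerate = converged & (x_spread.max(axis=1) > 0.05)
    return DEResult(x=x_best, fun=f_best, n_gen=n_gen,
                    converged=converged, degenerate=degenerate)
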