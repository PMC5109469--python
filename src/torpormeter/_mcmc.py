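"""Thin wrapper around the emcee ensemble sampler with arviz diagnostics.

All models in this package have low-dimensional continuous posteriors once the
baseline vector is marginalised analytically, which is exactly the regime the
affine-invariant ensemble sampler handles well.  Walkers are treated as chains
for the rank-normalised R-hat / ESS diagnostics.
"""

from __future__ import annotations

import warnings

import emcee
import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az


def sample_ensemble(
    log_prob,
    x0_center,
    n_walkers,
    n_warmup,
    n_samples,
    rng,
    x0_scale=0.1,
):
    """Run the ensemble sampler and return flattened draws plus diagnostics.

    Parameters
    ----------
    log_prob : callable mapping a parameter vector to a log posterior density
        (may return -inf outside the support).
    x0_center : starting point; walkers are initialised with Gaussian jitter
        of scale ``x0_scale`` around it.
    rng : numpy Generator driving both the walker initialisation and the
        sampler's internal randomness (fully deterministic given the rng).

    Returns
    -------
    dict with ``draws`` (n_walkers * n_samples, ndim), ``chain``
    (n_walkers, n_samples, ndim), ``rhat`` and ``ess`` (per dimension),
    ``accept_fraction``.
    """
    x0_center = np.atleast_1d(np.asarray(x0_center, dtype=float))
    ndim = x0_center.size
    if n_walkers < 2 * ndim:
        raise ValueError(f"need at least {2 * ndim} walkers for {ndim} dimensions")
    p0 = x0_center + x0_scale * rng.standard_normal((n_walkers, ndim))
    # make sure every walker starts inside the support
    for i in range(n_walkers):
        tries = 0
        while not np.isfinite(log_prob(p0[i])):
            p0[i] = x0_center + x0_scale * rng.standard_normal(ndim)
            tries += 1
            if tries > 100:
                raise RuntimeError("could not initialise walkers inside the support")
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    # emcee's internal randomness runs off a legacy RandomState; seed it from rng
    seed = int(rng.integers(2**31))
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_samples, progress=False)
    chain = np.swapaxes(sampler.get_chain(), 0, 1)  # (walkers, steps, ndim)
    rhat = np.empty(ndim)
    ess = np.empty(ndim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in range(ndim):
            rhat[d] = float(az.rhat(chain[:, :, d]))
            ess[d] = float(az.ess(chain[:, :, d]))
    return {
        "draws": chain.reshape(-1, ndim),
        "chain": chain,
        "rhat": rhat,
        "ess": ess,
        "accept_fraction": float(np.mean(sampler.acceptance_fraction)),
    }


def grid_init(log_prob_1d, grid):
    """Return the grid point maximising a one-dimensional log density."""
    vals = np.array([log_prob_1d(g) for g in grid])
    return grid[int(np.nanargmax(vals))]
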