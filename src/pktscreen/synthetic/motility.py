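"""Persistent-random-walk (PRW) motility simulator.

The generative model is a constant-speed directional PRW: the cell moves
with fixed speed while its heading angle diffuses on the circle with
correlation time ``persistence_time`` (plus optional white ``turn_noise``).
The ensemble mean-squared displacement follows the Fuerth form

    MSD(t) = 2 s^2 P [ t - P (1 - exp(-t/P)) ]

with s the speed and P the persistence time, interpolating between the
ballistic (t << P) and diffusive (t >> P) regimes.  Straight ("long") and
curly ("small/round") track phenotypes are reproduced by varying P.
"""

from __future__ import annotations

import math

import numpy as np

from ..datatypes import MotilityParams

__all__ = ["simulate_prw_path", "furth_msd"]


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def furth_msd(lags: np.ndarray, speed: float, persistence_time: float) -> np.ndarray:
    """Closed-form ensemble MSD of the PRW at time lags ``lags`` (min)."""
    lags = np.asarray(lags, dtype=float)
    s2, p = speed ** 2, persistence_time
    if p == 0:
        return np.zeros_like(lags)
    if math.isinf(p):
        return s2 * lags ** 2
    return 2.0 * s2 * p * (lags - p * (1.0 - np.exp(-lags / p)))


def simulate_prw_path(
    params: MotilityParams,
    n_steps: int,
    dt: float,
    rng_seed=None,
    *,
    start: tuple[float, float] = (0.0, 0.0),
    n_substeps: int | None = None,
) -> np.ndarray:
    """Simulate one PRW path and return ``n_steps + 1`` positions (um).

    Parameters
    ----------
    params
        Motility parameters; only ``speed``, ``persistence_time`` and
        ``turn_noise`` enter the path model.
    n_steps, dt
        Number of recorded steps (>= 1) and the recording interval (min).
    rng_seed
        Seed or ``numpy.random.Generator``.
    start
        Initial position (um).
    n_substeps
        Internal Euler substeps per recorded interval.  ``None`` picks
        enough substeps (up to 64) that the sampled ensemble MSD tracks
        the continuous Fuerth form to well under 1%.

    Returns
    -------
    (n_steps + 1, 2) float array of positions, first row = ``start``.
    """
    if not isinstance(params, MotilityParams):
        raise TypeError("params must be a MotilityParams")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    rng = _as_rng(rng_seed)

    out = np.empty((n_steps + 1, 2), dtype=float)
    out[0] = start
    if params.speed == 0:
        out[:] = start
        return out

    p = params.persistence_time
    if n_substeps is None:
        if p > 0 and math.isfinite(p):
            n_substeps = int(min(64, max(1, math.ceil(16.0 * dt / p))))
        else:
            n_substeps = 1
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")

    dts = dt / n_substeps
    n_tot = n_steps * n_substeps
    theta0 = rng.uniform(0.0, 2.0 * math.pi)

    if p == 0:
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_tot)
        theta[0] = theta0
    else:
        var = (0.0 if math.isinf(p) else 2.0 * dts / p) + params.turn_noise ** 2 * (dts / dt)
        if var > 0:
            dtheta = rng.normal(0.0, math.sqrt(var), size=n_tot - 1) if n_tot > 1 else np.empty(0)
        else:
            dtheta = np.zeros(n_tot - 1)
        theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])

    step = params.speed * dts
    dx = np.cumsum(step * np.cos(theta))
    dy = np.cumsum(step * np.sin(theta))
    out[1:, 0] = start[0] + dx[n_substeps - 1::n_substeps]
    out[1:, 1] = start[1] + dy[n_substeps - 1::n_substeps]
    return out
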