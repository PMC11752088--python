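"""Monte-Carlo random-walk simulator for restricted diffusion in a sphere.

Independent numerical ground truth for the closed-form GPD sphere
attenuation: spins perform a Gaussian random walk inside an impermeable
sphere (radial reflection at the wall) while accruing phase under a pulsed
gradient pair.  Because the pulse shape is fixed, a single trajectory
ensemble yields the signal at every gradient amplitude: the net phase is
``gamma * g * psi`` with ``psi`` the accumulated (first pulse minus second
pulse) integral of the on-gradient coordinate.

This module deliberately shares no code with :mod:`sandicortex.signal`.
"""

from __future__ import annotations

import numpy as np

from .scheme import GAMMA_PROTON

__all__ = ["sphere_mc_signal"]


def sphere_mc_signal(r_um: float, d: float, g_values, delta: float, Delta: float,
                     n_spins: int = 100_000, dt: float = 0.015,
                     gamma: float = GAMMA_PROTON,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Attenuation at each gradient amplitude in ``g_values`` (mT/um).

    Spins start uniformly inside the sphere of radius ``r_um`` and diffuse
    with free diffusivity ``d`` (um^2/ms) in steps of ``dt`` ms; steps that
    leave the sphere are reflected radially.  The gradient points along z:
    phase is integrated over [0, delta] and subtracted over
    [Delta, Delta + delta].
    """
    if r_um <= 0 or d <= 0 or not (0 < delta <= Delta):
        raise ValueError("non-physical Monte-Carlo parameters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g_values = np.atleast_1d(np.asarray(g_values, dtype=float))

    # uniform start positions in the sphere
    pos = rng.standard_normal((n_spins, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= r_um * rng.random(n_spins)[:, None] ** (1.0 / 3.0)

    step_sd = np.sqrt(2.0 * d * dt)
    n_steps = int(np.ceil((Delta + delta) / dt))
    psi = np.zeros(n_spins)
    for k in range(n_steps):
        t_mid = (k + 0.5) * dt
        if t_mid < delta:
            psi += pos[:, 2] * dt
        elif Delta <= t_mid < Delta + delta:
            psi -= pos[:, 2] * dt
        pos += step_sd * rng.standard_normal((n_spins, 3))
        radius = np.linalg.norm(pos, axis=1)
        outside = radius > r_um
        if outside.any():
            # radial reflection back inside
            scale = (2.0 * r_um - radius[outside]) / radius[outside]
            pos[outside] *= scale[:, None]

    return np.array([np.mean(np.cos(gamma * g * psi)) for g in g_values])
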