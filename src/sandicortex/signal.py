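"""Three-compartment (sphere + stick + ball) powder-averaged signal model.

The model decomposes the direction-averaged diffusion signal of brain tissue
into restricted diffusion inside cell bodies (impermeable sphere of radius
``R_s``), diffusion along randomly oriented neurites (sticks) and Gaussian
extracellular diffusion (ball):

    S(b) / S(0) = f_is * A_sphere(b; R_s, D_is)
                + f_in * A_stick(b; D_in)
                + f_ec * A_ball(b; D_ec)

with signal fractions summing to one.  The sphere attenuation uses the
Gaussian-phase-distribution (GPD) series over the roots of the derivative of
the first-order spherical Bessel function; its correctness is anchored to a
Monte-Carlo random-walk simulator (see :mod:`sandicortex.montecarlo`).

Units: b in ms/um^2, diffusivities in um^2/ms, radii in um, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from .scheme import GAMMA_PROTON, GradientScheme

__all__ = [
    "SANDIParams",
    "ball_signal",
    "stick_powder_signal",
    "sphere_signal",
    "sphere_bessel_roots",
    "powder_signal",
    "spherical_mean",
]


@dataclass(frozen=True)
class SANDIParams:
    """Scalar compartment parameters of the three-compartment model."""

    f_is: float
    f_in: float
    f_ec: float
    r_s: float          # apparent soma radius, um
    d_is: float = 3.0   # intra-soma diffusivity, um^2/ms
    d_in: float = 2.0   # intra-neurite diffusivity, um^2/ms
    d_ec: float = 2.0   # extracellular diffusivity, um^2/ms

    def __post_init__(self) -> None:
        fr = np.array([self.f_is, self.f_in, self.f_ec], dtype=float)
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValueError("signal fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"signal fractions must sum to 1, got {fr.sum()!r}")
        if not self.r_s > 0:
            raise ValueError("soma radius must be positive")
        if min(self.d_is, self.d_in, self.d_ec) <= 0:
            raise ValueError("diffusivities must be positive")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_is, self.f_in, self.f_ec])


def ball_signal(b, d_ec):
    """Isotropic Gaussian attenuation exp(-b * D)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if np.any(np.asarray(d_ec) <= 0):
        raise ValueError("diffusivity must be positive")
    return np.exp(-b * d_ec)


def stick_powder_signal(b, d_in):
    """Direction-averaged attenuation of a stick compartment.

    sqrt(pi / (4 b D)) * erf(sqrt(b D)); the b*D -> 0 limit is 1.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative b-value")
    if np.any(np.asarray(d_in) <= 0):
        raise ValueError("diffusivity must be positive")
    bd = b * d_in
    out = np.ones(np.broadcast(b, np.asarray(d_in)).shape)
    nz = bd > 1e-12
    bdnz = np.broadcast_to(bd, out.shape)[nz]
    out[nz] = np.sqrt(np.pi / (4.0 * bdnz)) * erf(np.sqrt(bdnz))
    if out.ndim == 0 or np.isscalar(b):
        return float(out) if out.shape == () else out
    return out


def _neuman_characteristic(x: float) -> float:
    # roots of d/dx j1(x): 2 x cos x + (x^2 - 2) sin x = 0
    return 2.0 * x * np.cos(x) + (x * x - 2.0) * np.sin(x)


@lru_cache(maxsize=8)
def sphere_bessel_roots(m: int) -> np.ndarray:
    """First ``m`` positive roots of j1'(x) (first root ~2.0816)."""
    xs = np.arange(1e-4, (m + 3) * np.pi, 0.01)
    vals = np.array([_neuman_characteristic(x) for x in xs])
    sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
    roots = []
    for i in sign_change:
        r = brentq(_neuman_characteristic, xs[i], xs[i + 1], xtol=1e-14, rtol=1e-15)
        if r > 1e-3:
            roots.append(r)
        if len(roots) == m:
            break
    return np.array(roots)


def sphere_signal(r, d_is, g, delta, Delta, gamma: float = GAMMA_PROTON,
                  n_roots: int = 30):
    """GPD attenuation for diffusion restricted in an impermeable sphere.

    Parameters broadcast; ``r`` in um, ``d_is`` in um^2/ms, ``g`` in mT/um,
    timings in ms.  The series is truncated at ``n_roots`` Bessel-root terms;
    30 terms are converged to well below 1e-8 over the radii of interest.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    if np.any(np.asarray(d_is) <= 0):
        raise ValueError("diffusivity must be positive")
    if not (0 < delta <= Delta):
        raise ValueError("require 0 < delta <= Delta")
    if n_roots < 10:
        raise ValueError("series truncation below 10 terms is not reliable")
    beta = sphere_bessel_roots(n_roots)            # (M,)
    shape = np.broadcast(r, np.asarray(d_is), g).shape
    rb = np.broadcast_to(r, shape)[..., None]       # (..., 1)
    db = np.broadcast_to(np.asarray(d_is, dtype=float), shape)[..., None]
    gb = np.broadcast_to(g, shape)[..., None]
    a = (beta / rb) ** 2 * db                       # alpha_m^2 D, 1/ms
    # geometric weight: alpha^-4 / (alpha^2 R^2 - 2) = R^4 / (beta^4 (beta^2 - 2))
    weight = rb ** 4 / (beta ** 4 * (beta ** 2 - 2.0))
    bracket = 2.0 * delta - (
        2.0
        + np.exp(-a * (Delta - delta))
        - 2.0 * np.exp(-a * delta)
        - 2.0 * np.exp(-a * Delta)
        + np.exp(-a * (Delta + delta))
    ) / a
    log_att = -(2.0 * gamma ** 2 * gb ** 2 / db) * weight * bracket
    out = np.exp(np.sum(log_att, axis=-1))
    return float(out) if out.shape == () else out


def powder_signal(params: SANDIParams, scheme: GradientScheme,
                  n_roots: int = 30) -> np.ndarray:
    """Per-shell direction-averaged attenuation of the three-compartment mix.

    Returns one value per nonzero-b shell, ordered by increasing b.
    """
    shells = scheme.shells
    g = scheme.g_amplitudes()
    sph = sphere_signal(params.r_s, params.d_is, g, scheme.delta, scheme.Delta,
                        scheme.gamma, n_roots=n_roots)
    stk = stick_powder_signal(shells, params.d_in)
    bal = ball_signal(shells, params.d_ec)
    return params.f_is * np.asarray(sph) + params.f_in * stk + params.f_ec * bal


def spherical_mean(signal: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Per-shell mean over directions, normalized by the mean b=0 signal.

    ``signal`` may be (N,) for one voxel or (V, N) for V voxels; the shell
    means come back as (n_shells,) or (V, n_shells) ordered by increasing b.
    """
    sig = np.asarray(signal, dtype=float)
    one_d = sig.ndim == 1
    sig = np.atleast_2d(sig)
    if sig.shape[-1] != scheme.n_volumes:
        raise ValueError("signal length does not match scheme")
    b0 = scheme.b0_mask
    if not b0.any():
        raise ValueError("scheme has no b=0 volumes")
    s0 = sig[:, b0].mean(axis=1)
    out = np.empty((sig.shape[0], scheme.n_shells))
    for k in range(scheme.n_shells):
        sel = scheme.shell_index == k
        if not sel.any():
            raise ValueError(f"shell {k} has no directions")
        out[:, k] = sig[:, sel].mean(axis=1)
    out /= s0[:, None]
    return out[0] if one_d else out
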