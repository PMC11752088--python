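"""Pulsed-gradient spin-echo acquisition schemes.

A scheme is the per-volume table of b-values and gradient directions of a
multi-shell diffusion acquisition, together with the pulse timings (duration
``delta``, separation ``Delta``) that the restricted-diffusion compartment
needs.  Internal units follow the microstructure convention: b in ms/um^2,
diffusivity in um^2/ms, distances in um, gradient amplitude in mT/um, so that

    b = gamma^2 g^2 delta^2 (Delta - delta / 3)

holds without conversion factors.  File I/O speaks FSL bval/bvec (b in
s/mm^2, which is numerically 1e-3 ms/um^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "GradientScheme",
    "build_default_scheme",
    "b_to_g",
    "g_to_b",
    "fibonacci_directions",
    "read_scheme",
    "write_scheme",
]

#: Proton gyromagnetic ratio, rad / (ms * mT).
GAMMA_PROTON = 267.513_287_18

#: The eight diffusion weightings of the default protocol, s/mm^2.
DEFAULT_SHELLS_SMM2 = (50.0, 350.0, 800.0, 1500.0, 2400.0, 3450.0, 4750.0, 6000.0)
DEFAULT_SHELL_SIZES = (32, 32, 32, 32, 64, 64, 64, 64)
B0_EVERY = 16


def b_to_g(b: float | np.ndarray, delta: float, Delta: float,
           gamma: float = GAMMA_PROTON) -> float | np.ndarray:
    """Gradient amplitude (mT/um) giving diffusion weighting ``b`` (ms/um^2)."""
    return np.sqrt(np.asarray(b, dtype=float) / (gamma ** 2 * delta ** 2 * (Delta - delta / 3.0)))


def g_to_b(g: float | np.ndarray, delta: float, Delta: float,
           gamma: float = GAMMA_PROTON) -> float | np.ndarray:
    return gamma ** 2 * np.asarray(g, dtype=float) ** 2 * delta ** 2 * (Delta - delta / 3.0)


def fibonacci_directions(n: int, seed: int | None = None) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (spherical Fibonacci).

    A seeded random rotation decorrelates the lattice between shells while
    keeping the construction fully deterministic.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    if seed is not None:
        rng = np.random.default_rng(seed)
        # random rotation from QR of a Gaussian matrix
        q, rr = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(rr))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        dirs = dirs @ q.T
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume acquisition table of a PGSE multi-shell protocol.

    Attributes
    ----------
    b : (N,) float array, ms/um^2.  Zero marks non-diffusion-weighted volumes.
    bvecs : (N, 3) float array of unit direction vectors (zero rows for b=0).
    delta, Delta : gradient pulse duration and separation, ms.
    gamma : gyromagnetic ratio, rad/(ms*mT).
    """

    b: np.ndarray
    bvecs: np.ndarray
    delta: float
    Delta: float
    gamma: float = GAMMA_PROTON
    shell_index: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        v = np.asarray(self.bvecs, dtype=float)
        if b.ndim != 1 or v.shape != (b.size, 3):
            raise ValueError("b must be (N,) and bvecs (N, 3)")
        if np.any(b < 0):
            raise ValueError("negative b-value")
        if not (self.delta > 0 and self.Delta >= self.delta):
            raise ValueError("require 0 < delta <= Delta")
        weighted = b > 0
        norms = np.linalg.norm(v[weighted], axis=1)
        if weighted.any() and np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError("weighted directions must have unit norm")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "bvecs", v)
        if self.shell_index is None:
            shells = self.shells
            idx = np.full(b.size, -1, dtype=int)
            for k, bs in enumerate(shells):
                idx[np.isclose(b, bs)] = k
            object.__setattr__(self, "shell_index", idx)

    # -- derived views -------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return int(self.b.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique nonzero b-values, ms/um^2."""
        return np.unique(self.b[self.b > 0])

    @property
    def n_shells(self) -> int:
        return int(self.shells.size)

    def g_amplitudes(self, shells: np.ndarray | None = None) -> np.ndarray:
        """Gradient amplitude per shell (mT/um)."""
        bs = self.shells if shells is None else np.asarray(shells, dtype=float)
        return b_to_g(bs, self.delta, self.Delta, self.gamma)

    def shell_sizes(self) -> np.ndarray:
        return np.array([int(np.sum(self.shell_index == k)) for k in range(self.n_shells)])


def build_default_scheme(delta: float = 8.0, Delta: float = 19.0,
                         seed: int = 20_260_101) -> GradientScheme:
    """The default 8-shell protocol.

    Four shells at b = 50, 350, 800, 1500 s/mm^2 with 32 directions and four
    at b = 2400, 3450, 4750, 6000 s/mm^2 with 64 directions; an unweighted
    (b=0) volume every 16 volumes, as acquired in practice.
    """
    b_list: list[float] = []
    v_list: list[np.ndarray] = []
    for k, (b_smm2, n_dir) in enumerate(zip(DEFAULT_SHELLS_SMM2, DEFAULT_SHELL_SIZES)):
        dirs = fibonacci_directions(n_dir, seed=seed + k)
        for d in dirs:
            b_list.append(b_smm2 * 1e-3)  # s/mm^2 -> ms/um^2
            v_list.append(d)
    # interleave b=0 at every B0_EVERY-th position
    b_out: list[float] = []
    v_out: list[np.ndarray] = []
    j = 0
    i = 0
    while j < len(b_list):
        if i % B0_EVERY == 0:
            b_out.append(0.0)
            v_out.append(np.zeros(3))
        else:
            b_out.append(b_list[j])
            v_out.append(v_list[j])
            j += 1
        i += 1
    return GradientScheme(np.array(b_out), np.array(v_out), delta=delta, Delta=Delta)


# ---------------------------------------------------------------------------
# FSL-style I/O: prefix.bval / prefix.bvec / prefix.json (delta, Delta)
# ---------------------------------------------------------------------------

def write_scheme(scheme: GradientScheme, prefix: str | Path) -> None:
    prefix = Path(prefix)
    # round at 1e-6 s/mm^2 so the s/mm^2 <-> ms/um^2 conversion is exactly
    # invertible for protocol-precision b-values
    bvals_smm2 = np.round(scheme.b * 1e3, 6)
    with open(prefix.with_suffix(".bval"), "w") as fh:
        fh.write(" ".join(repr(float(x)) for x in bvals_smm2) + "\n")
    with open(prefix.with_suffix(".bvec"), "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump({"delta_ms": scheme.delta, "Delta_ms": scheme.Delta,
                   "gamma_rad_per_ms_mT": scheme.gamma}, fh, indent=1)


def read_scheme(prefix: str | Path) -> GradientScheme:
    prefix = Path(prefix)
    bvec_path = prefix.with_suffix(".bvec")
    if not bvec_path.exists():
        raise FileNotFoundError(f"missing bvec file: {bvec_path}")
    bvals = np.loadtxt(prefix.with_suffix(".bval"), ndmin=1) * 1e-3
    bvecs = np.loadtxt(bvec_path, ndmin=2).T
    with open(prefix.with_suffix(".json")) as fh:
        side = json.load(fh)
    return GradientScheme(bvals, bvecs, delta=side["delta_ms"], Delta=side["Delta_ms"],
                          gamma=side.get("gamma_rad_per_ms_mT", GAMMA_PROTON))
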