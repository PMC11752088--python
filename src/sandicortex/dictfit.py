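"""Dictionary-based linearized estimation of soma/neurite/extracellular maps.

The voxelwise inverse problem is solved in the linearized, dictionary style:
the forward model is precomputed as per-shell powder attenuations of sphere
atoms (soma-radius grid at fixed intra-soma diffusivity), stick atoms
(intra-neurite diffusivity grid) and ball atoms (extracellular diffusivity
grid), and every voxel's spherical-mean signal is decomposed into
nonnegative atom weights under an L2 (ridge) penalty ``lambda2``:

    min_x  || A_m x - y ||^2 + lambda2 ||x||^2,   x >= 0.

Because the tissue model has a *single* intra-neurite diffusivity, a single
extracellular diffusivity and a single soma radius per voxel, the
decomposition is not a free spectrum over all atoms at once (with eight
shell means such a spectrum is wildly degenerate, and any penalty then
shuffles weight between compartments).  Instead the fit enumerates compact
candidate models m — one sphere atom, one stick atom, one ball atom, plus
the free-water ball — and selects the candidate with the lowest objective.
The apparent soma radius is refined off-grid by parabolic interpolation of
the objective profile along the radius grid.  Each candidate is a small
well-conditioned NNLS problem solved exactly by active-set enumeration,
batched over voxels; keeping a single sphere atom per candidate avoids the
near-collinear atom pairs whose sign clamps bias the compartment fractions
under noise.

Shell-mean rows are weighted by their direction counts, which reproduces
the least-squares objective of the full per-volume acquisition and whitens
the shell-mean noise.

Free-water handling: at 2 mm isotropic resolution cortical voxels carry
appreciable CSF partial volume.  The ball atom at the free-water
diffusivity (3.0 um^2/ms by default) is therefore treated as a separate
CSF compartment, always available to the fit and excluded from the
tissue-fraction normalization, so the reported fractions are tissue
fractions.  Set ``free_water_compartment=False`` for the plain all-atom
normalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .scheme import GradientScheme
from .signal import ball_signal, sphere_signal, spherical_mean, stick_powder_signal

__all__ = ["FitConfig", "Dictionary", "SANDIMaps", "build_dictionary",
           "fit_voxel", "fit_shell_means", "fit_volume", "VoxelFit"]

_TOL = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Dictionary-fit configuration.

    ``lambda2`` is the ridge weight of the regularized NNLS; the grids
    define the dictionary atoms; ``d_is`` is the fixed intra-soma
    diffusivity.  The exploratory defaults span diffusivity grids; the
    cohort pipeline fixes the diffusivities to the model defaults
    (:func:`FitConfig.pipeline_default`), which makes the voxelwise problem
    well conditioned at realistic noise levels.
    """

    lambda2: float = 0.005
    r_grid: tuple = tuple(float(r) for r in np.linspace(1.0, 12.0, 12))
    d_in_grid: tuple = (0.25, 0.75, 1.25, 2.0, 3.0)
    d_ec_grid: tuple = (0.25, 0.75, 1.25, 2.0, 3.0)
    d_is: float = 3.0
    n_roots: int = 30
    free_water_compartment: bool = True
    free_water_diffusivity: float = 3.0
    rs_volume_weighted: bool = False
    rician_floor_correction: bool = True

    def __post_init__(self) -> None:
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be nonnegative")
        for grid in (self.r_grid, self.d_in_grid, self.d_ec_grid):
            g = np.asarray(grid, dtype=float)
            if np.any(g <= 0) or (g.size > 1 and np.any(np.diff(g) <= 0)):
                raise ValueError("grids must be strictly increasing and positive")

    @classmethod
    def pipeline_default(cls, **overrides) -> "FitConfig":
        """Fixed default diffusivities (single stick and ball atoms)."""
        kw = dict(d_in_grid=(2.0,), d_ec_grid=(2.0,))
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_atoms(self) -> int:
        return len(self.r_grid) + len(self.d_in_grid) + len(self.d_ec_grid)


@dataclass
class Dictionary:
    """Atom matrix plus metadata mapping columns to compartments.

    ``matrix`` rows are the hypothetical b=0 row (all ones) followed by the
    nonzero-b shells in increasing order; columns are atoms.
    """

    matrix: np.ndarray              # (1 + n_shells, n_atoms)
    compartment: np.ndarray         # (n_atoms,) str in {"sphere", "stick", "ball"}
    value: np.ndarray               # (n_atoms,) radius or diffusivity
    config: FitConfig
    row_weights: np.ndarray = None  # volumes per row; shell means are averages
    _banks: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.row_weights is None:
            self.row_weights = np.ones(self.matrix.shape[0])

    @property
    def sphere_cols(self) -> np.ndarray:
        return self.compartment == "sphere"

    @property
    def stick_cols(self) -> np.ndarray:
        return self.compartment == "stick"

    @property
    def ball_cols(self) -> np.ndarray:
        return self.compartment == "ball"

    @property
    def csf_cols(self) -> np.ndarray:
        """Columns used as free water (excluded from tissue fractions)."""
        if not self.config.free_water_compartment:
            return np.zeros(self.value.size, dtype=bool)
        return self.ball_cols & np.isclose(self.value, self.config.free_water_diffusivity)


def build_dictionary(scheme: GradientScheme, config: FitConfig | None = None) -> Dictionary:
    """Per-shell powder attenuations of every atom, with a leading b=0 row.

    When the free-water compartment is enabled and the ball grid does not
    contain the free-water diffusivity, a dedicated free-water ball atom is
    appended.
    """
    config = config or FitConfig()
    shells = scheme.shells
    if shells.size == 0:
        raise ValueError("scheme has no nonzero-b shells")
    g = scheme.g_amplitudes()
    cols, comp, val = [], [], []
    for r in config.r_grid:
        cols.append(sphere_signal(r, config.d_is, g, scheme.delta, scheme.Delta,
                                  scheme.gamma, n_roots=config.n_roots))
        comp.append("sphere")
        val.append(r)
    for d in config.d_in_grid:
        cols.append(stick_powder_signal(shells, d))
        comp.append("stick")
        val.append(d)
    ball_grid = list(config.d_ec_grid)
    if config.free_water_compartment and not np.any(
            np.isclose(ball_grid, config.free_water_diffusivity)):
        ball_grid.append(config.free_water_diffusivity)
    for d in ball_grid:
        cols.append(ball_signal(shells, d))
        comp.append("ball")
        val.append(d)
    matrix = np.vstack([np.ones(len(cols)), np.column_stack(cols)])
    # Each shell-mean row stands for all the volumes averaged into it, so
    # the rows are weighted by direction counts: this reproduces the
    # per-volume least-squares objective and whitens the shell-mean noise.
    weights = np.concatenate([[max(int(scheme.b0_mask.sum()), 1)],
                              scheme.shell_sizes()]).astype(float)
    return Dictionary(matrix, np.array(comp), np.array(val, dtype=float), config,
                      row_weights=weights)


# ---------------------------------------------------------------------------
# candidate-model bank: precomputed active-set solvers, shared across voxels
# ---------------------------------------------------------------------------

class _Candidate:
    """One compact model: column indices plus exact NNLS machinery.

    The free-water coefficient (``free_row``) is sign-unconstrained: a
    nonnegativity bound there would truncate its noise one-sidedly and bias
    the tissue fractions upward wherever CSF partial volume is small.
    """

    __slots__ = ("cols", "a", "g0", "gl", "supports", "free_row")

    def __init__(self, a_full: np.ndarray, cols: np.ndarray, lam: float,
                 row_weights: np.ndarray, free_row: int | None):
        self.cols = cols
        self.free_row = free_row
        self.a = a_full[:, cols] * np.sqrt(row_weights)[:, None]
        k = cols.size
        self.g0 = self.a.T @ self.a
        self.gl = self.g0 + lam * np.eye(k)
        constrained = [i for i in range(k) if i != free_row]
        always = [] if free_row is None else [free_row]
        self.supports = []
        for size in range(0, len(constrained) + 1):
            for s in itertools.combinations(constrained, size):
                s = np.array(list(s) + always, dtype=int)
                if s.size == 0:
                    continue
                self.supports.append((
                    s,
                    np.linalg.pinv(self.g0[np.ix_(s, s)]),
                    np.linalg.pinv(self.gl[np.ix_(s, s)]),
                ))


def _model_bank(dictionary: Dictionary, config: FitConfig) -> list[list[_Candidate]]:
    """Candidates grouped by (stick, ball) pair, ordered by sphere radius."""
    key = (config.lambda2, config.free_water_compartment, config.free_water_diffusivity)
    if key in dictionary._banks:
        return dictionary._banks[key]
    a = dictionary.matrix
    sph = np.where(dictionary.sphere_cols)[0]
    csf = np.where(dictionary.csf_cols)[0][:1]
    stk = np.where(dictionary.stick_cols)[0]
    bal = np.where(dictionary.ball_cols & ~dictionary.csf_cols)[0]
    if bal.size == 0:       # the only ball atom is the free-water one
        bal = np.where(dictionary.ball_cols)[0]
        csf = np.array([], dtype=int)
    bank = []
    for i_s in stk:
        for i_b in bal:
            group = []
            for i_r in sph:
                cols = np.concatenate([[i_r, i_s, i_b], csf])
                free_row = cols.size - 1 if csf.size else None
                group.append(_Candidate(a, cols, config.lambda2,
                                        dictionary.row_weights, free_row))
            bank.append(group)
    dictionary._banks[key] = bank
    return bank


def _nnls_enum(cand: _Candidate, b: np.ndarray, which: str,
               support_of: np.ndarray | None = None) -> tuple:
    """Exact batched NNLS via support enumeration.

    Returns (x_full (k, V), objective_quadratic (V,), solved (V,)) where the
    objective omits the constant ||y||^2 term.  When ``support_of`` is
    given, only supports contained in its per-voxel nonzero pattern are
    admitted (KKT is then checked within that pattern).
    """
    g = cand.g0 if which == "g0" else cand.gl
    k, v = cand.cols.size, b.shape[1]
    x_out = np.zeros((k, v))
    obj = np.full(v, np.inf)
    solved = np.zeros(v, dtype=bool)
    allowed = None
    if support_of is not None:
        allowed = np.abs(support_of) > _TOL
        if cand.free_row is not None:
            allowed[cand.free_row] = True
    for s, inv0, invl in cand.supports:
        inv = inv0 if which == "g0" else invl
        x = inv @ b[s]
        if cand.free_row is None:
            signed = np.zeros(s.size, dtype=bool)
        else:
            signed = s == cand.free_row      # sign-unconstrained rows of s
        feas = np.all(x[~signed] >= -_TOL, axis=0)
        if allowed is not None:
            feas = feas & np.all(allowed[s], axis=0)
        if not feas.any():
            continue
        grad = g[:, s] @ x - b
        nots = np.setdiff1d(np.arange(k), s)
        if nots.size:
            if allowed is not None:
                # zero coordinates outside the admitted pattern are fixed,
                # not constrained-active: no dual condition applies there
                kkt = np.all((grad[nots] >= -1e-8) | ~allowed[nots], axis=0)
            else:
                kkt = np.all(grad[nots] >= -1e-8, axis=0)
        else:
            kkt = np.ones(v, bool)
        gss = g[np.ix_(s, s)]
        score = -2.0 * np.einsum("iv,iv->v", x, b[s]) + np.einsum(
            "iv,iv->v", x, gss @ x)
        upd = feas & kkt & (score < obj - 1e-15)
        if not upd.any():
            continue
        obj[upd] = score[upd]
        solved[upd] = True
        x_out[:, upd] = 0.0
        xu = x[:, upd]
        xu[~signed] = np.clip(xu[~signed], 0.0, None)
        x_out[np.ix_(s, np.where(upd)[0])] = xu
    return x_out, obj, solved


def fit_shell_means(shell_means: np.ndarray, dictionary: Dictionary,
                    config: FitConfig | None = None) -> dict:
    """Fit many voxels at once.

    ``shell_means`` is (V, n_shells), already normalized by b=0.  Returns a
    dict of (V,) arrays: f_is, f_in, f_ec, r_s, f_csf, residual, ok,
    soma_defined.
    """
    config = config or dictionary.config
    y = np.atleast_2d(np.asarray(shell_means, dtype=float))
    if y.shape[1] != dictionary.matrix.shape[0] - 1:
        raise ValueError("shell_means length does not match dictionary")
    v = y.shape[0]
    bad = ~np.all(np.isfinite(y), axis=1) | np.all(y == 0, axis=1)
    yf = np.vstack([np.ones(v), y.T])
    yf[:, bad] = 0.0
    yf = yf * np.sqrt(dictionary.row_weights)[:, None]
    total_w = float(np.sum(dictionary.row_weights))
    yty = np.einsum("iv,iv->v", yf, yf)
    bank = _model_bank(dictionary, config)

    best_obj = np.full(v, np.inf)
    best_group = np.full(v, -1, dtype=int)
    best_ridx = np.full(v, -1, dtype=int)
    out = {k: np.full(v, np.nan) for k in
           ("sph_sum", "stick", "ball", "csf", "rss", "r_grid")}
    profiles = []                                  # per group: (n_R, V)
    for gi, group in enumerate(bank):
        prof = np.full((len(group), v), np.inf)
        for ri, cand in enumerate(group):
            b = cand.a.T @ yf
            # model choice by unpenalized residual; the ridge then only
            # stabilizes the coefficients within the chosen support
            x0, obj, solved = _nnls_enum(cand, b, "g0")
            if config.lambda2 > 0:
                xl, _, okl = _nnls_enum(cand, b, "gl", support_of=x0)
                x = np.where(okl[None, :], xl, x0)
            else:
                x = x0
            prof[ri] = np.where(solved, obj + yty, np.inf)
            upd = solved & (obj + yty < best_obj - 1e-15)
            if not upd.any():
                continue
            best_obj[upd] = (obj + yty)[upd]
            best_group[upd] = gi
            best_ridx[upd] = ri
            comp = dictionary.compartment[cand.cols]
            is_csf = dictionary.csf_cols[cand.cols]
            xu = x[:, upd]
            sph_rows = np.where(comp == "sphere")[0]
            out["sph_sum"][upd] = xu[sph_rows].sum(axis=0)
            out["r_grid"][upd] = dictionary.value[cand.cols[sph_rows[0]]]
            stick_rows = np.where((comp == "stick") & ~is_csf)[0]
            out["stick"][upd] = xu[stick_rows].sum(axis=0)
            ball_rows = np.where((comp == "ball") & ~is_csf)[0]
            out["ball"][upd] = xu[ball_rows].sum(axis=0)
            csf_rows = np.where(is_csf)[0]
            out["csf"][upd] = xu[csf_rows].sum(axis=0) if csf_rows.size else 0.0
            rss = yty[upd] - 2.0 * np.einsum("iv,iv->v", xu, b[:, upd]) \
                + np.einsum("iv,iv->v", xu, cand.g0 @ xu)
            out["rss"][upd] = rss
        profiles.append(prof)

    # sub-grid soma radius: parabolic refinement of the objective profile
    # along the radius grid within the winning (stick, ball) pair
    radii = np.array([dictionary.value[cand.cols[0]] for cand in bank[0]]) \
        if bank else np.array([])
    n_r = len(bank[0]) if bank else 0
    r_s = out["r_grid"].copy()
    if n_r >= 3:
        interior = (best_ridx > 0) & (best_ridx < n_r - 1) & (best_group >= 0)
        idx = np.where(interior)[0]
        if idx.size:
            gi = best_group[idx]
            ri = best_ridx[idx]
            prof_all = np.stack(profiles)           # (G, n_R, V)
            a_ = prof_all[gi, ri - 1, idx]
            b_ = prof_all[gi, ri, idx]
            c_ = prof_all[gi, ri + 1, idx]
            r0, r1, r2 = radii[ri - 1], radii[ri], radii[ri + 1]
            num = (r1 - r0) ** 2 * (b_ - c_) - (r1 - r2) ** 2 * (b_ - a_)
            den = (r1 - r0) * (b_ - c_) - (r1 - r2) * (b_ - a_)
            usable = (np.isfinite(a_) & np.isfinite(c_) & (den < 0)
                      & (b_ > 1e-8))               # exact fits stay on-grid
            vertex = np.where(usable, r1 - 0.5 * num / np.where(den == 0, 1, den), r1)
            vertex = np.clip(vertex, r0, r2)
            r_s[idx] = vertex

    tissue = out["sph_sum"] + out["stick"] + out["ball"]
    total = tissue + out["csf"]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = {
            "f_is": out["sph_sum"] / tissue,
            "f_in": out["stick"] / tissue,
            "f_ec": out["ball"] / tissue,
            "f_csf": out["csf"] / total,
            "residual": np.sqrt(np.clip(out["rss"], 0.0, None) / total_w),
            "r_s": r_s,
        }
    res["soma_defined"] = out["sph_sum"] > _TOL
    res["r_s"] = np.where(res["soma_defined"], res["r_s"], np.nan)
    res["ok"] = (best_group >= 0) & ~bad & (tissue > _TOL)
    for name in ("f_is", "f_in", "f_ec", "r_s", "f_csf", "residual"):
        res[name] = np.where(res["ok"], res[name], np.nan)
    res["soma_defined"] &= res["ok"]
    return res


@dataclass
class VoxelFit:
    f_is: float
    f_in: float
    f_ec: float
    r_s: float            # nan when no soma weight
    f_csf: float          # free-water signal share (0 without the option)
    residual: float       # rms residual per acquired volume
    ok: bool
    soma_defined: bool


def fit_voxel(shell_means: np.ndarray, dictionary: Dictionary,
              config: FitConfig | None = None) -> VoxelFit:
    """Regularized NNLS decomposition of one voxel's spherical-mean signal.

    ``shell_means`` are the per-shell direction averages already normalized
    by the mean b=0 signal (the fit prepends the implicit y=1 at b=0).
    """
    r = fit_shell_means(np.asarray(shell_means, dtype=float)[None, :],
                        dictionary, config)
    return VoxelFit(*(float(r[k][0]) for k in
                      ("f_is", "f_in", "f_ec", "r_s", "f_csf", "residual")),
                    ok=bool(r["ok"][0]), soma_defined=bool(r["soma_defined"][0]))


MAP_NAMES = ("f_is", "f_in", "f_ec", "r_s")


@dataclass
class SANDIMaps:
    """Voxelwise parameter maps sharing one image grid."""

    maps: dict                      # name -> 3D float32 array (nan outside fit)
    valid: np.ndarray               # bool, fit succeeded
    soma_defined: np.ndarray        # bool, R_s defined
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def fit_volume(dwi: np.ndarray, scheme: GradientScheme, mask: np.ndarray,
               config: FitConfig | None = None,
               affine: np.ndarray | None = None) -> SANDIMaps:
    """Apply the spherical-mean dictionary fit to every voxel in ``mask``.

    With ``rician_floor_correction`` the per-shell means are computed from
    second moments with the noise variance estimated from the interleaved
    b=0 volumes, removing the Rician noise floor at high b.
    """
    config = config or FitConfig()
    dwi = np.asarray(dwi)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4 or dwi.shape[:3] != mask.shape:
        raise ValueError("dwi must be 4D and share its grid with mask")
    if dwi.shape[3] != scheme.n_volumes:
        raise ValueError("scheme does not match the 4th dimension")
    if not mask.any():
        raise ValueError("empty mask")
    dictionary = build_dictionary(scheme, config)
    vox = dwi[mask].astype(float)                       # (V, N)
    if config.rician_floor_correction and int(scheme.b0_mask.sum()) >= 3:
        b0 = vox[:, scheme.b0_mask]
        sigma2 = np.var(b0, axis=1, ddof=1)
        s0 = np.sqrt(np.clip(np.mean(b0 ** 2, axis=1) - 2.0 * sigma2, 1e-12, None))
        means = np.empty((vox.shape[0], scheme.n_shells))
        for k in range(scheme.n_shells):
            m2 = np.mean(vox[:, scheme.shell_index == k] ** 2, axis=1)
            means[:, k] = np.sqrt(np.clip(m2 - 2.0 * sigma2, 0.0, None))
        means /= s0[:, None]
    else:
        means = spherical_mean(vox, scheme)
    fits = fit_shell_means(means, dictionary, config)
    shape = mask.shape
    out = {}
    for name in MAP_NAMES + ("f_csf", "residual"):
        vol = np.full(shape, np.nan, dtype=np.float32)
        vol[mask] = fits[name]
        out[name] = vol
    valid = np.zeros(shape, dtype=bool)
    valid[mask] = fits["ok"]
    soma = np.zeros(shape, dtype=bool)
    soma[mask] = fits["soma_defined"]
    return SANDIMaps(out, valid, soma,
                     affine=np.eye(4) if affine is None else affine)
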