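"""Synthetic cortical-lesion phantom cohorts.

Builds subject-level phantoms — a spherical "brain" with a WM core, a
cortical gray-matter ribbon and surrounding CSF on a 1 mm construction
grid, leukocortical lesions seeded on the GM/WM interface, per-region
ground-truth tissue parameters — and simulates the multi-shell
diffusion-weighted signal at 2 mm with Rician noise.

The cohort generator mirrors the study design the package targets: an MS
group whose regional parameter distributions follow the published
lesional → perilesional → normal-appearing gradients, and an age/sex
comparable healthy-control group with a single whole-cortex parameter
distribution and no lesions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .regions import RegionMasks, build_shells
from .scheme import GradientScheme, build_default_scheme, write_scheme
from .signal import SANDIParams, ball_signal, sphere_signal, stick_powder_signal

__all__ = [
    "GeometryConfig", "CohortConfig", "Geometry", "PhantomSubject",
    "REGION_PRESETS", "TISSUE_DEFAULTS",
    "make_geometry", "sample_lesions", "assign_truth", "simulate_dwi",
    "generate_cohort", "write_subject",
]

# ---------------------------------------------------------------------------
# presets: per-region (mean, between-subject SD) of each measure
# ---------------------------------------------------------------------------

#: Regional measure distributions of the MS group: mean and between-subject
#: SD of each measure in normal-appearing cortex, the outer and inner
#: perilesional layers and cortical lesions.
PRESET_TABLE3_MS = {
    "na_cortex":   {"f_is": (0.57, 0.034), "f_in": (0.17, 0.015),
                    "f_ec": (0.26, 0.036), "r_s": (9.99, 0.127)},
    "outer_layer": {"f_is": (0.55, 0.039), "f_in": (0.18, 0.030),
                    "f_ec": (0.27, 0.035), "r_s": (10.07, 0.149)},
    "inner_layer": {"f_is": (0.55, 0.049), "f_in": (0.19, 0.030),
                    "f_ec": (0.27, 0.042), "r_s": (10.19, 0.140)},
    "lesion":      {"f_is": (0.49, 0.089), "f_in": (0.18, 0.041),
                    "f_ec": (0.32, 0.086), "r_s": (10.38, 0.209)},
}

#: Healthy-control whole-cortex distribution.
PRESET_TABLE2_HC = {
    "cortex": {"f_is": (0.58, 0.028), "f_in": (0.17, 0.015),
               "f_ec": (0.25, 0.024), "r_s": (10.02, 0.069)},
}

REGION_PRESETS = {"table3_ms": PRESET_TABLE3_MS, "table2_hc": PRESET_TABLE2_HC}

#: Fixed non-cortical tissue parameters (plumbing, not study claims): WM is
#: stick-dominated with a plausible soma contribution; CSF is free water.
TISSUE_DEFAULTS = {
    "wm": SANDIParams(f_is=0.35, f_in=0.45, f_ec=0.20, r_s=9.0,
                      d_in=2.0, d_ec=2.0),
    "csf_diffusivity": 3.0,
}

MEASURES = ("f_is", "f_in", "f_ec", "r_s")


@dataclass(frozen=True)
class GeometryConfig:
    """Spherical brain geometry on the 1 mm construction grid.

    The cortical ribbon spans ``r_wm``..``r_gm`` (3.5 mm by default) and
    CSF fills out to ``r_csf``; everything beyond is background.
    """

    n: int = 96                 # construction grid size (1 mm isotropic)
    voxel_mm: float = 1.0
    r_wm: float = 28.0
    r_gm: float = 31.5
    r_csf: float = 36.0
    block: int = 2              # aggregation factor to the analysis grid

    @property
    def analysis_voxel_mm(self) -> float:
        return self.voxel_mm * self.block


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design: group sizes, lesion burden, presets, noise, seed."""

    n_ms: int = 41
    n_hc: int = 34
    ms_preset: str = "table3_ms"
    hc_preset: str = "table2_hc"
    lesion_count_median: float = 8.0
    lesion_count_log_sd: float = 0.8
    lesion_radius_median_mm: float = 1.55
    lesion_radius_log_sd: float = 0.25
    lesion_radius_min_mm: float = 1.0
    snr: float = 50.0
    age_ms: tuple = (45.2, 12.9)
    age_hc: tuple = (39.1, 14.8)
    male_frac_ms: float = 0.268
    male_frac_hc: float = 0.41
    jitter_fraction_sd: float = 0.01
    jitter_radius_sd: float = 0.05
    master_seed: int = 1
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.n_ms < 1 or self.n_hc < 1:
            raise ValueError("group sizes must be positive")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        for preset in (self.ms_preset, self.hc_preset):
            if preset not in REGION_PRESETS:
                raise ValueError(f"unknown preset {preset!r}")


# tissue label codes on the construction grid
BG, CSF, GM, WM, LESION = 0, 1, 2, 3, 4


@dataclass
class Geometry:
    labels: np.ndarray              # (n, n, n) int8 on the 1 mm grid
    config: GeometryConfig

    def partial_volumes(self) -> dict:
        """Exact 2x2x2 block aggregation of the labels to the 2 mm grid."""
        return {name: _block_mean(self.labels == code, self.config.block)
                for name, code in
                (("csf", CSF), ("gm", GM), ("wm", WM), ("lesion", LESION))}


def _block_mean(vol: np.ndarray, block: int) -> np.ndarray:
    n = vol.shape[0]
    m = n // block
    return (vol.astype(np.float32)
            .reshape(m, block, m, block, m, block).mean(axis=(1, 3, 5)))


def _radius_grid(cfg: GeometryConfig) -> np.ndarray:
    idx = np.arange(cfg.n) - (cfg.n - 1) / 2.0
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    return np.sqrt(x * x + y * y + z * z) * cfg.voxel_mm


def make_geometry(seed: int = 0, config: GeometryConfig | None = None) -> Geometry:
    """Concentric spherical geometry: WM core, cortical ribbon, CSF.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages.
    """
    cfg = config or GeometryConfig()
    r = _radius_grid(cfg)
    labels = np.zeros((cfg.n,) * 3, dtype=np.int8)
    labels[r < cfg.r_csf] = CSF
    labels[r < cfg.r_gm] = GM
    labels[r < cfg.r_wm] = WM
    return Geometry(labels, cfg)


@dataclass
class LesionRecord:
    center_mm: tuple
    radius_mm: float
    n_voxels_1mm: int               # voxels newly converted by this lesion


def sample_lesions(geometry: Geometry, config: CohortConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[LesionRecord]]:
    """Draw a lesion burden and carve leukocortical lesions into the labels.

    Lesion count is lognormal (median/log-SD from the config, rounded, at
    least 1); each lesion is a sphere centered on the GM/WM interface so it
    straddles the boundary (leukocortical).  Returns updated labels and the
    per-lesion records; lesions may coalesce, in which case the later
    record only counts newly converted voxels.
    """
    cfg = geometry.config
    labels = geometry.labels.copy()
    r = _radius_grid(cfg)
    interface = np.abs(r - cfg.r_wm) < 0.5 * cfg.voxel_mm
    sites = np.argwhere(interface)
    if sites.size == 0:
        raise ValueError("no placeable lesion sites on the GM/WM interface")
    count = max(1, int(round(rng.lognormal(np.log(config.lesion_count_median),
                                           config.lesion_count_log_sd))))
    idx = np.arange(cfg.n) - (cfg.n - 1) / 2.0
    records = []
    for _ in range(count):
        c = sites[rng.integers(len(sites))]
        rad = max(config.lesion_radius_min_mm,
                  rng.lognormal(np.log(config.lesion_radius_median_mm),
                                config.lesion_radius_log_sd))
        lo = np.maximum(c - int(np.ceil(rad)) - 1, 0)
        hi = np.minimum(c + int(np.ceil(rad)) + 2, cfg.n)
        sl = tuple(slice(lo[d], hi[d]) for d in range(3))
        xx, yy, zz = np.meshgrid(*(idx[sl[d]] for d in range(3)), indexing="ij")
        cx, cy, cz = (c - (cfg.n - 1) / 2.0) * cfg.voxel_mm
        inside = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) <= rad ** 2
        patch = labels[sl]
        new = inside & ((patch == GM) | (patch == WM))
        patch[new] = LESION
        labels[sl] = patch
        records.append(LesionRecord(tuple(float(v) for v in (cx, cy, cz)),
                                    float(rad), int(new.sum())))
    return labels, records


@dataclass
class PhantomSubject:
    """One synthetic subject: geometry, lesions, truth draws, demographics."""

    subject_id: str
    group: str                      # "MS" | "HC"
    age: float
    sex: str                        # "M" | "F"
    seed: int
    labels: np.ndarray              # 1 mm labels including lesions
    pv: dict                        # 2 mm partial-volume maps per tissue
    lesion_records: list
    region_params: dict             # region -> SANDIParams (subject draws)
    masks: RegionMasks | None = None
    truth: dict | None = None       # voxelwise truth fields (2 mm)
    dwi: np.ndarray | None = None   # (m, m, m, N) float32
    geometry_config: GeometryConfig = field(default_factory=GeometryConfig)

    @property
    def total_lesion_volume_ml(self) -> float:
        vox = self.geometry_config.voxel_mm ** 3
        return sum(rec.n_voxels_1mm for rec in self.lesion_records) * vox / 1000.0

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_records)

    @property
    def cortex_pv(self) -> np.ndarray:
        """Cortical partial volume: GM ribbon plus cortical-lesion tissue."""
        return self.pv["gm"] + self.pv["lesion"]

    @property
    def brain_pv(self) -> np.ndarray:
        return self.pv["gm"] + self.pv["wm"] + self.pv["csf"] + self.pv["lesion"]


def _draw_region_params(preset: dict, rng: np.random.Generator,
                        sd_scale: float = 1.0) -> dict:
    """One Normal draw per region per measure; fractions renormalized."""
    out = {}
    for region, entries in preset.items():
        vals = {}
        for m in MEASURES:
            mean, sd = entries[m]
            v = rng.normal(mean, sd * sd_scale)
            if m == "r_s":
                v = max(v, 0.5)
            else:
                v = min(max(v, 1e-3), 1 - 1e-3)
            vals[m] = v
        tot = vals["f_is"] + vals["f_in"] + vals["f_ec"]
        params = SANDIParams(f_is=vals["f_is"] / tot, f_in=vals["f_in"] / tot,
                             f_ec=vals["f_ec"] / tot, r_s=vals["r_s"],
                             d_in=2.0, d_ec=2.0)
        out[region] = params
    return out


def assign_truth(subject: PhantomSubject, rng: np.random.Generator,
                 jitter_fraction_sd: float = 0.01,
                 jitter_radius_sd: float = 0.05) -> dict:
    """Voxelwise ground-truth parameter fields on the analysis grid.

    Every cortical voxel (GM or lesion partial volume > 0) receives its
    region's subject-level parameter draw plus small within-region jitter;
    fractions are renormalized after jittering.  Returns a dict of 3D
    arrays ``gm_f_is`` .. ``gm_r_s`` and ``lesion_*`` (the per-tissue values
    used by the simulator), and stores it on the subject.
    """
    if subject.masks is None:
        raise ValueError("subject has no region masks; build them first")
    masks = subject.masks
    shape = subject.pv["gm"].shape
    truth = {}
    for tissue in ("gm", "lesion"):
        for m in MEASURES:
            truth[f"{tissue}_{m}"] = np.full(shape, np.nan, dtype=np.float32)

    def fill(target: str, sel: np.ndarray, p: SANDIParams) -> None:
        n = int(sel.sum())
        if n == 0:
            return
        fr = np.stack([
            np.clip(rng.normal(p.f_is, jitter_fraction_sd, n), 1e-3, None),
            np.clip(rng.normal(p.f_in, jitter_fraction_sd, n), 1e-3, None),
            np.clip(rng.normal(p.f_ec, jitter_fraction_sd, n), 1e-3, None)])
        fr /= fr.sum(axis=0)
        truth[f"{target}_f_is"][sel] = fr[0]
        truth[f"{target}_f_in"][sel] = fr[1]
        truth[f"{target}_f_ec"][sel] = fr[2]
        truth[f"{target}_r_s"][sel] = np.clip(
            rng.normal(p.r_s, jitter_radius_sd, n), 0.5, None)

    params = subject.region_params
    gm_here = subject.pv["gm"] > 0
    if "cortex" in params:                      # HC: one region everywhere
        fill("gm", gm_here, params["cortex"])
    else:
        fill("gm", masks.inner & gm_here, params["inner_layer"])
        fill("gm", masks.outer & gm_here, params["outer_layer"])
        fill("gm", masks.na & gm_here, params["na_cortex"])
        # ribbon GM sharing a voxel with the lesion mask behaves like the
        # innermost perilesional tissue
        leftover = gm_here & ~np.isfinite(truth["gm_f_is"])
        fill("gm", leftover, params["inner_layer"])
    if "lesion" in params:
        fill("lesion", subject.pv["lesion"] > 0, params["lesion"])
    subject.truth = truth
    return truth


def _tissue_shell_attenuations(scheme: GradientScheme, f_is, f_in, f_ec, r_s,
                               d_is=3.0, d_in=2.0, d_ec=2.0,
                               n_roots: int = 30) -> np.ndarray:
    """Powder attenuation per shell for arrays of tissue parameters."""
    g = scheme.g_amplitudes()
    shells = scheme.shells
    att = np.empty(np.shape(f_is) + (shells.size,))
    sph = sphere_signal(np.asarray(r_s)[..., None], d_is, g[None, :],
                        scheme.delta, scheme.Delta, scheme.gamma, n_roots=n_roots)
    stk = stick_powder_signal(shells, d_in)
    bal = ball_signal(shells, d_ec)
    att[:] = (np.asarray(f_is)[..., None] * sph
              + np.asarray(f_in)[..., None] * stk[None, :]
              + np.asarray(f_ec)[..., None] * bal[None, :])
    return att


def simulate_dwi(subject: PhantomSubject, scheme: GradientScheme,
                 config: CohortConfig, rng: np.random.Generator,
                 noiseless: bool = False) -> np.ndarray:
    """Simulate the 4D DWI of one subject on the analysis grid.

    Per voxel the noiseless signal is the partial-volume-weighted sum of
    each tissue's powder attenuation, replicated across the directions of
    each shell; b=0 volumes carry the total water content.  Rician noise:
    S' = sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma), sigma = S(b=0)/SNR.
    """
    if subject.truth is None:
        raise ValueError("assign_truth must run before simulate_dwi")
    pv = subject.pv
    shape = pv["gm"].shape
    brain = subject.brain_pv > 0
    vox = np.where(brain)
    n_vox = vox[0].size
    t = subject.truth
    shell_att = np.zeros((n_vox, scheme.n_shells))
    s0 = np.zeros(n_vox)
    # cortical GM and lesion tissue: voxelwise truth parameters
    for tissue in ("gm", "lesion"):
        w = pv[tissue][brain]
        has = w > 0
        if not has.any():
            continue
        f_is = t[f"{tissue}_f_is"][brain][has]
        att = _tissue_shell_attenuations(
            scheme, f_is, t[f"{tissue}_f_in"][brain][has],
            t[f"{tissue}_f_ec"][brain][has], t[f"{tissue}_r_s"][brain][has])
        shell_att[has] += w[has, None] * att
        s0 += np.where(has, w, 0.0)
    # WM: fixed parameters
    w = pv["wm"][brain]
    if np.any(w > 0):
        wm = TISSUE_DEFAULTS["wm"]
        att_wm = _tissue_shell_attenuations(
            scheme, np.array([wm.f_is]), np.array([wm.f_in]),
            np.array([wm.f_ec]), np.array([wm.r_s]),
            d_in=wm.d_in, d_ec=wm.d_ec)[0]
        shell_att += np.outer(w, att_wm)
        s0 += w
    # CSF: free water
    w = pv["csf"][brain]
    att_csf = ball_signal(scheme.shells, TISSUE_DEFAULTS["csf_diffusivity"])
    shell_att += np.outer(w, att_csf)
    s0 += w

    sig = np.empty((n_vox, scheme.n_volumes), dtype=np.float32)
    sig[:, scheme.b0_mask] = s0[:, None]
    for k in range(scheme.n_shells):
        sig[:, scheme.shell_index == k] = shell_att[:, k][:, None]
    if not noiseless:
        sigma = (s0 / config.snr).astype(np.float32)
        e1 = rng.standard_normal(sig.shape).astype(np.float32) * sigma[:, None]
        e2 = rng.standard_normal(sig.shape).astype(np.float32) * sigma[:, None]
        sig = np.sqrt((sig + e1) ** 2 + e2 ** 2)
    dwi = np.zeros(shape + (scheme.n_volumes,), dtype=np.float32)
    dwi[vox] = sig
    subject.dwi = dwi
    return dwi


def generate_cohort(config: CohortConfig | None = None,
                    with_dwi: bool = False,
                    scheme: GradientScheme | None = None) -> tuple[list[PhantomSubject], dict]:
    """Generate the full two-group cohort.

    Returns the subject list and a manifest dict (per-subject seeds, lesion
    burden, demographics).  DWI volumes are memory-hungry, so they are only
    attached when ``with_dwi`` is requested; the pipeline otherwise
    simulates and fits subject by subject.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.master_seed)
    n_total = config.n_ms + config.n_hc
    children = root.spawn(n_total)
    base_geom = make_geometry(config=config.geometry)
    if with_dwi and scheme is None:
        scheme = build_default_scheme()
    subjects, rows = [], []
    for i, child in enumerate(children):
        group = "MS" if i < config.n_ms else "HC"
        rng = np.random.default_rng(child)
        seed_int = int(child.generate_state(1)[0] % (2 ** 31))
        age_mu, age_sd = config.age_ms if group == "MS" else config.age_hc
        age = float(np.clip(rng.normal(age_mu, age_sd), 18.0, 85.0))
        male_p = config.male_frac_ms if group == "MS" else config.male_frac_hc
        sex = "M" if rng.random() < male_p else "F"
        if group == "MS":
            labels, records = sample_lesions(base_geom, config, rng)
            preset = REGION_PRESETS[config.ms_preset]
        else:
            labels, records = base_geom.labels.copy(), []
            preset = REGION_PRESETS[config.hc_preset]
        geom = Geometry(labels, config.geometry)
        pv = geom.partial_volumes()
        region_params = _draw_region_params(preset, rng)
        subj = PhantomSubject(
            subject_id=f"{group.lower()}{i + 1:03d}", group=group, age=age,
            sex=sex, seed=seed_int, labels=labels, pv=pv,
            lesion_records=records, region_params=region_params,
            geometry_config=config.geometry)
        subj.masks = build_shells(pv["lesion"] > 0.25, subj.cortex_pv,
                                  config.geometry.analysis_voxel_mm)
        assign_truth(subj, rng, config.jitter_fraction_sd, config.jitter_radius_sd)
        if with_dwi:
            simulate_dwi(subj, scheme, config, rng)
        subjects.append(subj)
        rows.append({"subject_id": subj.subject_id, "group": group,
                     "age": round(age, 2), "sex": sex, "seed": seed_int,
                     "n_lesions": subj.n_lesions,
                     "lesion_volume_ml": round(subj.total_lesion_volume_ml, 5)})
    manifest = {"master_seed": config.master_seed, "subjects": rows}
    return subjects, manifest


def write_subject(subject: PhantomSubject, scheme: GradientScheme,
                  out_dir: str | Path) -> None:
    """Write one subject's volumes and metadata to disk (NIfTI + sidecars)."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = subject.geometry_config.analysis_voxel_mm
    affine = np.diag([h, h, h, 1.0])
    for name, arr in subject.pv.items():
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine),
                 out / f"pv_{name}.nii.gz")
    nib.save(nib.Nifti1Image(subject.labels.astype(np.int16),
                             np.diag([1.0, 1.0, 1.0, 1.0])),
             out / "labels_1mm.nii.gz")
    if subject.dwi is not None:
        nib.save(nib.Nifti1Image(subject.dwi, affine), out / "dwi.nii.gz")
        write_scheme(scheme, out / "dwi")
    meta = {"subject_id": subject.subject_id, "group": subject.group,
            "age": subject.age, "sex": subject.sex, "seed": subject.seed,
            "n_lesions": subject.n_lesions,
            "lesion_volume_ml": subject.total_lesion_volume_ml}
    with open(out / "subject.json", "w") as fh:
        json.dump(meta, fh, indent=1)
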