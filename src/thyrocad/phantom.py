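"""Synthetic DWI phantom cohorts with planted benign/malignant structure.

Each case is one ellipsoidal nodule embedded in homogeneous background tissue.
The forward signal model is Stejskal–Tanner: ``S_b = S_0 · exp(−b · D)`` with a
voxelwise diffusivity field ``D``.  Class structure is planted twice over:

* malignant nodules have a lower mean diffusivity than benign ones (dense
  cellularity restricts water diffusion);
* spatially correlated texture fields modulate ``S_0`` and ``D`` with
  class-dependent amplitudes *and* correlation lengths — malignant nodules
  carry the larger, finer-grained relative local variation on the T2 (b=0)
  signal, benign nodules the larger and finer variation on the diffusivity
  (hence on every ADC map).  Fine-vs-coarse texture survives the per-sample
  min–max normalization applied downstream, so the planted class contrast
  remains visible to the classifier.

Both the T2 signal and the diffusivity also carry a fixed-amplitude smooth
radial profile, so that per-sample min–max normalization downstream does not
erase the class-dependent texture amplitude: the normalization range is pinned
by the profile, and texture amplitude remains visible relative to it.

A fixed seed makes the whole cohort bit-exact reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    CaseRecord,
    Manifest,
    NoduleMask,
    ValidationError,
    VolumeGrid,
    save_manifest,
    save_mask,
    save_volume,
)

__all__ = ["PhantomParams", "generate_nodule", "generate_cohort"]

NONZERO_B = (500, 1000, 1500)


@dataclass
class PhantomParams:
    """Cohort-level generation parameters (the emulated study conditions).

    Diffusivities are in mm²/s; texture SDs are relative amplitudes (fraction
    of the local mean) of the smoothed Gaussian random fields; ``noise_sd`` is
    the additive signal noise as a fraction of the nodule's base S0 level.
    """

    n_malignant: int = 16
    n_benign: int = 32
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    d_mean_malignant: float = 0.9e-3
    d_mean_benign: float = 1.8e-3
    t2_texture_sd_malignant: float = 0.12
    t2_texture_sd_benign: float = 0.04
    adc_texture_sd_malignant: float = 0.04
    adc_texture_sd_benign: float = 0.12
    t2_texture_corr_malignant: float = 1.2
    t2_texture_corr_benign: float = 3.0
    adc_texture_corr_malignant: float = 3.0
    adc_texture_corr_benign: float = 1.2
    noise_sd: float = 0.02
    noise_model: str = "gaussian"  # or "rician"
    nodule_radius_range: tuple[float, float] = (5.0, 10.0)  # mm, in-plane semi-axes
    s0_base: float = 400.0
    s0_background: float = 150.0
    d_background: float = 1.5e-3
    profile_amplitude_s0: float = 0.4
    profile_amplitude_d: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ValidationError("case counts must be >= 0")
        if min(self.d_mean_malignant, self.d_mean_benign, self.d_background) <= 0:
            raise ValidationError("diffusivities must be > 0")
        sds = (
            self.t2_texture_sd_malignant,
            self.t2_texture_sd_benign,
            self.adc_texture_sd_malignant,
            self.adc_texture_sd_benign,
            self.noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ValidationError("texture/noise SDs must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


def _smooth_field(rng: np.random.Generator, shape, corr_voxels: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian random field."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=corr_voxels, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_nodule(
    params: PhantomParams, label: int, rng: np.random.Generator
) -> tuple[dict[int, VolumeGrid], NoduleMask]:
    """One case: signal volumes at b ∈ {0, 500, 1000, 1500} plus the mask."""
    shape = tuple(params.grid_shape)
    spacing = np.asarray(params.voxel_spacing, float)
    lo, hi = params.nodule_radius_range
    # random ellipsoid semi-axes (mm) and a center keeping the nodule inside
    semi = rng.uniform(lo, hi, size=3)
    semi_vox = semi / spacing
    extent_mm = np.asarray(shape) * spacing
    if np.any(2 * semi >= extent_mm):
        raise ValidationError(f"nodule radius {semi} mm exceeds grid extent {extent_mm} mm")
    center = np.array(
        [rng.uniform(s + 1, n - s - 1) for s, n in zip(semi_vox, shape)]
    )

    ix = np.arange(shape[0])[:, None, None]
    iy = np.arange(shape[1])[None, :, None]
    iz = np.arange(shape[2])[None, None, :]
    r2 = (
        ((ix - center[0]) / semi_vox[0]) ** 2
        + ((iy - center[1]) / semi_vox[1]) ** 2
        + ((iz - center[2]) / semi_vox[2]) ** 2
    )
    inside = r2 <= 1.0
    if inside.sum() < 8:
        raise ValidationError("degenerate nodule: fewer than 8 voxels")
    profile = np.clip(1.0 - r2, 0.0, 1.0)  # 1 at center, 0 at boundary

    if label == 1:
        d_mean = params.d_mean_malignant
        a_t2 = params.t2_texture_sd_malignant
        a_adc = params.adc_texture_sd_malignant
        c_t2 = params.t2_texture_corr_malignant
        c_adc = params.adc_texture_corr_malignant
    else:
        d_mean = params.d_mean_benign
        a_t2 = params.t2_texture_sd_benign
        a_adc = params.adc_texture_sd_benign
        c_t2 = params.t2_texture_corr_benign
        c_adc = params.adc_texture_corr_benign

    g_t2 = _smooth_field(rng, shape, c_t2)
    g_d = _smooth_field(rng, shape, c_adc)

    s0 = np.full(shape, params.s0_background, float)
    s0[inside] = params.s0_base * (
        1.0 + params.profile_amplitude_s0 * profile[inside] + a_t2 * g_t2[inside]
    )
    d = np.full(shape, params.d_background, float)
    d[inside] = d_mean * (
        1.0 + params.profile_amplitude_d * profile[inside] + a_adc * g_d[inside]
    )
    np.clip(s0, 0.0, None, out=s0)
    np.clip(d, 1e-6, None, out=d)

    volumes: dict[int, VolumeGrid] = {}
    sigma = params.noise_sd * params.s0_base
    for b in (0,) + NONZERO_B:
        signal = s0 * np.exp(-b * d)
        if sigma > 0:
            if params.noise_model == "rician":
                re = signal + rng.normal(0.0, sigma, shape)
                im = rng.normal(0.0, sigma, shape)
                signal = np.hypot(re, im)
            else:
                signal = np.clip(signal + rng.normal(0.0, sigma, shape), 0.0, None)
        volumes[b] = VolumeGrid(data=signal, spacing=tuple(spacing))
    mask = NoduleMask(data=inside, spacing=tuple(spacing))
    return volumes, mask


def generate_cohort(params: PhantomParams, out_dir: str | Path) -> Manifest:
    """Write a full phantom cohort (volumes, masks, manifest.csv) to ``out_dir``.

    Case order interleaves nothing: malignant cases first, then benign, with
    ids ``mal##``/``ben##``.  The same seed reproduces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    cases: list[CaseRecord] = []
    specs = [("mal", 1, i) for i in range(params.n_malignant)]
    specs += [("ben", 0, i) for i in range(params.n_benign)]
    for prefix, label, i in specs:
        pid = f"{prefix}{i:03d}"
        volumes, mask = generate_nodule(params, label, rng)
        volume_paths = {}
        for b, grid in volumes.items():
            p = out / f"{pid}_b{b}.nii"  # uncompressed: byte-identical across runs
            save_volume(grid, p)
            volume_paths[b] = p
        mask_path = out / f"{pid}_mask.nii"
        save_mask(mask, mask_path)
        cases.append(
            CaseRecord(patient_id=pid, label=label, volume_paths=volume_paths, mask_path=mask_path)
        )
    manifest = Manifest(cases=cases, provenance=f"thyrocad phantom cohort, seed={params.seed}")
    save_manifest(manifest, out / "manifest.csv")
    _write_params_echo(params, out / "params.yaml")
    return manifest


def _write_params_echo(params: PhantomParams, path: Path) -> None:
    import yaml

    payload = {k: _plain(v) for k, v in vars(params).items()}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def cohort_checksum(out_dir: str | Path) -> str:
    """SHA-256 over the manifest and all volume payloads (determinism checks)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.nii")):
        h.update(p.read_bytes())
    return h.hexdigest()
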