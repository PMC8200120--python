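"""DWI → ADC preprocessing and conversion of raw cases into model samples.

The apparent diffusion coefficient is estimated voxelwise from a pair of
diffusion-weighted acquisitions via the Stejskal–Tanner signal model
``S_b = S_0 · exp(−b · ADC)``, i.e. ``ADC = ln(S_0 / S_b) / b`` in mm²/s.
Three maps (ADC500, ADC1000, ADC1500) are computed against the b=0 reference.

A model sample standardizes the nodule: the in-plane-square bounding box of the
mask is cropped (background zeroed), centred in a fixed 48×48×20 block, and
min–max normalized to [0, 1] over in-mask voxels so the zero padding stays an
exact black background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import CaseRecord, NoduleMask, ValidationError, VolumeGrid, load_mask, load_volume

__all__ = [
    "TARGET_SHAPE",
    "ADCMap",
    "ChannelPlan",
    "NoduleSample",
    "compute_adc",
    "extract_roi",
    "standardize",
    "make_sample",
    "load_case_volumes",
]

logger = logging.getLogger(__name__)

#: Fixed spatial shape of every model input block (x, y, slice).
TARGET_SHAPE = (48, 48, 20)

#: Relative threshold below which signals are treated as empty background.
SIGNAL_EPS_REL = 1e-6


@dataclass
class ADCMap:
    """Voxelwise apparent diffusion coefficient map in mm²/s."""

    values: np.ndarray
    b_target: int
    b_reference: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ChannelPlan:
    """Which modalities feed each network branch.

    ``t2`` / ``adc`` list the channels of the two branches; entries are the
    b-value for raw DWI channels (``0`` = the T2-weighted reference) or
    ``"adc<b>"`` for ADC maps.  ``stacked=True`` collapses everything into a
    single multi-channel input (the single-input ablation).
    """

    t2: tuple = (0,)
    adc: tuple = ("adc500", "adc1000", "adc1500")
    stacked: bool = False

    @classmethod
    def default(cls) -> "ChannelPlan":
        return cls()

    @classmethod
    def t2_only(cls) -> "ChannelPlan":
        return cls(t2=(0,), adc=())

    @classmethod
    def adc_only(cls) -> "ChannelPlan":
        return cls(t2=(), adc=("adc500", "adc1000", "adc1500"))

    @classmethod
    def stacked_single_input(cls) -> "ChannelPlan":
        return cls(t2=(0, "adc500", "adc1000", "adc1500"), adc=(), stacked=True)

    def required_bvalues(self) -> set[int]:
        need = {0}
        for ch in tuple(self.t2) + tuple(self.adc):
            if isinstance(ch, str) and ch.startswith("adc"):
                need.add(int(ch[3:]))
            else:
                need.add(int(ch))
        return need


@dataclass
class NoduleSample:
    """Standardized paired model input: 48×48×20×C blocks in [0, 1]."""

    t2_block: np.ndarray  # (48, 48, 20, C1); C1 may be 0 for ADC-only plans
    adc_block: np.ndarray  # (48, 48, 20, C2)
    label: int
    patient_id: str

    def __post_init__(self) -> None:
        for name, block in (("t2_block", self.t2_block), ("adc_block", self.adc_block)):
            if block.shape[:3] != TARGET_SHAPE:
                raise ValidationError(f"{name} spatial shape {block.shape[:3]} != {TARGET_SHAPE}")
            if block.size and (block.min() < 0 or block.max() > 1):
                raise ValidationError(f"{name} values must lie in [0, 1]")


def compute_adc(s0: VolumeGrid, sb: VolumeGrid, b: float) -> ADCMap:
    """Two-point ADC map ``ln(S0/Sb)/b`` (mm²/s) against the b=0 reference.

    Voxels whose signal is ≤ 1e-6 of the volume maximum in either input are
    set to ADC 0 — these are empty background in practice and would otherwise
    produce ±inf.
    """
    if b <= 0:
        raise ValidationError("reference b-value cannot be the target; b must be > 0")
    a0, ab = np.asarray(s0.data, float), np.asarray(sb.data, float)
    if a0.shape != ab.shape:
        raise ValidationError(f"shape mismatch {a0.shape} vs {ab.shape}")
    if a0.min() < 0 or ab.min() < 0:
        raise ValidationError("signal intensities must be non-negative")
    eps0 = SIGNAL_EPS_REL * max(a0.max(), 1e-300)
    epsb = SIGNAL_EPS_REL * max(ab.max(), 1e-300)
    ok = (a0 > eps0) & (ab > epsb)
    values = np.zeros_like(a0)
    values[ok] = np.log(a0[ok] / ab[ok]) / b
    return ADCMap(values=values, b_target=int(b), spacing=s0.spacing)


def extract_roi(volume: VolumeGrid, mask: NoduleMask) -> VolumeGrid:
    """Crop the in-plane-square bounding box of the mask, zeroing background.

    The square is the smallest one covering the mask's (x, y) extent over all
    slices; the slice axis is cropped to the tight foreground extent.  The
    square is clipped at volume borders if it would overhang.
    """
    if volume.shape != mask.shape:
        raise ValidationError(f"volume {volume.shape} and mask {mask.shape} misaligned")
    m = mask.data
    xs, ys, zs = np.nonzero(m)
    if xs.size == 0:
        raise ValidationError("empty mask")
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    z0, z1 = int(zs.min()), int(zs.max()) + 1
    side = max(x1 - x0, y1 - y0)

    def _grow(lo: int, hi: int, limit: int) -> tuple[int, int]:
        extra = side - (hi - lo)
        lo = max(0, lo - extra // 2)
        hi = min(limit, lo + side)
        lo = max(0, hi - side)
        return lo, hi

    x0, x1 = _grow(x0, x1, volume.shape[0])
    y0, y1 = _grow(y0, y1, volume.shape[1])
    crop = np.where(m, volume.data, 0)[x0:x1, y0:y1, z0:z1]
    return VolumeGrid(data=np.ascontiguousarray(crop, dtype=float), spacing=volume.spacing)


def standardize(crop: VolumeGrid) -> np.ndarray:
    """Centre a masked crop in a 48×48×20 zero block, min–max mapped to [0, 1].

    Normalization statistics come from the non-zero (in-mask) voxels only, so
    the black background is preserved exactly; a constant in-mask intensity
    maps to 1.0.  The in-mask minimum is floored at 1e-6 rather than 0 so the
    nodule support remains distinguishable from background and the operation
    is idempotent.  Crops exceeding the target along any axis are downscaled
    to fit by spline interpolation first (logged as a warning).
    """
    data = np.asarray(crop.data, dtype=float)
    if data.size == 0:
        raise ValidationError("empty crop")
    if any(s > t for s, t in zip(data.shape, TARGET_SHAPE)):
        factors = [min(1.0, t / s) for s, t in zip(data.shape, TARGET_SHAPE)]
        logger.warning("crop %s exceeds %s; downscaling by %s", data.shape, TARGET_SHAPE, factors)
        inmask = data != 0
        data = ndimage.zoom(data, factors, order=1)
        # interpolation can smear mask borders; re-zero sub-threshold background
        data[np.abs(data) < 1e-12] = 0.0
        data = data[: TARGET_SHAPE[0], : TARGET_SHAPE[1], : TARGET_SHAPE[2]]

    inmask = data != 0
    out_vals = np.zeros_like(data)
    if inmask.any():
        vals = data[inmask]
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            out_vals[inmask] = np.maximum((vals - lo) / (hi - lo), 1e-6)
        else:
            out_vals[inmask] = 1.0  # constant-intensity tie rule

    out = np.zeros(TARGET_SHAPE, dtype=np.float32)
    starts = [(t - s) // 2 for s, t in zip(out_vals.shape, TARGET_SHAPE)]
    sl = tuple(slice(st, st + s) for st, s in zip(starts, out_vals.shape))
    out[sl] = out_vals
    return out


def load_case_volumes(case: CaseRecord) -> tuple[dict[int, VolumeGrid], NoduleMask]:
    volumes = {b: load_volume(p) for b, p in case.volume_paths.items()}
    mask = load_mask(case.mask_path)
    return volumes, mask


def make_sample(
    case: CaseRecord,
    channel_plan: ChannelPlan | None = None,
    volumes: dict[int, VolumeGrid] | None = None,
    mask: NoduleMask | None = None,
) -> NoduleSample:
    """Build the standardized two-input sample for one case.

    Each channel (the b=0/T2 image and each ADC map) is ROI-extracted with the
    b=0 mask and standardized independently.  ``volumes``/``mask`` may be
    passed to skip re-reading from disk.
    """
    plan = channel_plan or ChannelPlan.default()
    if volumes is None or mask is None:
        volumes, mask = load_case_volumes(case)
    missing = plan.required_bvalues() - set(volumes)
    if missing:
        raise ValidationError(f"case {case.patient_id}: missing b-values {sorted(missing)}")

    def _channel(ch) -> np.ndarray:
        if isinstance(ch, str) and ch.startswith("adc"):
            b = int(ch[3:])
            grid = VolumeGrid(compute_adc(volumes[0], volumes[b], b).values, volumes[0].spacing)
        else:
            grid = volumes[int(ch)]
        return standardize(extract_roi(grid, mask))

    def _block(channels) -> np.ndarray:
        if not channels:
            return np.zeros(TARGET_SHAPE + (0,), dtype=np.float32)
        return np.stack([_channel(ch) for ch in channels], axis=-1)

    return NoduleSample(
        t2_block=_block(plan.t2),
        adc_block=_block(plan.adc),
        label=case.label,
        patient_id=case.patient_id,
    )
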