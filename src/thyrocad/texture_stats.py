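"""Pixel-level local-intensity-variation statistics between classes.

For every case the slice where the nodule has its biggest area is selected,
high-pass filtered with the rotation-invariant (45°) 3x3 Laplacian kernel,
and the absolute in-mask responses of all cases are pooled into a malignant
and a benign pixel group per modality (T2 and each ADC map).  A Welch
two-sample t-test then quantifies the group mean difference, with a 95%
confidence interval normalized by the benign group's standard deviation
(reportable as a percentage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .io import CaseRecord, NoduleMask, ValidationError, VolumeGrid
from .preprocess import compute_adc, load_case_volumes

__all__ = [
    "LAPLACIAN_KERNEL",
    "WelchResult",
    "largest_slice",
    "laplacian_highpass",
    "case_modality_image",
    "group_pixels",
    "welch_ttest",
    "welch_table",
]

#: 8-connected Laplacian, invariant to 45° rotations; zero-sum.
LAPLACIAN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0],
     [-1.0, 8.0, -1.0],
     [-1.0, -1.0, -1.0]]
)

MODALITIES = ("t2", "adc500", "adc1000", "adc1500")


@dataclass
class WelchResult:
    """Unequal-variance t-test summary for malignant-vs-benign pixel groups.

    ``delta_mean`` and the CI bounds are normalized by the benign group SD
    (unitless; multiply by 100 to report as %).  ``orientation`` names the
    sign convention of the difference.
    """

    t: float
    df: float
    p: float
    delta_mean: float
    ci_low: float
    ci_high: float
    n_malignant: int
    n_benign: int
    orientation: str = "malignant-minus-benign"

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValidationError("Welch degrees of freedom must be > 0")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p-value outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValidationError("CI bounds out of order")


def largest_slice(mask: NoduleMask) -> int:
    """Index of the slice with maximal foreground area (ties -> lowest index)."""
    areas = mask.data.sum(axis=(0, 1))
    if areas.sum() == 0:
        raise ValidationError("empty mask")
    return int(np.argmax(areas))


def laplacian_highpass(image: np.ndarray) -> np.ndarray:
    """Convolve a 2D image with the 8-connected Laplacian (reflect borders)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValidationError(f"need a 2D image of at least 3x3, got {image.shape}")
    return ndimage.convolve(image, LAPLACIAN_KERNEL, mode="reflect")


def case_modality_image(volumes: dict[int, VolumeGrid], modality: str) -> VolumeGrid:
    """The raw T2 (b=0) volume or one of the ADC maps for a loaded case."""
    if modality == "t2":
        return volumes[0]
    if modality.startswith("adc"):
        b = int(modality[3:])
        if b not in volumes:
            raise ValidationError(f"modality {modality!r}: b={b} volume absent")
        adc = compute_adc(volumes[0], volumes[b], b)
        return VolumeGrid(adc.values, volumes[0].spacing)
    raise ValidationError(f"unknown modality {modality!r}")


def group_pixels(
    cases: Sequence[CaseRecord],
    modality: str,
    loaded: Sequence[tuple[dict[int, VolumeGrid], NoduleMask]] | None = None,
    absolute: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool |high-pass| responses of each case's largest slice by class.

    Returns ``(malignant_pixels, benign_pixels)``.  ``absolute=False`` pools
    the raw signed responses instead.
    """
    if not cases:
        raise ValidationError("no cases given")
    groups: dict[int, list[np.ndarray]] = {0: [], 1: []}
    for i, case in enumerate(cases):
        volumes, mask = loaded[i] if loaded is not None else load_case_volumes(case)
        grid = case_modality_image(volumes, modality)
        z = largest_slice(mask)
        response = laplacian_highpass(grid.data[:, :, z])
        if absolute:
            response = np.abs(response)
        groups[case.label].append(response[mask.data[:, :, z]])
    if not groups[0] or not groups[1]:
        raise ValidationError("need at least one case per class")
    return np.concatenate(groups[1]), np.concatenate(groups[0])


def welch_ttest(a: Sequence[float], b: Sequence[float],
                orientation: str = "malignant-minus-benign") -> WelchResult:
    """Welch's unequal-variance t-test of ``a`` (malignant) vs ``b`` (benign).

    The difference of means, its 95% CI and the t statistic follow the
    Welch–Satterthwaite formulation; CI bounds and ``delta_mean`` are divided
    by the benign sample SD.  ``orientation="benign-minus-malignant"`` flips
    the sign of the difference (the convention some reports use).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValidationError("degenerate test: both variances zero, equal means")
        raise ValidationError("degenerate test: both variances zero")
    sa2, sb2 = va / a.size, vb / b.size
    se = np.sqrt(sa2 + sb2)
    diff = a.mean() - b.mean()
    if orientation == "benign-minus-malignant":
        diff = -diff
    elif orientation != "malignant-minus-benign":
        raise ValidationError(f"unknown orientation {orientation!r}")
    t = diff / se
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    sd_ben = np.sqrt(vb)
    if sd_ben == 0:
        raise ValidationError("benign group SD is zero; normalized CI undefined")
    return WelchResult(
        t=float(t),
        df=float(df),
        p=float(min(p, 1.0)),
        delta_mean=float(diff / sd_ben),
        ci_low=float((diff - tcrit * se) / sd_ben),
        ci_high=float((diff + tcrit * se) / sd_ben),
        n_malignant=int(a.size),
        n_benign=int(b.size),
        orientation=orientation,
    )


def welch_table(
    cases: Sequence[CaseRecord],
    modalities: Sequence[str] = MODALITIES,
    loaded: Sequence[tuple[dict[int, VolumeGrid], NoduleMask]] | None = None,
    orientation: str = "malignant-minus-benign",
) -> dict[str, WelchResult]:
    """One Welch result per modality (the per-modality comparison table)."""
    if loaded is None:
        loaded = [load_case_volumes(c) for c in cases]
    table = {}
    for modality in modalities:
        mal, ben = group_pixels(cases, modality, loaded=loaded)
        table[modality] = welch_ttest(mal, ben, orientation=orientation)
    return table
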