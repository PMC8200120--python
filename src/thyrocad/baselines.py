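"""Hand-crafted radiomics features and the classical classifier benchmark.

Three feature families are extracted per case:

* **shape** — nodule size in voxels, convexity ratio (size / convex-hull
  voxel count), bounding-box ratio, and the per-degree spherical-harmonic
  power spectrum of the nodule surface's radial function about its centroid
  (a star-shaped approximation sampled on a latitude–longitude grid);
* **histogram** — mean, SD, entropy (bits, fixed 32-bin partition of [0, 1]),
  skewness and kurtosis of the in-mask intensity distribution, per modality;
* **filterbank** — mean absolute in-mask response to a fixed bank of nine 3x3
  kernels applied slice-wise: Sobel-style edges at 0°/45°/90°/135°,
  second-derivative line detectors at the same orientations, and the
  8-connected Laplacian point kernel.  All nine kernels are zero-sum; the
  four edge kernels are odd-symmetric.

The features feed four classical classifiers (decision tree, random forest,
Gaussian naive Bayes, linear SVM), evaluated with the same leave-one-out fold
structure as the CNN; hyperparameters are selected inside each fold by a
3-fold inner grid search so the held-out case never influences tuning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import Delaunay, QhullError
from scipy.special import sph_harm_y

from .evaluate import CVReport, report_from_probs
from .io import CaseRecord, NoduleMask, ValidationError, VolumeGrid
from .preprocess import load_case_volumes
from .texture_stats import case_modality_image

__all__ = [
    "FeatureVector",
    "FILTER_BANK",
    "shape_features",
    "histogram_features",
    "filterbank_features",
    "extract_features",
    "features_table",
    "fit_classifiers",
    "DEFAULT_GRIDS",
]

SH_MAX_DEGREE = 8
SH_GRID = (32, 64)  # latitude x longitude samples
HIST_BINS = 32
MODALITIES = ("t2", "adc500", "adc1000", "adc1500")


def _build_filter_bank() -> dict[str, np.ndarray]:
    e0 = np.array([[-1.0, -2, -1], [0, 0, 0], [1, 2, 1]])  # edge across rows (x)
    e90 = e0.T.copy()  # edge across columns (y)
    e45 = np.array([[0.0, 1, 2], [-1, 0, 1], [-2, -1, 0]])
    e135 = np.array([[-2.0, -1, 0], [-1, 0, 1], [0, 1, 2]])
    l0 = np.array([[-1.0, -1, -1], [2, 2, 2], [-1, -1, -1]])  # horizontal line
    l90 = l0.T.copy()
    l45 = np.array([[-1.0, -1, 2], [-1, 2, -1], [2, -1, -1]])
    l135 = np.fliplr(l45).copy()
    point = np.array([[-1.0, -1, -1], [-1, 8, -1], [-1, -1, -1]])
    bank = {
        "edge_0": e0, "edge_45": e45, "edge_90": e90, "edge_135": e135,
        "line_0": l0, "line_45": l45, "line_90": l90, "line_135": l135,
        "point": point,
    }
    for name, k in bank.items():
        assert abs(k.sum()) < 1e-12, f"{name} kernel is not zero-sum"
    for name in ("edge_0", "edge_45", "edge_90", "edge_135"):
        k = bank[name]
        assert np.allclose(k[::-1, ::-1], -k), f"{name} kernel is not odd-symmetric"
    return bank


#: The fixed nine-kernel 3x3 texture bank (zero-sum; edges odd-symmetric).
FILTER_BANK = _build_filter_bank()


@dataclass
class FeatureVector:
    """Named scalar features for one case, grouped by family prefix."""

    features: dict[str, float]
    patient_id: str
    label: int

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.features[k] for k in order], dtype=float)


# ---------------------------------------------------------------------------
# Shape features


def _convex_hull_voxels(points: np.ndarray, shape) -> int:
    """Count grid voxels inside the convex hull of the foreground points."""
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValidationError(f"convex hull undefined (degenerate mask): {exc}") from exc
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    grids = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
    box = np.stack([g.ravel() for g in grids], axis=1)
    return int(np.sum(tri.find_simplex(box) >= 0))


def _radial_function(mask: np.ndarray, centroid: np.ndarray,
                     theta: np.ndarray, phi: np.ndarray, step: float = 0.25) -> np.ndarray:
    """First surface crossing along each (theta, phi) ray from the centroid."""
    dirs = np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=-1
    )
    rmax = float(np.linalg.norm(mask.shape)) + 1.0
    radii = np.arange(step, rmax, step)
    # sample the mask along all rays at once (nearest-neighbour lookup)
    pts = centroid[None, None, :] + radii[None, :, None] * dirs[:, None, :]
    idx = np.round(pts).astype(int)
    inside_grid = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=-1)
    vals = np.zeros(idx.shape[:2], dtype=bool)
    ig = np.nonzero(inside_grid)
    vals[ig] = mask[idx[ig][:, 0], idx[ig][:, 1], idx[ig][:, 2]]
    # first index where the ray has left the mask
    left = ~vals
    first_out = np.argmax(left, axis=1)
    all_in = ~left.any(axis=1)
    first_out[all_in] = len(radii) - 1
    return radii[first_out]


def sh_power_spectrum(mask: NoduleMask, max_degree: int = SH_MAX_DEGREE) -> np.ndarray:
    """Per-degree power of the mask surface's radial function (degrees 0..L)."""
    m = mask.data
    centroid = np.array(ndimage.center_of_mass(m))
    nth, nph = SH_GRID
    theta = (np.arange(nth) + 0.5) * np.pi / nth
    phi = (np.arange(nph) + 0.5) * 2 * np.pi / nph
    tg, pg = np.meshgrid(theta, phi, indexing="ij")
    r = _radial_function(m, centroid, tg.ravel(), pg.ravel()).reshape(nth, nph)
    w = np.sin(tg) * (np.pi / nth) * (2 * np.pi / nph)  # quadrature weights
    power = np.zeros(max_degree + 1)
    for l in range(max_degree + 1):
        for mm in range(-l, l + 1):
            y = sph_harm_y(l, mm, tg, pg)
            c = np.sum(r * np.conj(y) * w)
            power[l] += float(np.abs(c) ** 2)
    return power


def shape_features(mask: NoduleMask) -> dict[str, float]:
    """Size, convexity, bounding-box ratio and spherical-harmonic powers."""
    m = mask.data
    size = int(m.sum())
    points = np.argwhere(m)
    extent = points.max(axis=0) - points.min(axis=0) + 1
    bbox = int(np.prod(extent))
    hull = _convex_hull_voxels(points, m.shape)
    feats = {
        "shape_size": float(size),
        "shape_convex_hull_ratio": size / hull,
        "shape_bounding_ratio": size / bbox,
    }
    power = sh_power_spectrum(mask)
    for l, p in enumerate(power):
        feats[f"shape_sh_power_{l}"] = float(p)
    return feats


# ---------------------------------------------------------------------------
# Intensity features


def _normalized_inmask(volume: VolumeGrid, mask: NoduleMask) -> np.ndarray:
    vals = np.asarray(volume.data, float)[mask.data]
    if vals.size == 0:
        raise ValidationError("empty mask")
    lo, hi = vals.min(), vals.max()
    return (vals - lo) / (hi - lo) if hi > lo else np.ones_like(vals)


def histogram_features(volume: VolumeGrid, mask: NoduleMask, prefix: str = "hist") -> dict[str, float]:
    """Mean/SD/entropy/skewness/kurtosis of the in-mask intensity histogram.

    Intensities are min–max normalized over the mask so the entropy's fixed
    32-bin partition of [0, 1] applies; a constant region has SD 0, entropy 0
    and absent (NaN) skewness/kurtosis.
    """
    vals = _normalized_inmask(volume, mask)
    hist, _ = np.histogram(vals, bins=HIST_BINS, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    sd = float(vals.std(ddof=0))
    if sd > 0:
        skew = float(stats.skew(vals))
        kurt = float(stats.kurtosis(vals))
    else:
        skew = kurt = float("nan")  # undefined for a constant region
        entropy = 0.0
    return {
        f"{prefix}_mean": float(vals.mean()),
        f"{prefix}_sd": sd,
        f"{prefix}_entropy": entropy,
        f"{prefix}_skewness": skew,
        f"{prefix}_kurtosis": kurt,
    }


def filterbank_features(volume: VolumeGrid, mask: NoduleMask, prefix: str = "fb") -> dict[str, float]:
    """Mean absolute in-mask response to each of the nine 3x3 kernels."""
    data = np.asarray(volume.data, float)
    m = mask.data
    out = {}
    slices = np.flatnonzero(m.sum(axis=(0, 1)))
    for name, kernel in FILTER_BANK.items():
        acc, cnt = 0.0, 0
        for z in slices:
            resp = ndimage.convolve(data[:, :, z], kernel, mode="reflect")
            sel = m[:, :, z]
            acc += float(np.abs(resp[sel]).sum())
            cnt += int(sel.sum())
        out[f"{prefix}_{name}"] = acc / cnt if cnt else 0.0
    return out


def extract_features(
    case: CaseRecord,
    volumes: dict[int, VolumeGrid] | None = None,
    mask: NoduleMask | None = None,
    modalities: Sequence[str] = MODALITIES,
) -> FeatureVector:
    """All three feature families for one case (intensity families per modality)."""
    if volumes is None or mask is None:
        volumes, mask = load_case_volumes(case)
    feats = dict(shape_features(mask))
    for modality in modalities:
        grid = case_modality_image(volumes, modality)
        feats.update(histogram_features(grid, mask, prefix=f"hist_{modality}"))
        feats.update(filterbank_features(grid, mask, prefix=f"fb_{modality}"))
    return FeatureVector(features=feats, patient_id=case.patient_id, label=case.label)


def features_table(
    cases: Sequence[CaseRecord],
    loaded: Sequence[tuple[dict[int, VolumeGrid], NoduleMask]] | None = None,
    modalities: Sequence[str] = MODALITIES,
) -> pd.DataFrame:
    """One row per case; columns = feature names + patient_id + label."""
    rows = []
    for i, case in enumerate(cases):
        volumes, mask = loaded[i] if loaded is not None else load_case_volumes(case)
        fv = extract_features(case, volumes, mask, modalities)
        rows.append({"patient_id": fv.patient_id, "label": fv.label, **fv.features})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classical classifiers

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "dt": {"clf__min_samples_split": [2, 4, 8]},
    "rf": {"clf__n_estimators": [50, 100], "clf__max_depth": [3, 5, None]},
    "nb": {},
    "svm": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
}


def _make_pipeline(name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    clf = {
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "rf": lambda: RandomForestClassifier(random_state=seed),
        "nb": lambda: GaussianNB(),
        "svm": lambda: SVC(kernel="linear", random_state=seed),
    }[name]()
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _positive_probability(est, X) -> float:
    """Malignancy score in [0, 1]: predict_proba, else squashed margin."""
    if hasattr(est, "predict_proba"):
        return float(est.predict_proba(X)[0, 1])
    margin = float(est.decision_function(X)[0])
    return 1.0 / (1.0 + np.exp(-margin))


def fit_classifiers(
    features: pd.DataFrame,
    grids: Mapping[str, Mapping[str, list]] | None = None,
    seed: int = 0,
    classifiers: Sequence[str] = ("dt", "rf", "nb", "svm"),
) -> dict[str, CVReport]:
    """LOOCV each classical classifier over the feature table.

    Non-finite feature values (undefined higher moments of constant regions)
    are replaced by 0 before fitting.  Hyperparameters are tuned per fold by
    a stratified 3-fold inner grid search (accuracy scoring).
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    grids = dict(DEFAULT_GRIDS) if grids is None else dict(grids)
    feature_cols = [c for c in features.columns if c not in ("patient_id", "label")]
    X = features[feature_cols].to_numpy(dtype=float)
    X[~np.isfinite(X)] = 0.0
    y = features["label"].to_numpy(dtype=int)
    ids = features["patient_id"].astype(str).tolist()
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("LOOCV needs at least 2 cases per class")

    reports: dict[str, CVReport] = {}
    for name in classifiers:
        probs = np.empty(len(y))
        for k in range(len(y)):
            train = np.arange(len(y)) != k
            pipe = _make_pipeline(name, seed)
            grid = grids.get(name, {})
            n_splits = min(3, int((y[train] == 1).sum()), int((y[train] == 0).sum()))
            if grid and n_splits >= 2:
                inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
                search = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", n_jobs=1)
                search.fit(X[train], y[train])
                est = search.best_estimator_
            else:  # too few cases for an inner split: fall back to defaults
                est = pipe.fit(X[train], y[train])
            probs[k] = _positive_probability(est, X[k : k + 1])
        reports[name] = report_from_probs(ids, probs, y)
    return reports
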