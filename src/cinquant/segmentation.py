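"""Nuclei segmentation from the DAPI channel and segment quality filtering.

The segmenter estimates a per-pixel foreground probability from the smoothed
DAPI max-projection (a logistic map centred on an Otsu threshold), binarises at
0.5, then post-processes the mask (hole filling, morphological opening,
minimum-size filtering) before connected-component labelling.  Nuclei are flat,
so segmentation runs on the 2D projection and the resulting labels are
broadcast across z for 3D feature extraction and spot fitting.

Unusable fields are rejected up-front with a Shannon-entropy filter, and
individual segments (debris, unresolved touching nuclei) are discarded by a
gradient-boosted decision-tree classifier over morphological features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu

from .synth import ImageField

log = logging.getLogger(__name__)

FEATURE_NAMES = (
    "volume",
    "equivalent_diameter",
    "extent",
    "axis_major_length",
    "axis_minor_length",
    "convex_volume",
    "solidity",
    "surface_area",
)


# ---------------------------------------------------------------------------
# entropy field filter


def dapi_entropy_bits(dapi: np.ndarray, bin_width: float = 1.0) -> float:
    """Shannon entropy (bits) of the DAPI max-projection intensity histogram.

    Bins have fixed width (default one camera count) so the entropy reflects
    absolute dynamic range: blank/noise-only fields score lower than fields
    containing chromatin.
    """
    if dapi.size == 0:
        raise ValueError("empty image has no entropy")
    proj = dapi.max(axis=0) if dapi.ndim == 3 else np.asarray(dapi, dtype=float)
    lo, hi = float(proj.min()), float(proj.max())
    if hi == lo:
        return 0.0
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    hist, _ = np.histogram(proj, bins=edges)
    p = hist[hist > 0] / hist.sum()
    return float(-(p * np.log2(p)).sum())


def field_passes_entropy_filter(field: ImageField, threshold: float) -> bool:
    """True iff the DAPI channel's histogram entropy is >= ``threshold`` bits."""
    return dapi_entropy_bits(field.dapi) >= threshold


def calibrate_entropy_threshold(
    fields_with_cells, blank_fields
) -> float:
    """Midpoint between the mean entropies of populated and blank fields."""
    e_with = [dapi_entropy_bits(f.dapi) for f in fields_with_cells]
    e_blank = [dapi_entropy_bits(f.dapi) for f in blank_fields]
    return 0.5 * (float(np.mean(e_with)) + float(np.mean(e_blank)))


# ---------------------------------------------------------------------------
# segmentation


def foreground_probability(
    dapi_projection: np.ndarray, smooth_sigma_px: float = 2.0
) -> np.ndarray:
    """Per-pixel nucleus probability in [0, 1], 0.5 at the Otsu threshold."""
    img = np.asarray(dapi_projection, dtype=float)
    smoothed = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return np.zeros_like(smoothed)
    t = threshold_otsu(smoothed)
    med = np.median(smoothed)
    mad_scale = 1.4826 * np.median(np.abs(smoothed - med))
    if t - med < 5.0 * mad_scale:
        # no real foreground: Otsu is just splitting the noise
        return np.zeros_like(smoothed)
    width = max((t - med) / 4.0, 1e-6)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(smoothed - t) / width))


def postprocess_mask(
    binary: np.ndarray, opening_radius: int = 2, min_size: int = 500
) -> np.ndarray:
    """Hole filling -> opening -> minimum-size filter (idempotent)."""
    out = ndimage.binary_fill_holes(binary)
    if opening_radius > 0:
        out = morphology.opening(out, morphology.disk(opening_radius))
        # opening can re-open enclosed background; fill again for idempotence
        out = ndimage.binary_fill_holes(out)
    return morphology.remove_small_objects(out, max_size=min_size - 1)


def segment_nuclei(
    field: ImageField,
    smooth_sigma_px: float = 2.0,
    opening_radius: int = 2,
    min_size: int = 500,
) -> np.ndarray:
    """Label mask of nuclei, shape (nz, ny, nx), 2D labels broadcast across z.

    Probability >= 0.5 is foreground (ties kept).  A blank field yields an
    empty mask.
    """
    proj = field.dapi.max(axis=0)
    prob = foreground_probability(proj, smooth_sigma_px=smooth_sigma_px)
    binary = prob >= 0.5
    binary = postprocess_mask(binary, opening_radius=opening_radius, min_size=min_size)
    labels2d = measure.label(binary, connectivity=2).astype(np.uint16)
    return np.broadcast_to(labels2d, field.dapi.shape).copy()


def touches_field_edge(mask3d: np.ndarray, label: int) -> bool:
    """True if any voxel of ``label`` lies on the xy border (z ignored)."""
    m = mask3d == label
    return bool(
        m[:, 0, :].any() or m[:, -1, :].any() or m[:, :, 0].any() or m[:, :, -1].any()
    )


# ---------------------------------------------------------------------------
# morphological features


def _surface_area(region_mask: np.ndarray) -> float:
    """Exposed voxel faces of the region (exact, in voxel-face units)."""
    m = region_mask.astype(np.int8)
    n = int(m.sum())
    adjacent = 0
    for ax in range(m.ndim):
        sl_a = [slice(None)] * m.ndim
        sl_b = [slice(None)] * m.ndim
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        adjacent += int((m[tuple(sl_a)] & m[tuple(sl_b)]).sum())
    return float(6 * n - 2 * adjacent)


def extract_features(mask3d: np.ndarray, label: int) -> dict[str, float]:
    """Morphological feature vector of one labelled 3D segment.

    All features are in voxel units: ``volume`` (voxel count), the diameter of
    the equal-volume ball, ``extent`` (volume / bounding-box volume),
    principal-axis lengths, convex-hull volume, ``solidity`` and mesh surface
    area.
    """
    if label <= 0 or not (mask3d == label).any():
        raise KeyError(f"label {label} not present in mask")
    props = measure.regionprops((mask3d == label).astype(np.uint8))[0]
    volume = float(props.area)
    region = props.image
    try:
        if volume <= 4:  # too few voxels for a hull
            convex = volume
        elif region.shape[0] > 1 and (region == region[0]).all():
            # z-broadcast prism (2D segmentation): hull = 2D hull extruded
            hull2d = morphology.convex_hull_image(region[0], offset_coordinates=False)
            convex = float(hull2d.sum()) * region.shape[0]
        else:
            hull = morphology.convex_hull_image(region, offset_coordinates=False)
            convex = float(hull.sum())
        convex = max(convex, volume)
        solidity = volume / convex if convex > 0 else 1.0
    except Exception:  # Qhull fails on degenerate (flat/line/point) segments
        convex, solidity = volume, 1.0
    try:
        major = float(props.axis_major_length)
        minor = float(props.axis_minor_length)
    except Exception:
        major = minor = 0.0
    return {
        "volume": volume,
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "extent": float(props.extent),
        "axis_major_length": major,
        "axis_minor_length": minor,
        "convex_volume": convex,
        "solidity": solidity,
        "surface_area": _surface_area(props.image),
    }


def feature_table(mask3d: np.ndarray) -> pd.DataFrame:
    """Features for every label in the mask, one row per segment."""
    labels = np.unique(mask3d)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        row = {"label": int(lab), **extract_features(mask3d, int(lab))}
        row["touches_field_edge"] = touches_field_edge(mask3d, int(lab))
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", *FEATURE_NAMES, "touches_field_edge"])


# ---------------------------------------------------------------------------
# segment classifier


@dataclass
class SegmentClassifier:
    """Keep/discard filter over segment features (gradient-boosted trees)."""

    model: object
    feature_names: tuple[str, ...]
    holdout_accuracy: float

    def predict_keep(self, features) -> np.ndarray:
        X = self._as_frame(features)
        return self.model.predict(X).astype(bool)

    def _as_frame(self, features) -> pd.DataFrame:
        if isinstance(features, pd.DataFrame):
            return features[list(self.feature_names)]
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature vector length mismatch")
        return pd.DataFrame(X, columns=list(self.feature_names))

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "model": self.model,
                "feature_names": self.feature_names,
                "holdout_accuracy": self.holdout_accuracy,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "SegmentClassifier":
        blob = joblib.load(path)
        return cls(
            model=blob["model"],
            feature_names=tuple(blob["feature_names"]),
            holdout_accuracy=blob["holdout_accuracy"],
        )


def train_segment_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> SegmentClassifier:
    """Train the keep/discard classifier; deterministic for a given seed.

    ``labels`` is boolean (True = keep).  Raises on a single-class training
    set.  Held-out accuracy on a seeded split is stored on the classifier.
    """
    import lightgbm as lgb
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = features[list(FEATURE_NAMES)].astype(float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    model = lgb.LGBMClassifier(
        n_estimators=200,
        learning_rate=0.1,
        num_leaves=15,
        min_child_samples=5,
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbosity=-1,
    )
    model.fit(X_tr, y_tr)
    acc = float((model.predict(X_te) == y_te).mean())
    log.info("segment classifier held-out accuracy: %.3f", acc)
    return SegmentClassifier(
        model=model, feature_names=FEATURE_NAMES, holdout_accuracy=acc
    )


def classify_segment(classifier: SegmentClassifier, features) -> bool:
    """True = keep the segment, False = discard."""
    return bool(classifier.predict_keep(features)[0])


@dataclass
class RuleBasedSegmentFilter:
    """Fallback keep/discard rule used when no trained classifier is supplied.

    Keeps segments whose volume sits in a plausible single-nucleus range and
    whose solidity is high (merged doublets and irregular debris fail one of
    the two).
    """

    min_volume: float = 10_000.0
    max_volume: float = 250_000.0
    min_solidity: float = 0.92

    def predict_keep(self, features) -> np.ndarray:
        df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
        return (
            (df["volume"] >= self.min_volume)
            & (df["volume"] <= self.max_volume)
            & (df["solidity"] >= self.min_solidity)
        ).to_numpy()
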