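"""Micronuclei counting on the DAPI max-projection.

Micronuclei (MN) are small DNA-containing bodies near, but separate from,
retained nuclei.  The detector thresholds DAPI-positive pixels outside the
(slightly dilated) nucleus masks, keeps connected components within a
physical size range and within a maximum distance of a retained nucleus, and
reports the count.  Rates are normalised as MN per 100 retained nuclei.
The detector sits behind a small functional interface so a learned counter
could be swapped in.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import ndimage
from skimage import measure, morphology

from ._utils import robust_location_scale
from .synth import ImageField


class MnParams(BaseModel):
    model_config = dict(frozen=True)

    min_area_um2: float = 0.5
    max_area_um2: float = 12.0
    max_distance_um: float = 8.0
    intensity_floor_sd: float = 10.0  # background threshold: median + k * MAD
    exclusion_dilation_px: int = 5  # nucleus rim margin (soft edges bleed out)

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("size range must satisfy 0 < min < max")
        if self.max_distance_um <= 0:
            raise ValueError("max_distance_um must be positive")
        return self


def count_micronuclei_field(
    field: ImageField,
    nuclei_mask: np.ndarray,
    params: MnParams | None = None,
    retained_labels: list[int] | None = None,
    return_centroids: bool = False,
):
    """Count micronuclei in one field; deterministic.

    ``nuclei_mask`` is the (3D or 2D) nucleus label mask from segmentation;
    ``retained_labels`` restricts the "near a retained nucleus" test to
    classifier-retained segments (defaults to all labels).  MN must be
    separated from any nucleus by at least one background pixel (enforced by a
    1-pixel dilation of the nucleus mask).
    """
    params = params or MnParams()
    proj = field.dapi.max(axis=0)
    labels2d = nuclei_mask.max(axis=0) if nuclei_mask.ndim == 3 else nuclei_mask
    if retained_labels is None:
        retained = labels2d > 0
    else:
        retained = np.isin(labels2d, retained_labels)
    any_nucleus = labels2d > 0
    excluded = morphology.dilation(
        any_nucleus, morphology.disk(max(params.exclusion_dilation_px, 1))
    )

    outside = ~excluded
    if outside.sum() < 16:
        return (0, []) if return_centroids else 0
    med, sd = robust_location_scale(proj[outside])
    binary = (proj > med + params.intensity_floor_sd * sd) & outside
    binary = morphology.opening(binary, morphology.disk(1))

    dy, dx = field.spacing[1], field.spacing[2]
    px_area = dy * dx
    if retained.any():
        dist_um = ndimage.distance_transform_edt(~retained, sampling=(dy, dx))
    else:
        dist_um = np.full(proj.shape, np.inf)

    count = 0
    centroids = []
    for region in measure.regionprops(measure.label(binary, connectivity=2)):
        area = region.area * px_area
        if not params.min_area_um2 <= area <= params.max_area_um2:
            continue
        cy, cx = region.centroid
        if dist_um[int(round(cy)), int(round(cx))] > params.max_distance_um:
            continue
        count += 1
        centroids.append((cy, cx))
    return (count, centroids) if return_centroids else count


def save_mn_overlay(field, nuclei_mask, centroids, path) -> None:
    """QC overlay: DAPI max-projection with nucleus outlines and MN circles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = field.dapi.max(axis=0)
    labels2d = nuclei_mask.max(axis=0) if nuclei_mask.ndim == 3 else nuclei_mask
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj, cmap="gray")
    ax.contour(labels2d > 0, levels=[0.5], colors="cyan", linewidths=0.6)
    for cy, cx in centroids:
        ax.add_patch(plt.Circle((cx, cy), 10, fill=False, color="red", lw=1.0))
    ax.set_axis_off()
    ax.set_title(f"{field.field_id}: {len(centroids)} micronuclei")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def mn_per_100_cells(total_mn: int, retained_nuclei: int) -> float:
    """MN rate normalised to 100 retained nuclei."""
    if retained_nuclei <= 0:
        raise ValueError("retained_nuclei must be positive")
    if total_mn < 0:
        raise ValueError("total_mn must be non-negative")
    return 100.0 * total_mn / retained_nuclei
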