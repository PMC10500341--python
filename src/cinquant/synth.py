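"""Synthetic fixed-cell assay generator with per-voxel ground truth.

Emulates fields of flat interphase nuclei imaged in three channels — DAPI
(chromatin), CENP-A (one diffraction-limited centromere spot per chromosome)
and EdU (S-phase marker) — so that every stage of the counting pipeline can be
benchmarked against known truth.  Each nucleus carries ~46 centromeres; a
configurable fraction of centromeres sit in co-located ("superimposed") pairs
that render as a single double-amplitude spot, G2 nuclei carry sister-chromatid
spot pairs closer than the pairing cutoff, and fields additionally contain
micronuclei, debris objects and Poisson + Gaussian camera noise.

Coordinates are in micrometres; voxel ``i`` along an axis with spacing ``s``
is centred at ``(i + 0.5) * s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

CHANNELS = ("dapi", "cenpa", "edu")


class SynthConfig(BaseModel):
    """All knobs of the synthetic assay; defaults define the reference conditions."""

    model_config = dict(frozen=True)

    field_shape: tuple[int, int, int] = (17, 320, 320)
    voxel_size: tuple[float, float, float] = (0.5, 0.1, 0.1)
    n_nuclei: int = 4
    ploidy_distribution: dict[int, float] = Field(default_factory=lambda: {46: 1.0})
    superimposed_fraction: float = 0.1
    s_phase_fraction: float = 0.3
    g2_fraction: float = 0.0
    mn_rate: float = 5.0  # expected micronuclei per 100 nuclei
    detritus_rate: float = 0.0  # expected debris objects per field
    merged_fraction: float = 0.0  # fraction of nuclei placed touching a neighbour
    psf_sigma: tuple[float, float, float] = (0.4, 0.15, 0.15)  # um, (z, y, x)
    amplitude_mean: float = 1000.0
    amplitude_cv: float = 0.1
    background_mean: float = 100.0
    background_sd: float = 10.0
    dapi_amplitude: float = 500.0
    edu_amplitude: float = 500.0
    nucleus_radius_um: float = 4.5  # mean in-plane semi-axis
    nucleus_radius_cv: float = 0.08
    nucleus_z_semiaxis_um: float = 1.6
    spot_min_separation_um: float = 0.9  # 3D floor: keeps G1 spots above pair cutoff
    spot_xy_separation_um: float = 0.45  # in-plane resolvability floor ...
    spot_z_separation_um: float = 1.1  # ... unless z-separated by this much
    pair_separation_um: tuple[float, float] = (0.4, 0.75)
    pair_cutoff_um: float = 0.8
    superimposed_jitter_um: float = 0.0
    mn_radius_um: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    @field_validator("field_shape")
    @classmethod
    def _shape_positive(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("field_shape must be strictly positive")
        return v

    @field_validator("voxel_size", "psf_sigma")
    @classmethod
    def _positive_triplet(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("per-axis sizes must be strictly positive")
        return v

    @field_validator(
        "superimposed_fraction", "s_phase_fraction", "g2_fraction", "merged_fraction"
    )
    @classmethod
    def _fraction(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @field_validator("mn_rate", "detritus_rate")
    @classmethod
    def _rate(cls, v):
        if v < 0:
            raise ValueError("rates must be non-negative")
        return v

    @field_validator("ploidy_distribution")
    @classmethod
    def _ploidy(cls, v):
        if not v:
            raise ValueError("ploidy_distribution must be non-empty")
        if any(k <= 0 for k in v) or any(p < 0 for p in v.values()):
            raise ValueError("ploidy counts must be positive, probabilities >= 0")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("ploidy_distribution probabilities must sum to 1")
        return v

    @model_validator(mode="after")
    def _field_fits_nucleus(self):
        for ax in (1, 2):
            extent = self.field_shape[ax] * self.voxel_size[ax]
            if extent < 2.2 * self.nucleus_radius_um:
                raise ValueError(
                    "field_shape too small to hold one nucleus "
                    f"(xy extent {extent:.1f} um < nucleus diameter)"
                )
        return self

    @property
    def field_extent_um(self) -> np.ndarray:
        return np.asarray(self.field_shape) * np.asarray(self.voxel_size)


@dataclass
class ImageField:
    """Calibrated multichannel 3D stack: channel axis (dapi, cenpa, edu) first."""

    data: np.ndarray  # (3, nz, ny, nx) float32
    spacing: tuple[float, float, float]  # um per axis (z, y, x)
    field_id: str = "field_000"

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNELS):
            raise ValueError("expected data of shape (3, nz, ny, nx)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]

    @property
    def dapi(self) -> np.ndarray:
        return self.channel("dapi")

    @property
    def cenpa(self) -> np.ndarray:
        return self.channel("cenpa")

    @property
    def edu(self) -> np.ndarray:
        return self.channel("edu")


@dataclass
class NucleusTruth:
    label: int
    center_um: np.ndarray  # (3,)
    semi_axes_um: np.ndarray  # (3,)
    theta: float  # in-plane rotation, radians
    centromere_count: int
    s_phase: bool
    g2: bool
    spot_positions_um: np.ndarray  # (n_spots, 3)
    spot_multiplicity: np.ndarray  # (n_spots,) int
    sister_pairs: np.ndarray  # (n_pairs, 2) spot indices
    merged_with: Optional[int] = None  # label of the touching partner, if any


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth]
    nucleus_mask: np.ndarray  # (nz, ny, nx) uint16 labels
    mn_positions_um: np.ndarray  # (n_mn, 3)
    mn_radii_um: np.ndarray  # (n_mn,)
    mn_mask: np.ndarray  # (nz, ny, nx) bool
    detritus_mask: np.ndarray  # (nz, ny, nx) bool

    @property
    def n_micronuclei(self) -> int:
        return len(self.mn_positions_um)

    def validate(self) -> None:
        """Assert the generator's conservation invariants."""
        for nuc in self.nuclei:
            if int(nuc.spot_multiplicity.sum()) != nuc.centromere_count:
                raise AssertionError(
                    f"nucleus {nuc.label}: spot multiplicities do not sum to count"
                )
            for i, j in nuc.sister_pairs:
                d = np.linalg.norm(nuc.spot_positions_um[i] - nuc.spot_positions_um[j])
                if not d < 0.8 + 1e-9:
                    raise AssertionError("sister pair farther than pairing cutoff")

    def to_jsonable(self) -> dict:
        """JSON-serialisable summary (masks are stored separately as TIFF)."""
        return {
            "nuclei": [
                {
                    "label": n.label,
                    "center_um": n.center_um.tolist(),
                    "semi_axes_um": n.semi_axes_um.tolist(),
                    "theta": n.theta,
                    "centromere_count": n.centromere_count,
                    "s_phase": n.s_phase,
                    "g2": n.g2,
                    "spot_positions_um": n.spot_positions_um.tolist(),
                    "spot_multiplicity": n.spot_multiplicity.tolist(),
                    "sister_pairs": n.sister_pairs.tolist(),
                    "merged_with": n.merged_with,
                }
                for n in self.nuclei
            ],
            "mn_positions_um": self.mn_positions_um.tolist(),
            "mn_radii_um": self.mn_radii_um.tolist(),
        }


# ---------------------------------------------------------------------------
# geometry helpers


def _axis_coords(shape, spacing):
    """Per-axis voxel-centre coordinates in um."""
    return [((np.arange(n) + 0.5) * s) for n, s in zip(shape, spacing)]


def _ellipsoid_radius(coords, center, semi_axes, theta):
    """Normalised ellipsoid radius field (1.0 on the surface) on an open grid.

    The ellipsoid is rotated by ``theta`` in the xy plane.
    """
    z, y, x = coords
    dz = (z - center[0])[:, None, None]
    dy = (y - center[1])[None, :, None]
    dx = (x - center[2])[None, None, :]
    ct, st = math.cos(theta), math.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    return np.sqrt(
        (dz / semi_axes[0]) ** 2 + (u / semi_axes[1]) ** 2 + (v / semi_axes[2]) ** 2
    )


def _soft_edge(r, width=0.04):
    """Logistic profile: ~1 inside the unit ellipsoid, ~0 outside."""
    return 1.0 / (1.0 + np.exp((r - 1.0) / width))


def _bbox_slices(center, extent_um, shape, spacing, pad_um=0.6):
    sl = []
    for ax in range(3):
        lo = int(max(0, (center[ax] - extent_um[ax] - pad_um) / spacing[ax]))
        hi = int(min(shape[ax], (center[ax] + extent_um[ax] + pad_um) / spacing[ax] + 1))
        sl.append(slice(lo, max(hi, lo + 1)))
    return tuple(sl)


def _dart_throw(rng, n, sampler, min_sep, max_tries=2000, restarts=20):
    """Rejection-sample ``n`` points with pairwise distance >= min_sep.

    Restarts from scratch when a configuration dead-ends (greedy dart
    throwing can paint itself into a corner at high packing fractions).
    """
    if callable(min_sep):
        ok = min_sep
    else:
        def ok(p, q):
            return np.linalg.norm(p - q) >= min_sep
    for _ in range(restarts):
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n and tries < max_tries:
            p = sampler()
            tries += 1
            if all(ok(p, q) for q in pts):
                pts.append(p)
        if len(pts) == n:
            return np.array(pts)
    raise RuntimeError(f"could not place {n} separated points")


def _sample_in_ellipsoid(rng, center, semi_axes, theta, shrink=1.0):
    """Uniform sample inside the (shrunken) rotated ellipsoid."""
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() <= 1.0:
            break
    local = u * semi_axes * shrink
    ct, st = math.cos(theta), math.sin(theta)
    dy = local[1] * ct - local[2] * st
    dx = local[1] * st + local[2] * ct
    return center + np.array([local[0], dy, dx])


def _render_gaussian(volume, coords, pos, amplitude, sigma, spacing):
    """Add one 3D Gaussian spot in a local +-4 sigma window."""
    sl = _bbox_slices(pos, 4.0 * np.asarray(sigma), volume.shape, spacing, pad_um=0.0)
    z = coords[0][sl[0]][:, None, None]
    y = coords[1][sl[1]][None, :, None]
    x = coords[2][sl[2]][None, None, :]
    g = np.exp(
        -0.5
        * (
            ((z - pos[0]) / sigma[0]) ** 2
            + ((y - pos[1]) / sigma[1]) ** 2
            + ((x - pos[2]) / sigma[2]) ** 2
        )
    )
    volume[sl] += amplitude * g


# ---------------------------------------------------------------------------
# nucleus content


def _resolvable_predicate(config: SynthConfig, scale: float = 1.0):
    """Pairwise separation rule under which two rendered spots stay resolvable.

    Requires a 3D floor (keeps non-sister spots above the 0.8 um pairing
    cutoff) plus either in-plane separation or a large axial separation —
    near-axial pairs otherwise merge, because the PSF is ~2.5x wider in z.
    """
    d3 = scale * config.spot_min_separation_um
    dxy = scale * config.spot_xy_separation_um
    dz = scale * config.spot_z_separation_um

    def ok(p, q):
        delta = p - q
        if np.linalg.norm(delta) < d3:
            return False
        return math.hypot(delta[1], delta[2]) >= dxy or abs(delta[0]) >= dz

    return ok


def _draw_ploidy(rng, config: SynthConfig) -> int:
    counts = np.array(sorted(config.ploidy_distribution))
    probs = np.array([config.ploidy_distribution[int(c)] for c in counts])
    return int(rng.choice(counts, p=probs / probs.sum()))


def _make_g1_spots(rng, config, center, semi_axes, theta):
    """Spot positions/multiplicities for a G1/S nucleus.

    ``superimposed_fraction`` is the fraction of centromeres residing in
    co-located pairs: a nucleus with N centromeres holds D ~ Binomial(N//2, f)
    double-occupancy positions, hence N - D rendered spots.
    """
    n_cen = _draw_ploidy(rng, config)
    n_double = int(rng.binomial(n_cen // 2, config.superimposed_fraction))
    n_pos = n_cen - n_double
    positions = _dart_throw(
        rng,
        n_pos,
        lambda: _sample_in_ellipsoid(rng, center, semi_axes, theta, shrink=0.86),
        _resolvable_predicate(config, scale=1.0),
    )
    mult = np.ones(n_pos, dtype=int)
    if n_double:
        idx = rng.choice(n_pos, size=n_double, replace=False)
        mult[idx] = 2
    return n_cen, positions, mult, np.empty((0, 2), dtype=int)


def _make_g2_spots(rng, config, center, semi_axes, theta):
    """Sister-chromatid pairs: each chromosome renders two nearby spots.

    Anchor (chromosome) positions are kept just far enough apart that greedy
    pairing predominantly matches true sisters; full mutual resolvability of
    92 spots is geometrically impossible in a flat nucleus (and unnecessary —
    the G2 filter only needs a large detected pair count).
    """
    n_chrom = _draw_ploidy(rng, config)
    pair_hi = config.pair_separation_um[1]

    def anchors_ok(p, q):
        delta = p - q
        if np.linalg.norm(delta) < pair_hi + 0.25:
            return False
        return (
            math.hypot(delta[1], delta[2]) >= 1.75 * config.spot_xy_separation_um
            or abs(delta[0]) >= config.spot_z_separation_um
        )

    anchors = _dart_throw(
        rng,
        n_chrom,
        lambda: _sample_in_ellipsoid(rng, center, semi_axes, theta, shrink=0.80),
        anchors_ok,
    )
    lo, hi = config.pair_separation_um
    positions = []
    pairs = []
    for k, a in enumerate(anchors):
        d = rng.uniform(lo, hi)
        direction = rng.normal(size=3)
        direction[0] *= 0.3  # flat nuclei: pairs lie mostly in-plane
        direction /= np.linalg.norm(direction)
        positions.append(a - 0.5 * d * direction)
        positions.append(a + 0.5 * d * direction)
        pairs.append((2 * k, 2 * k + 1))
    return (
        2 * n_chrom,
        np.array(positions),
        np.ones(2 * n_chrom, dtype=int),
        np.array(pairs, dtype=int),
    )


# ---------------------------------------------------------------------------
# field generation


def generate_field(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    field_id: str = "field_000",
) -> tuple[ImageField, GroundTruth]:
    """Render one multichannel field and its ground truth.

    Deterministic for a given config (uses ``config.seed`` when ``rng`` is not
    supplied).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = tuple(config.field_shape)
    spacing = tuple(config.voxel_size)
    coords = _axis_coords(shape, spacing)
    extent = config.field_extent_um

    dapi = np.zeros(shape, dtype=np.float64)
    cenpa = np.zeros(shape, dtype=np.float64)
    edu = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.uint16)
    mn_mask = np.zeros(shape, dtype=bool)
    det_mask = np.zeros(shape, dtype=bool)

    # -- nucleus geometry ---------------------------------------------------
    r_mean = config.nucleus_radius_um
    margin = r_mean * (1 + 3 * config.nucleus_radius_cv) + 0.3
    n_merged = int(round(config.merged_fraction * config.n_nuclei))

    def _xy_center():
        zc = extent[0] / 2 + rng.uniform(-0.8, 0.8)
        yc = rng.uniform(margin, extent[1] - margin)
        xc = rng.uniform(margin, extent[2] - margin)
        return np.array([zc, yc, xc])

    n_primary = config.n_nuclei - n_merged
    try:
        centers = _dart_throw(rng, n_primary, _xy_center, 2.0 * r_mean + 1.2)
    except RuntimeError:
        raise ValueError(
            "field_shape too small to hold the requested number of nuclei"
        ) from None
    centers = list(centers)
    merged_partner: dict[int, int] = {}
    for k in range(n_merged):
        host = int(rng.integers(0, n_primary))
        ang = rng.uniform(0, 2 * math.pi)
        offset = 1.75 * r_mean  # centres closer than 2r: masks touch/overlap
        c = centers[host] + np.array(
            [0.0, offset * math.sin(ang), offset * math.cos(ang)]
        )
        c[1] = np.clip(c[1], margin * 0.6, extent[1] - margin * 0.6)
        c[2] = np.clip(c[2], margin * 0.6, extent[2] - margin * 0.6)
        merged_partner[len(centers)] = host
        centers.append(c)

    n_nuclei = len(centers)
    s_flags = rng.random(n_nuclei) < config.s_phase_fraction
    g2_flags = (~s_flags) & (rng.random(n_nuclei) < config.g2_fraction)

    nuclei: list[NucleusTruth] = []
    for i, center in enumerate(centers):
        axes = np.array(
            [
                config.nucleus_z_semiaxis_um,
                r_mean * (1 + rng.normal(0, config.nucleus_radius_cv)),
                r_mean * (1 + rng.normal(0, config.nucleus_radius_cv)),
            ]
        )
        axes = np.maximum(axes, 0.4 * np.array([config.nucleus_z_semiaxis_um, r_mean, r_mean]))
        if g2_flags[i]:
            axes[1:] *= 1.25  # G2 cells are larger; also makes room for 46 pairs
        theta = rng.uniform(0, math.pi)
        sl = _bbox_slices(center, axes, shape, spacing)
        local = (coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]])
        r = _ellipsoid_radius(local, center, axes, theta)
        dapi[sl] += config.dapi_amplitude * _soft_edge(r)
        inside = r <= 1.0
        region = labels[sl]
        region[inside & (region == 0)] = i + 1
        if s_flags[i]:
            edu[sl] += config.edu_amplitude * _soft_edge(r)

        if g2_flags[i]:
            n_cen, pos, mult, pairs = _make_g2_spots(rng, config, center, axes, theta)
        else:
            n_cen, pos, mult, pairs = _make_g1_spots(rng, config, center, axes, theta)

        psf = np.asarray(config.psf_sigma)
        for p, m in zip(pos, mult):
            for _ in range(int(m)):  # superimposed pairs: two co-located unit spots
                amp = config.amplitude_mean * (1 + rng.normal(0, config.amplitude_cv))
                q = p
                if m > 1 and config.superimposed_jitter_um > 0:
                    q = p + rng.normal(0, config.superimposed_jitter_um, size=3)
                _render_gaussian(cenpa, coords, q, max(amp, 0.0), psf, spacing)

        nuclei.append(
            NucleusTruth(
                label=i + 1,
                center_um=np.asarray(center, dtype=float),
                semi_axes_um=axes,
                theta=theta,
                centromere_count=int(n_cen),
                s_phase=bool(s_flags[i]),
                g2=bool(g2_flags[i]),
                spot_positions_um=pos,
                spot_multiplicity=mult,
                sister_pairs=pairs,
                merged_with=(merged_partner[i] + 1) if i in merged_partner else None,
            )
        )

    # -- micronuclei --------------------------------------------------------
    n_mn = int(rng.poisson(config.mn_rate * n_nuclei / 100.0)) if config.mn_rate else 0
    mn_positions, mn_radii = [], []
    for _ in range(n_mn):
        for _attempt in range(200):
            host = nuclei[int(rng.integers(0, n_nuclei))]
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(*config.mn_radius_um)
            dist = float(max(host.semi_axes_um[1:])) + rng.uniform(1.5, 4.0)
            pos = host.center_um + np.array(
                [rng.uniform(-0.5, 0.5), dist * math.sin(ang), dist * math.cos(ang)]
            )
            if not (
                rad + 0.3 < pos[1] < extent[1] - rad - 0.3
                and rad + 0.3 < pos[2] < extent[2] - rad - 0.3
            ):
                continue
            too_close = any(
                np.linalg.norm((pos - n.center_um)[1:]) < max(n.semi_axes_um[1:]) + rad + 0.5
                for n in nuclei
            ) or any(
                np.linalg.norm(pos - q) < rad + rq + 0.5
                for q, rq in zip(mn_positions, mn_radii)
            )
            if too_close:
                continue
            mn_positions.append(pos)
            mn_radii.append(rad)
            axes = np.array([min(rad, 0.8), rad, rad])
            sl = _bbox_slices(pos, axes, shape, spacing)
            local = (coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]])
            r = _ellipsoid_radius(local, pos, axes, 0.0)
            dapi[sl] += config.dapi_amplitude * _soft_edge(r)
            mn_mask[sl] |= r <= 1.0
            break

    # -- detritus -----------------------------------------------------------
    n_det = int(rng.poisson(config.detritus_rate)) if config.detritus_rate else 0
    for _ in range(n_det):
        for _attempt in range(200):
            pos = np.array(
                [
                    extent[0] / 2 + rng.uniform(-1, 1),
                    rng.uniform(4.0, extent[1] - 4.0),
                    rng.uniform(4.0, extent[2] - 4.0),
                ]
            )
            if any(
                np.linalg.norm((pos - n.center_um)[1:]) < max(n.semi_axes_um[1:]) + 4.0
                for n in nuclei
            ):
                continue
            # irregular blob: union of a few small flat ellipsoids
            for _k in range(int(rng.integers(3, 6))):
                c = pos + np.array([rng.uniform(-0.3, 0.3), *rng.uniform(-1.6, 1.6, 2)])
                axes = np.array([0.7, rng.uniform(0.9, 1.9), rng.uniform(0.5, 1.1)])
                th = rng.uniform(0, math.pi)
                sl = _bbox_slices(c, axes, shape, spacing)
                local = (coords[0][sl[0]], coords[1][sl[1]], coords[2][sl[2]])
                r = _ellipsoid_radius(local, c, axes, th)
                dapi[sl] += 0.9 * config.dapi_amplitude * _soft_edge(r)
                det_mask[sl] |= r <= 1.0
            break

    # -- camera model: Poisson shot noise (Gaussian approximation, valid at
    # the >=100-count background) + additive Gaussian read noise ------------
    signal = np.stack([dapi, cenpa, edu]) + config.background_mean
    np.clip(signal, 0.0, None, out=signal)
    noise_sd = np.sqrt(signal + config.background_sd**2)
    noisy = (signal + rng.standard_normal(signal.shape) * noise_sd).astype(np.float32)

    field = ImageField(data=noisy, spacing=spacing, field_id=field_id)
    truth = GroundTruth(
        nuclei=nuclei,
        nucleus_mask=labels,
        mn_positions_um=np.array(mn_positions).reshape(-1, 3),
        mn_radii_um=np.asarray(mn_radii, dtype=float),
        mn_mask=mn_mask,
        detritus_mask=det_mask,
    )
    truth.validate()
    return field, truth


def generate_fields(
    config: SynthConfig, n_fields: int, seed: int | None = None
) -> list[tuple[ImageField, GroundTruth]]:
    """Generate ``n_fields`` independent fields from one master seed."""
    master = config.seed if seed is None else seed
    streams = np.random.SeedSequence(master).spawn(n_fields)
    return [
        generate_field(config, rng=np.random.default_rng(s), field_id=f"field_{i:03d}")
        for i, s in enumerate(streams)
    ]


# ---------------------------------------------------------------------------
# count-level condition generator (statistics layer input)


def generate_condition(
    config: SynthConfig,
    missegregation_rate: float,
    mn_rate: float | None = None,
    n_nuclei: int = 2000,
    n_replicates: int = 4,
    nuclei_per_field: int = 30,
    condition: str = "condition",
    seed: int | None = None,
):
    """Draw a labelled per-nucleus count table for one experimental condition.

    Each chromosome of a nucleus independently gains or loses one copy with
    probability ``missegregation_rate / 2`` each, so the count distribution
    widens monotonically with the rate while the mode stays at the base
    ploidy.  Per-field micronucleus counts are Poisson with mean
    ``retained * mn_rate / 100``.  Returns a :class:`cinquant.stats.CountTable`.
    """
    from .stats import CountTable

    r = float(missegregation_rate)
    if not 0.0 <= r <= 1.0:
        raise ValueError("mis-segregation rate must lie in [0, 1]")
    if mn_rate is None:
        mn_rate = config.mn_rate
    if mn_rate < 0:
        raise ValueError("mn_rate must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    base = np.array(
        [_draw_ploidy(rng, config) for _ in range(n_nuclei)], dtype=int
    )
    gains = rng.binomial(base, r / 2.0)
    losses = rng.binomial(base, r / 2.0)
    counts = np.clip(base + gains - losses, 0, None)

    replicate = np.repeat(np.arange(n_replicates), math.ceil(n_nuclei / n_replicates))[
        :n_nuclei
    ]
    nuclei_df = pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "nucleus_id": np.arange(n_nuclei),
            "centromere_count": counts,
        }
    )

    rows = []
    fid = 0
    for rep in range(n_replicates):
        n_rep = int((replicate == rep).sum())
        while n_rep > 0:
            retained = min(nuclei_per_field, n_rep)
            n_rep -= retained
            mn = int(rng.poisson(retained * mn_rate / 100.0))
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "field_id": f"field_{fid:04d}",
                    "mn_count": mn,
                    "retained_nuclei": retained,
                }
            )
            fid += 1
    fields_df = pd.DataFrame(rows)
    return CountTable(nuclei=nuclei_df, fields=fields_df)
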