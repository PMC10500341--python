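"""Pipeline orchestration: fixed stage order, configuration and QC accounting.

The processing order is: entropy field filter -> nuclei segmentation ->
segment feature filter (edge exclusion + keep/discard classifier) -> EdU
S-phase filter -> centromere detection/fitting/counting -> sister-pair G2
filter -> micronuclei counting -> statistics.  Every excluded nucleus or field
carries a machine-readable exclusion reason, and the QC report satisfies
``n_input_nuclei == n_retained + sum(per-reason exclusions)`` exactly.
Re-running on identical inputs and config is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from ._utils import child_seed
from .cellcycle import CellCycleParams, g2_filter, segment_mean_edu
from .micronuclei import MnParams, count_micronuclei_field
from .segmentation import (
    RuleBasedSegmentFilter,
    SegmentClassifier,
    feature_table,
    field_passes_entropy_filter,
    segment_nuclei,
)
from .spots import SpotParams, count_centromeres
from .stats import CountTable
from .synth import ImageField, SynthConfig

log = logging.getLogger(__name__)

EXCLUSION_REASONS = ("edge", "classifier", "edu_positive", "g2", "no_spots")


class SegmentationParams(BaseModel):
    model_config = dict(frozen=True)

    entropy_threshold_bits: float = 6.0
    smooth_sigma_px: float = 2.0
    opening_radius: int = 2
    min_size_px: int = 500


class StatsParams(BaseModel):
    model_config = dict(frozen=True)

    n_perm: int = 10_000
    n_boot: int = 1_000
    ci_level: float = 0.95


class PipelineConfig(BaseModel):
    """All stage parameter blocks plus the master seed; JSON round-trippable."""

    model_config = dict(frozen=True)

    synth: SynthConfig = Field(default_factory=SynthConfig)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    cellcycle: CellCycleParams = Field(default_factory=CellCycleParams)
    spots: SpotParams = Field(default_factory=SpotParams)
    micronuclei: MnParams = Field(default_factory=MnParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    seed: int = 0
    classifier_path: Optional[str] = None

    def to_json(self, path=None) -> str:
        text = self.model_dump_json(indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        try:
            return cls.model_validate_json(text)
        except Exception as exc:
            raise ValueError(f"invalid pipeline config: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a JSON or YAML config file."""
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            try:
                return cls.model_validate(yaml.safe_load(path.read_text()))
            except Exception as exc:
                raise ValueError(f"invalid pipeline config {path}: {exc}") from exc
        return cls.from_json(path.read_text())


@dataclass
class FieldResult:
    field_id: str
    passed_entropy: bool
    segments: pd.DataFrame  # label, features, flags, exclusion_reason, count
    spots: pd.DataFrame  # nucleus label, position, amplitude, sigma, multiplicity
    mn_count: int
    retained_nuclei: int

    @property
    def exclusions(self) -> dict[str, int]:
        if self.segments.empty:
            return {r: 0 for r in EXCLUSION_REASONS}
        reasons = self.segments["exclusion_reason"]
        return {r: int((reasons == r).sum()) for r in EXCLUSION_REASONS}


def process_field(
    field: ImageField,
    config: PipelineConfig,
    classifier: SegmentClassifier | RuleBasedSegmentFilter | None = None,
) -> FieldResult:
    """Run every stage on one field."""
    empty_segments = pd.DataFrame(
        columns=["label", "exclusion_reason", "centromere_count"]
    )
    empty_spots = pd.DataFrame(
        columns=[
            "nucleus", "z_um", "y_um", "x_um", "amplitude",
            "sigma_z_um", "sigma_y_um", "sigma_x_um", "multiplicity",
        ]
    )
    if not field_passes_entropy_filter(
        field, config.segmentation.entropy_threshold_bits
    ):
        return FieldResult(
            field_id=field.field_id, passed_entropy=False,
            segments=empty_segments, spots=empty_spots,
            mn_count=0, retained_nuclei=0,
        )

    mask = segment_nuclei(
        field,
        smooth_sigma_px=config.segmentation.smooth_sigma_px,
        opening_radius=config.segmentation.opening_radius,
        min_size=config.segmentation.min_size_px,
    )
    segs = feature_table(mask)
    if segs.empty:
        return FieldResult(
            field_id=field.field_id, passed_entropy=True,
            segments=empty_segments, spots=empty_spots,
            mn_count=0, retained_nuclei=0,
        )

    if classifier is None:
        classifier = RuleBasedSegmentFilter()
    segs["classifier_keep"] = classifier.predict_keep(segs)
    segs["exclusion_reason"] = ""
    segs.loc[~segs["classifier_keep"], "exclusion_reason"] = "classifier"
    segs.loc[segs["touches_field_edge"], "exclusion_reason"] = "edge"

    # EdU filter on surviving segments
    segs["edu_positive"] = False
    for i, row in segs.iterrows():
        if row["exclusion_reason"]:
            continue
        mean_edu = segment_mean_edu(mask, field.edu, int(row["label"]))
        if mean_edu > config.cellcycle.edu_threshold:
            segs.loc[i, "edu_positive"] = True
            segs.loc[i, "exclusion_reason"] = "edu_positive"

    # centromere counting + G2 filter
    spot_rows = []
    segs["centromere_count"] = np.nan
    segs["g2_excluded"] = False
    spacing = field.spacing
    gmm_seed = child_seed(config.seed, f"gmm:{field.field_id}")
    results = {}
    for i, row in segs.iterrows():
        if row["exclusion_reason"]:
            continue
        label = int(row["label"])
        result = count_centromeres(
            field.cenpa, mask == label, spacing, config.spots, seed=gmm_seed
        )
        if result.low_quality and result.count == 0:
            segs.loc[i, "exclusion_reason"] = "no_spots"
            continue
        results[i] = result

    # pooled intensity standard: either globally (gmm_mode="pooled") or as a
    # fallback for nuclei with too few spots for their own mixture model
    pooled_amps = np.array(
        [s.amplitude for r in results.values() for s in r.spots]
    )
    need_pooled = [
        i for i, r in results.items()
        if config.spots.gmm_mode == "pooled"
        or len(r.spots) < config.spots.min_spots_for_gmm
    ]
    if need_pooled and len(pooled_amps) >= config.spots.min_spots_for_gmm:
        from .spots import fit_amplitude_gmm, resolve_multiplicity

        pooled_std = fit_amplitude_gmm(
            pooled_amps, seed=gmm_seed,
            max_components=config.spots.gmm_max_components,
        ).intensity_standard
        for i in need_pooled:
            r = results[i]
            for s in r.spots:
                s.multiplicity = resolve_multiplicity(
                    s.amplitude, pooled_std, config.spots.max_multiplicity
                )
            r.count = int(sum(s.multiplicity for s in r.spots))

    for i, result in results.items():
        positions = np.array([s.position_um for s in result.spots])
        if g2_filter(positions, config.cellcycle):
            segs.loc[i, "g2_excluded"] = True
            segs.loc[i, "exclusion_reason"] = "g2"
            continue
        segs.loc[i, "centromere_count"] = result.count
        label = int(segs.loc[i, "label"])
        for s in result.spots:
            spot_rows.append(
                {
                    "nucleus": label,
                    "z_um": s.position_um[0],
                    "y_um": s.position_um[1],
                    "x_um": s.position_um[2],
                    "amplitude": s.amplitude,
                    "sigma_z_um": s.sigma_um[0],
                    "sigma_y_um": s.sigma_um[1],
                    "sigma_x_um": s.sigma_um[2],
                    "multiplicity": s.multiplicity,
                }
            )

    retained = segs[segs["exclusion_reason"] == ""]
    retained_labels = [int(v) for v in retained["label"]]
    mn = count_micronuclei_field(
        field, mask, config.micronuclei, retained_labels=retained_labels or None
    )
    spots_df = pd.DataFrame(spot_rows) if spot_rows else empty_spots
    return FieldResult(
        field_id=field.field_id,
        passed_entropy=True,
        segments=segs,
        spots=spots_df,
        mn_count=int(mn) if retained_labels else 0,
        retained_nuclei=len(retained_labels),
    )


@dataclass
class QcReport:
    n_fields: int
    n_fields_low_entropy: int
    n_input_nuclei: int
    n_retained: int
    exclusions: dict[str, int]
    version: str = dfield(default_factory=lambda: __version__)

    def validate(self) -> None:
        if self.n_input_nuclei != self.n_retained + sum(self.exclusions.values()):
            raise AssertionError("exclusion accounting does not balance")

    def to_dict(self) -> dict:
        return {
            "n_fields": self.n_fields,
            "n_fields_low_entropy": self.n_fields_low_entropy,
            "n_input_nuclei": self.n_input_nuclei,
            "n_retained": self.n_retained,
            "exclusions": dict(self.exclusions),
            "version": self.version,
        }


def process_fields(
    fields,
    config: PipelineConfig,
    classifier=None,
    condition: str = "condition",
    replicate: int = 0,
) -> tuple[CountTable, pd.DataFrame, QcReport]:
    """Process a sequence of fields into a count table, spot table and QC report."""
    results = [process_field(f, config, classifier) for f in fields]
    nuclei_rows, field_rows, spot_frames = [], [], []
    exclusions = {r: 0 for r in EXCLUSION_REASONS}
    n_input = n_retained = n_low_entropy = 0
    nucleus_id = 0
    for res in results:
        if not res.passed_entropy:
            n_low_entropy += 1
            continue
        n_input += len(res.segments)
        n_retained += res.retained_nuclei
        for r, v in res.exclusions.items():
            exclusions[r] += v
        kept = res.segments[res.segments["exclusion_reason"] == ""]
        for _, row in kept.iterrows():
            nuclei_rows.append(
                {
                    "condition": condition,
                    "replicate": replicate,
                    "nucleus_id": nucleus_id,
                    "field_id": res.field_id,
                    "centromere_count": int(row["centromere_count"]),
                }
            )
            nucleus_id += 1
        if res.retained_nuclei:
            field_rows.append(
                {
                    "condition": condition,
                    "replicate": replicate,
                    "field_id": res.field_id,
                    "mn_count": res.mn_count,
                    "retained_nuclei": res.retained_nuclei,
                }
            )
        if not res.spots.empty:
            frame = res.spots.copy()
            frame.insert(0, "field_id", res.field_id)
            spot_frames.append(frame)
    table = CountTable(
        nuclei=pd.DataFrame(
            nuclei_rows,
            columns=["condition", "replicate", "nucleus_id", "field_id", "centromere_count"],
        ),
        fields=pd.DataFrame(
            field_rows,
            columns=["condition", "replicate", "field_id", "mn_count", "retained_nuclei"],
        ),
    )
    spots_df = (
        pd.concat(spot_frames, ignore_index=True) if spot_frames else pd.DataFrame()
    )
    qc = QcReport(
        n_fields=len(results),
        n_fields_low_entropy=n_low_entropy,
        n_input_nuclei=n_input,
        n_retained=n_retained,
        exclusions=exclusions,
    )
    qc.validate()
    log.info(
        "processed %d fields: %d nuclei in, %d retained, exclusions %s",
        qc.n_fields, qc.n_input_nuclei, qc.n_retained, qc.exclusions,
    )
    return table, spots_df, qc


def process_directory(
    input_dir, config: PipelineConfig, classifier=None, condition: str = "condition"
):
    """Read every ``*.tif`` field in a directory and process it."""
    from .io import read_field_tiff

    paths = sorted(Path(input_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no TIFF fields found in {input_dir}")
    fields = (read_field_tiff(p) for p in paths)
    return process_fields(fields, config, classifier, condition=condition)
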