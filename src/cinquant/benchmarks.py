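"""Ground-truth recovery benchmarks built on the synthetic generator.

These drive the acceptance checks and are also useful for parameter tuning:
each streams freshly generated fields through the relevant pipeline stages and
scores the result against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .micronuclei import MnParams, count_micronuclei_field, mn_per_100_cells
from .segmentation import segment_nuclei
from .spots import SpotParams, count_centromeres
from .synth import SynthConfig, generate_field


def _match_segment(seg_mask, truth_mask, label):
    """Segment label holding the majority of a truth nucleus (0 if none)."""
    overlap = seg_mask[truth_mask == label]
    if overlap.size == 0:
        return 0
    return int(np.bincount(overlap.ravel()).argmax())


def count_recovery_benchmark(
    n_nuclei: int = 500,
    config: SynthConfig | None = None,
    seed: int = 0,
    resolve: bool = True,
    spot_params: SpotParams | None = None,
    use_true_masks: bool = False,
) -> pd.DataFrame:
    """Per-nucleus counted-vs-true centromere counts on synthetic fields.

    Fields are generated and processed one at a time (G1-only conditions:
    S-phase, G2 and debris are disabled so the benchmark isolates the
    counting stage).  ``resolve=False`` disables superimposed-spot
    multiplicity resolution.  Returns columns true/counted/error.
    """
    base = config or SynthConfig()
    cfg = base.model_copy(
        update={"s_phase_fraction": 0.0, "g2_fraction": 0.0, "detritus_rate": 0.0,
                "mn_rate": 0.0}
    )
    streams = np.random.SeedSequence(seed).spawn(max(n_nuclei, 1))
    rows = []
    i_field = 0
    while len(rows) < n_nuclei:
        rng = np.random.default_rng(streams[i_field % len(streams)].spawn(1)[0])
        field, truth = generate_field(cfg, rng=rng, field_id=f"bench_{i_field:04d}")
        seg = (
            truth.nucleus_mask if use_true_masks else segment_nuclei(field)
        )
        for nuc in truth.nuclei:
            if len(rows) >= n_nuclei:
                break
            lab = (
                nuc.label
                if use_true_masks
                else _match_segment(seg, truth.nucleus_mask, nuc.label)
            )
            if lab == 0:
                continue
            res = count_centromeres(
                field.cenpa,
                seg == lab,
                field.spacing,
                spot_params,
                seed=seed + i_field,
                resolve=resolve,
            )
            rows.append(
                {
                    "field": field.field_id,
                    "label": nuc.label,
                    "true": nuc.centromere_count,
                    "counted": res.count,
                    "n_spots": len(res.spots),
                }
            )
        i_field += 1
    df = pd.DataFrame(rows)
    df["error"] = df["counted"] - df["true"]
    return df


@dataclass
class MnBenchmarkResult:
    per_field: pd.DataFrame  # true vs predicted MN count per field
    pearson_r: float
    mae: float
    true_rate: float  # generating MN per 100 nuclei
    estimated_rate: float  # detector MN per 100 retained nuclei


def mn_recovery_benchmark(
    n_fields: int = 200,
    config: SynthConfig | None = None,
    seed: int = 0,
    mn_params: MnParams | None = None,
) -> MnBenchmarkResult:
    """Detector-vs-truth micronuclei counts over synthetic fields."""
    base = config or SynthConfig()
    cfg = base.model_copy(update={"mn_rate": base.mn_rate, "detritus_rate": 0.0})
    streams = np.random.SeedSequence(seed).spawn(n_fields)
    rows = []
    total_mn = 0
    total_nuclei = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        field, truth = generate_field(cfg, rng=rng, field_id=f"mn_{i:04d}")
        seg = segment_nuclei(field)
        pred = count_micronuclei_field(field, seg, mn_params)
        rows.append({"true": truth.n_micronuclei, "predicted": pred})
        total_mn += pred
        total_nuclei += len(truth.nuclei)
    df = pd.DataFrame(rows)
    if df["true"].std() > 0 and df["predicted"].std() > 0:
        r = float(np.corrcoef(df["true"], df["predicted"])[0, 1])
    else:
        r = float("nan")
    return MnBenchmarkResult(
        per_field=df,
        pearson_r=r,
        mae=float((df["predicted"] - df["true"]).abs().mean()),
        true_rate=cfg.mn_rate,
        estimated_rate=mn_per_100_cells(total_mn, total_nuclei),
    )


def make_segment_training_table(
    n_fields: int = 30,
    config: SynthConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled segment features for training the keep/discard classifier.

    Generates fields rich in debris and touching nuclei, segments them, and
    labels each segment from ground truth: ``keep`` is True only for segments
    holding exactly one nucleus and not dominated by debris.
    """
    from .segmentation import feature_table

    base = config or SynthConfig()
    clean = base.model_copy(
        update={"detritus_rate": 0.0, "merged_fraction": 0.0, "mn_rate": 0.0,
                "s_phase_fraction": 0.0, "g2_fraction": 0.0}
    )
    dirty = clean.model_copy(update={"detritus_rate": 2.0, "merged_fraction": 0.5})
    streams = np.random.SeedSequence(seed).spawn(n_fields)
    frames = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        cfg = clean if i % 2 == 0 else dirty
        field, truth = generate_field(cfg, rng=rng, field_id=f"train_{i:04d}")
        seg = segment_nuclei(field)
        feats = feature_table(seg)
        if feats.empty:
            continue
        owners = {
            int(lab): 0 for lab in feats["label"]
        }  # nuclei per segment
        for nuc in truth.nuclei:
            lab = _match_segment(seg, truth.nucleus_mask, nuc.label)
            if lab > 0:
                owners[lab] = owners.get(lab, 0) + 1
        det_frac = {}
        proj_det = truth.detritus_mask.any(axis=0)
        seg2d = seg.max(axis=0)
        for lab in owners:
            sel = seg2d == lab
            det_frac[lab] = float(proj_det[sel].mean()) if sel.any() else 0.0
        feats["n_nuclei"] = feats["label"].map(owners)
        feats["detritus_fraction"] = feats["label"].map(det_frac)
        feats["keep"] = (feats["n_nuclei"] == 1) & (feats["detritus_fraction"] < 0.3)
        frames.append(feats)
    return pd.concat(frames, ignore_index=True)
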