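"""Full analysis chain for one biochip image pair and helpers that build
classifier training data from the simulator.

Order of stages: channel registration -> focus scoring -> artefact
detection -> red-channel segmentation -> per-cell shape QC -> dark-cell
pre-classification (if *every* evaluable cell is dark the image is set to
negative and the discriminant is never invoked) -> orientation + axis
profile -> discriminant cell classification -> image verdict with titer and
confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cells as cells_mod
from . import classify as classify_mod
from . import preprocess
from .io import ChannelPair, RunConfig
from .simulate import SimConfig, simulate_image

log = logging.getLogger("clift")

__all__ = ["PairAnalysis", "analyze_pair", "analyze_sample", "merge_by_sample",
           "build_training_table", "cell_table"]


@dataclass
class PairAnalysis:
    """Everything the pipeline produced for one image pair."""

    image_call: classify_mod.ImageCall
    cell_calls: list = field(default_factory=list)
    qc: preprocess.ImageQC | None = None
    segmentation: preprocess.SegmentationResult | None = None
    records: list = field(default_factory=list)
    profiles: dict = field(default_factory=dict)  # cell_id -> AxisProfile
    short_circuited: bool = False
    background_stats: tuple = (0.0, 0.0)


def _background_stats(green, label_image, artefact_mask):
    bg = (label_image == 0) & ~artefact_mask
    if not bg.any():
        return float(green.mean()), float(green.std())
    vals = green[bg]
    return float(vals.mean()), float(vals.std())


def _reject(pair: ChannelPair, qc, reason: str) -> PairAnalysis:
    call = classify_mod.ImageCall(
        biochip_id=pair.biochip_id,
        sample_id=pair.sample_id,
        dilution_factor=pair.dilution_factor,
        verdict="rejected_qc",
        reject_reason=reason,
    )
    return PairAnalysis(image_call=call, qc=qc)


def analyze_pair(pair: ChannelPair, cfg: RunConfig | None = None,
                 model: classify_mod.TrainedClassifier | None = None) -> PairAnalysis:
    """Run the complete classification chain on one green/red pair."""
    cfg = cfg or RunConfig()
    pair, shift, reg_failed = preprocess.register_pair(pair, cfg)
    qc = preprocess.ImageQC(registration_shift=shift, registration_failed=reg_failed)
    qc.focus_score = preprocess.score_focus(pair.red)
    qc.in_focus = qc.focus_score >= cfg.focus_threshold
    qc.artefact_mask, qc.artefact_area_fraction = preprocess.detect_artefacts(
        pair.red, pair.green, cfg
    )
    if reg_failed:
        return _reject(pair, qc, "registration_failed")
    if not qc.in_focus:
        return _reject(pair, qc, "out_of_focus")
    if qc.artefact_area_fraction > cfg.artefact_area_fraction_max:
        return _reject(pair, qc, "artefact_area")

    seg = preprocess.segment_cells(pair.red, qc.artefact_mask, cfg)
    records = [
        cells_mod.measure_cell(seg.label_image, cid, pair.green, pair.red, cfg)
        for cid in range(1, seg.n_components + 1)
    ]
    areas = [r.area_px for r in records if "too_small" not in r.qc_reasons]
    median_area = float(np.median(areas)) if areas else 0.0
    for rec in records:
        cells_mod.apply_cell_qc(rec, cfg.cell_qc_limits, median_area)

    bg_stats = _background_stats(pair.green, seg.label_image, qc.artefact_mask)
    for rec in records:
        cells_mod.flag_dark_cell(rec, pair.green, bg_stats, cfg.dark_cell_k)

    evaluable = [r for r in records if r.qc_pass]
    analysis = PairAnalysis(
        image_call=None, qc=qc, segmentation=seg, records=records,
        background_stats=bg_stats,
    )

    profiles = {}
    cell_calls = []
    if evaluable and all(r.is_dark for r in evaluable):
        # dark-image short circuit: every cell below the brightness
        # threshold -> negative image, the classifier is never invoked
        log.info(
            "%s: all %d cells dark, image set negative without classification",
            pair.biochip_id, len(evaluable),
        )
        analysis.short_circuited = True
        for rec in records:
            if not rec.qc_pass:
                cell_calls.append(classify_mod.CellCall(rec.cell_id, "excluded"))
            else:
                cell_calls.append(
                    classify_mod.CellCall(rec.cell_id, "negative", posterior=1.0)
                )
    else:
        for rec in records:
            prof = None
            if rec.qc_pass:
                cells_mod.estimate_orientation(rec, pair.red, pair.green, cfg)
            if rec.qc_pass:
                prof = cells_mod.extract_profile(rec, pair.green, cfg)
                profiles[rec.cell_id] = prof
            if model is None:
                # measurement-only mode (training-data generation): no
                # discriminant available, non-dark cells stay unclassified
                if not rec.qc_pass:
                    call = classify_mod.CellCall(rec.cell_id, "excluded")
                else:
                    brightness = classify_mod.extract_kinetoplast_brightness(
                        prof, pair.green, rec, bg_stats[0], cfg
                    )
                    label = "negative" if rec.is_dark else "unclassified"
                    call = classify_mod.CellCall(
                        rec.cell_id, label, kinetoplast_brightness=brightness,
                        posterior=1.0 if rec.is_dark else None,
                    )
                cell_calls.append(call)
            else:
                cell_calls.append(
                    classify_mod.classify_cell(
                        prof, rec, model, bg_stats[0], pair.green, cfg
                    )
                )
    analysis.profiles = profiles
    analysis.cell_calls = cell_calls
    analysis.image_call = classify_mod.classify_image(
        cell_calls, cfg,
        biochip_id=pair.biochip_id, sample_id=pair.sample_id,
        dilution_factor=pair.dilution_factor,
    )
    log.info(
        "%s: %s (%d/%d cells positive, titer %s)",
        pair.biochip_id, analysis.image_call.verdict,
        sum(1 for c in cell_calls if c.label == "positive"),
        analysis.image_call.n_cells_classified,
        analysis.image_call.titer_estimate,
    )
    return analysis


def analyze_sample(pairs, cfg: RunConfig | None = None,
                   model: classify_mod.TrainedClassifier | None = None):
    """Analyze all dilutions of one sample and merge into a SampleResult."""
    cfg = cfg or RunConfig()
    analyses = [analyze_pair(p, cfg, model) for p in pairs]
    result = classify_mod.merge_dilutions([a.image_call for a in analyses], cfg)
    return result, analyses


def merge_by_sample(analyses, cfg: RunConfig | None = None):
    """Group analyzed pairs by sample_id and merge each group's dilutions."""
    cfg = cfg or RunConfig()
    groups: dict[str, list] = {}
    for a in analyses:
        groups.setdefault(a.image_call.sample_id, []).append(a.image_call)
    return [
        classify_mod.merge_dilutions(calls, cfg)
        for _, calls in sorted(groups.items())
    ]


def cell_table(analysis: PairAnalysis, ground_truth=None, match_radius: float = 10.0) -> pd.DataFrame:
    """Flatten one analysis into a per-cell feature table.

    One row per segmented cell: shape scalars, dark flag, kinetoplast
    brightness and the flattened profile (mean block ``pXX`` + sd block
    ``sXX``).  When simulator ground truth is given, each row gains the
    true organelle labels of the nearest ground-truth cell (within
    ``match_radius`` px of the centroid); unmatched rows are dropped.
    """
    rows = []
    gt_centroids = None
    if ground_truth is not None and ground_truth.cells:
        gt_centroids = np.array([c.centroid_rc for c in ground_truth.cells])
    for rec in analysis.records:
        row = {
            "cell_id": rec.cell_id,
            "area_px": rec.area_px,
            "aspect_ratio": rec.aspect_ratio,
            "solidity": rec.solidity,
            "orientation_deg": rec.orientation_deg,
            "qc_pass": rec.qc_pass,
            "qc_reasons": ";".join(rec.qc_reasons),
            "is_dark": rec.is_dark,
            "mean_green": rec.mean_green,
            "mean_red": rec.mean_red,
        }
        prof = analysis.profiles.get(rec.cell_id)
        if prof is not None:
            for i, v in enumerate(prof.values):
                row[f"p{i:02d}"] = v
            for i, v in enumerate(prof.spread):
                row[f"s{i:02d}"] = v
        call = next((c for c in analysis.cell_calls if c.cell_id == rec.cell_id), None)
        if call is not None:
            row["label"] = call.label
            row["kinetoplast_brightness"] = call.kinetoplast_brightness
        if gt_centroids is not None:
            d = np.linalg.norm(gt_centroids - np.array(rec.centroid_rc), axis=1)
            j = int(np.argmin(d))
            if d[j] > match_radius:
                continue
            truth = ground_truth.cells[j]
            row["kinetoplast_fluorescent"] = truth.is_positive
            row["nucleus_fluorescent"] = truth.nucleus_fluorescent
            row["basal_body_fluorescent"] = truth.basal_body_fluorescent
            row["kinetoplast_amplitude"] = truth.organelle_amplitude["kinetoplast"]
        rows.append(row)
    return pd.DataFrame(rows)


def build_training_table(
    n_cells: int,
    run_cfg: RunConfig | None = None,
    sim_cfg: SimConfig | None = None,
    seed: int = 0,
    balanced: bool = True,
) -> pd.DataFrame:
    """Generate a labelled cell-profile training table from the simulator.

    Simulates biochip images, runs the measurement chain (without any
    classifier) and joins the resulting profiles with ground-truth organelle
    labels.  With ``balanced=True`` the table is truncated to equal counts
    of kinetoplast-fluorescent and non-fluorescent cells, ``n_cells`` total.
    """
    run_cfg = run_cfg or RunConfig()
    base = sim_cfg or SimConfig()
    frames = []
    total = {True: 0, False: 0}
    target = n_cells // 2 if balanced else n_cells
    for i in range(1000):
        cfg_i = SimConfig(**{**base.__dict__, "rng_seed": int(seed) * 100_003 + i,
                             "positive_fraction": 0.5 if balanced else base.positive_fraction})
        green, red, gt = simulate_image(cfg_i)
        pair = ChannelPair(green=green, red=red, bit_depth=16, biochip_id=f"train{i}")
        analysis = analyze_pair(pair, run_cfg, model=None)
        if analysis.image_call.verdict == "rejected_qc" and not analysis.records:
            continue
        df = cell_table(analysis, gt)
        if df.empty:
            continue
        df = df[df["qc_pass"]]
        frames.append(df)
        for v, n in df["kinetoplast_fluorescent"].value_counts().items():
            total[bool(v)] = total.get(bool(v), 0) + int(n)
        if balanced and min(total[True], total[False]) >= target:
            break
        if not balanced and sum(total.values()) >= n_cells:
            break
    table = pd.concat(frames, ignore_index=True)
    if balanced:
        pos = table[table["kinetoplast_fluorescent"]].head(target)
        neg = table[~table["kinetoplast_fluorescent"]].head(target)
        table = pd.concat([pos, neg], ignore_index=True)
    else:
        table = table.head(n_cells)
    return table
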