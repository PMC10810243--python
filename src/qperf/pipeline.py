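"""End-to-end cohort pipeline: quantify, resample, threshold, agree.

For every patient the three slices are quantified to pixel-wise MBF maps,
resampled onto the 1800-point bullseye and median-filtered.  When
reference defect masks are available, MBF samples are pooled over the
cohort at four resolutions (pixel, AHA segment, coronary territory,
patient), an ROC/Youden-optimal cut-off is derived at each, and agreement
between the reference defects and the quantified defects (native-
resolution maps thresholded at the pixel-level cut-off) is reported.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from scipy import stats

from . import io
from .analysis import (
    AgreementReport,
    bland_altman,
    dice,
    mann_whitney,
    patient_summary,
    roc_youden,
    segment_mbf,
    segment_positive,
    territory_summary,
    threshold_map,
)
from .bullseye import (
    BullseyeGrid,
    assign_aha,
    burden,
    median_filter_grid,
    sample_bullseye_slice,
)
from .kinetics import quantify_map

log = logging.getLogger("qperf")

SLICE_ORDER = ("basal", "mid", "apical")

__all__ = ["quantify_patient", "run_pipeline", "cohort_thresholds", "cohort_agreement"]


def quantify_patient(slices, aif, config) -> dict:
    """Quantify one patient: maps, AHA labels and the filtered bullseye.

    ``slices`` maps slice label to ``(series, geometry, reference_mask)``
    (mask may be None).  Returns a dict with per-slice maps/labels/masks
    and the median-filtered ``BullseyeGrid``.
    """
    maps, labels, masks, grids = {}, {}, {}, []
    for label in SLICE_ORDER:
        series, geometry, ref_mask = slices[label]
        pmap = quantify_map(
            series, aif, geometry,
            baseline_frame_count=config["baseline_frame_count"],
            noise_floor_factor=config["noise_floor_factor"],
        )
        maps[label] = pmap
        labels[label] = assign_aha(geometry, series.shape)
        masks[label] = ref_mask
        grids.append(
            sample_bullseye_slice(
                pmap, geometry,
                n_layers=config["n_layers"], n_angles=config["n_angles"],
            )
        )
    grid = BullseyeGrid(np.stack(grids))
    filtered = median_filter_grid(grid, size=config["median_filter_size"])
    return {"maps": maps, "labels": labels, "ref_masks": masks,
            "bullseye": grid, "bullseye_filtered": filtered}


def _patient_samples(patient: dict) -> dict:
    """MBF samples with reference labels at the four resolution levels."""
    maps = [patient["maps"][s] for s in SLICE_ORDER]
    labels = [patient["labels"][s] for s in SLICE_ORDER]
    ref = [np.asarray(patient["ref_masks"][s], bool) for s in SLICE_ORDER]

    pixel_v, pixel_y = [], []
    for pmap, mask in zip(maps, ref):
        sel = pmap.valid_mask
        pixel_v.append(pmap.mbf[sel])
        pixel_y.append(mask[sel])
    seg_v = segment_mbf(maps, labels)
    seg_y = segment_positive(ref, labels)
    terr_v, terr_y = territory_summary(seg_v, seg_y)
    pat_v, pat_y = patient_summary(maps, terr_y)
    return {
        "pixel": (np.concatenate(pixel_v), np.concatenate(pixel_y)),
        "segment": (seg_v, seg_y),
        "territory": (terr_v, terr_y),
        "patient": (np.array([pat_v]), np.array([pat_y])),
    }


def cohort_thresholds(patients: list[dict]) -> dict:
    """ROC/Youden cut-offs per resolution level, pooled over the cohort.

    Levels where only one class is present are reported as None.
    """
    pooled = {lvl: ([], []) for lvl in ("pixel", "segment", "territory", "patient")}
    for patient in patients:
        samples = _patient_samples(patient)
        for lvl, (v, y) in samples.items():
            keep = np.isfinite(v)
            pooled[lvl][0].append(np.asarray(v)[keep])
            pooled[lvl][1].append(np.asarray(y)[keep])
    out = {}
    for lvl, (vs, ys) in pooled.items():
        v = np.concatenate(vs)
        y = np.concatenate(ys)
        try:
            out[lvl] = roc_youden(v, y)
        except ValueError as exc:
            log.warning("threshold at %s level skipped: %s", lvl, exc)
            out[lvl] = None
    return out


def cohort_agreement(patients: list[dict], pixel_cutoff: float) -> tuple[AgreementReport, list[dict]]:
    """Agreement between reference and quantified defects over the cohort.

    Quantified defect masks threshold the native-resolution maps at the
    pixel-level cut-off.  Dice is summarised as the cohort median.
    """
    burdens_manual, burdens_quant, dices, rows = [], [], [], []
    inside, outside = [], []
    for patient in patients:
        maps = [patient["maps"][s] for s in SLICE_ORDER]
        ref = [np.asarray(patient["ref_masks"][s], bool) for s in SLICE_ORDER]
        myo = [m.myo_mask for m in maps]
        quant = [
            (threshold_map(m, pixel_cutoff) == 1.0) & m.valid_mask for m in maps
        ]
        bm = burden(ref, myo)
        bq = burden(quant, myo)
        ds = dice(np.concatenate([r.ravel() for r in ref]),
                  np.concatenate([q.ravel() for q in quant]))
        burdens_manual.append(bm)
        burdens_quant.append(bq)
        dices.append(ds)
        rows.append({"burden_manual_pct": bm, "burden_quant_pct": bq, "dice": ds})
        for m, r in zip(maps, ref):
            sel = m.valid_mask
            inside.append(m.mbf[sel & r])
            outside.append(m.mbf[sel & ~r])
    ba = bland_altman(burdens_manual, burdens_quant)
    inside = np.concatenate(inside)
    outside = np.concatenate(outside)
    if inside.size and outside.size:
        u, p = mann_whitney(inside, outside)
    else:
        u, p = float("nan"), float("nan")
    if np.ptp(burdens_manual) > 0 and np.ptp(burdens_quant) > 0:
        r, _ = stats.pearsonr(burdens_manual, burdens_quant)
    else:
        r = float("nan")
    report = AgreementReport(
        dice=float(np.median(dices)),
        pearson_r=float(r),
        mean_bias=ba.mean_bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        prop_beta=ba.prop_beta,
        prop_p=ba.prop_p,
        mannwhitney_u=u,
        mannwhitney_p=p,
    )
    return report, rows


def run_pipeline(manifest, config: dict | None = None, out_dir=None) -> dict:
    """Run the full cohort pipeline from a manifest CSV (or DataFrame).

    Returns the cohort report as a dict; when ``out_dir`` is given, also
    writes per-patient maps and bullseye CSVs, the resolved configuration
    and the JSON report.
    """
    cfg = dict(io.default_config())
    if config:
        cfg.update(config)
    df = io.read_manifest(manifest) if not hasattr(manifest, "groupby") else manifest
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        io.write_config(cfg, out_dir / "config.yaml")

    patients, patient_ids = [], []
    have_masks = True
    for pid, rows in df.groupby("patient_id", sort=True):
        log.info("quantifying patient %s", pid)
        slices = {}
        aif = io.read_aif_csv(rows.iloc[0]["aif_path"])
        for _, row in rows.iterrows():
            series = io.read_series(row["series_path"],
                                    frame_interval=cfg["frame_interval_s"],
                                    slice_label=row["slice_label"])
            geometry = io.read_geometry(row["geometry_path"])
            mask = (io.read_mask(row["reference_mask_path"])
                    if row["reference_mask_path"] else None)
            slices[row["slice_label"]] = (series, geometry, mask)
        patient = quantify_patient(slices, aif, cfg)
        if any(m is None for m in patient["ref_masks"].values()):
            have_masks = False
        patients.append(patient)
        patient_ids.append(pid)
        if out_dir is not None:
            pdir = out_dir / str(pid)
            pdir.mkdir(exist_ok=True)
            for label in SLICE_ORDER:
                io.write_map(patient["maps"][label].mbf, pdir / f"mbf_{label}.nii.gz")
            io.bullseye_to_csv(patient["bullseye_filtered"], pdir / "bullseye.csv")

    report = {
        "n_patients": len(patients),
        "config": cfg,
        "thresholds": None,
        "agreement": None,
        "patients": None,
    }
    if have_masks and patients:
        log.info("deriving thresholds at 4 resolution levels")
        thresholds = cohort_thresholds(patients)
        report["thresholds"] = {
            lvl: (t.as_dict() if t is not None else None)
            for lvl, t in thresholds.items()
        }
        if thresholds["pixel"] is not None:
            agreement, rows = cohort_agreement(patients, thresholds["pixel"].cutoff)
            report["agreement"] = agreement.as_dict()
            report["patients"] = [
                {"patient_id": str(pid), **row}
                for pid, row in zip(patient_ids, rows)
            ]
    else:
        log.info("reference masks absent; thresholding skipped")
    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
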