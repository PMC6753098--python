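"""End-to-end orchestration: phantom -> separation -> registration ->
ROIs -> decade tracking -> cooling dose -> statistics -> report.

One synthetic subject is simulated through a personalized cooling protocol
and analyzed exactly as a real session would be; because the generator's
ground truth is known, the run doubles as a recovery experiment for the
whole measurement chain.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from . import __version__, io
from .config import PipelineConfig
from .cooling import Anthropometrics, sync_logs
from .decades import DecadeTrack, assign_decades, summarize_decades
from .fatwater import (
    FatSpectrum,
    FSFVolume,
    build_echo_schedule,
    compute_fsf_map,
    drop_leading_train_echoes,
    separate_fat_water,
)
from .phantom import (
    GroundTruth,
    LabelVolume,
    apply_motion,
    make_phantom,
    phantom_fiducials,
    phantom_seed_masks,
    simulate_cooling_protocol,
    simulate_cooling_response,
    synthesize_echoes,
)
from .registration import (
    DeformationField,
    FiducialSet,
    RegistrationReport,
    register_nonrigid,
    validate_fiducials,
    warp_fsf,
)
from .segmentation import apply_fsf_threshold, build_roi, erode_once, merge_bilateral
from .stats import spearman_rho

__all__ = ["PipelineResult", "run_pipeline", "derive_seeds"]


def derive_seeds(seed: int, n_acquisitions: int) -> dict:
    """Deterministic per-stage seeds from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    state = ss.generate_state(4 + 2 * n_acquisitions)
    ints = [int(s & 0x7FFFFFFF) for s in state]
    return {
        "phantom": ints[0],
        "protocol": ints[1],
        "response": ints[2],
        "echoes": ints[4 : 4 + n_acquisitions],
        "motion": ints[4 + n_acquisitions : 4 + 2 * n_acquisitions],
    }


@dataclass
class PipelineResult:
    """In-memory record of one end-to-end run."""

    config: PipelineConfig
    seed: int
    labels: LabelVolume
    truth: GroundTruth
    sync: pd.DataFrame
    dose_series: np.ndarray
    sensation_series: np.ndarray
    fsf_true_series: np.ndarray
    fsf_maps: list[FSFVolume]  # registered to acquisition 1
    fields: list[DeformationField | None]
    true_fields: list[DeformationField | None]
    registration_report: RegistrationReport
    bat_mask: np.ndarray
    threshold_masks: dict[str, np.ndarray]
    tracks: dict[str, DecadeTrack]
    decade_summary: pd.DataFrame
    endpoint_table: pd.DataFrame
    threshold_table: pd.DataFrame
    correlations: pd.DataFrame
    endpoint_acquisition: int
    outdir: Path | None = None


def _interp_field(fld: DeformationField, pts: np.ndarray) -> np.ndarray:
    """Field displacement sampled at (slice,row,col) fiducial points."""
    # points are (slice, row, col); arrays index (row, col, slice)
    coords = np.stack([pts[:, 1], pts[:, 2], pts[:, 0]])
    out = np.empty((pts.shape[0], 3))
    for a in range(3):
        out[:, a] = map_coordinates(fld.disp[..., a], coords, order=1, mode="nearest")
    return out


def _fiducials_after(
    fixed_pts: np.ndarray, before_pts: np.ndarray, fld: DeformationField
) -> np.ndarray:
    """Fiducial positions in the registered image.

    The registered image is moving(x + v(x)); a landmark sitting at
    ``before`` in the moving frame appears at the x solving
    ``x + v(x) = before`` (fixed-point iteration).
    """
    x = fixed_pts.copy()
    for _ in range(10):
        d = _interp_field(fld, x)
        # displacement in (row, col, slice) array order -> point order
        x = before_pts - d[:, [2, 0, 1]]
    return x


def _threshold_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}"


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on one synthetic subject.

    All randomness derives from ``seed``.  If ``outdir`` is given, tidy CSV
    tables, a JSON run manifest and summary plots are written there.
    """
    cfg = config or PipelineConfig()
    seeds = derive_seeds(seed, cfg.n_acquisitions)
    spectrum = FatSpectrum.seven_peak_3t()
    schedule = build_echo_schedule()

    # --- cooling protocol and dose bookkeeping -------------------------
    starts_min = np.arange(cfg.n_acquisitions) * cfg.acquisition_interval_s / 60.0
    duration = cfg.lead_in_min + starts_min[-1] + cfg.scan_duration_s / 60.0 + 2.0
    profile, sensation_log = simulate_cooling_protocol(
        cfg.shiver_threshold_c,
        cfg.thermoneutral_c,
        duration_min=duration,
        seed=seeds["protocol"],
        lead_in_min=cfg.lead_in_min,
    )
    anthro = Anthropometrics(cfg.mass_kg, cfg.height_cm)
    sync = sync_logs(
        profile, sensation_log, starts_min, anthro.bsa_m2, cfg.scan_duration_s
    )
    # truth is driven by the programmed (set) temperatures: exactly zero
    # during the thermoneutral lead-in and nondecreasing afterwards
    sync_set = sync_logs(
        profile,
        sensation_log,
        starts_min,
        anthro.bsa_m2,
        cfg.scan_duration_s,
        use_actual=False,
    )
    dose_true = sync_set["cum_norm_dose"].to_numpy()
    dose_series = sync["cum_norm_dose"].to_numpy()
    sensation_series = sync["sensation"].to_numpy()

    endpoint = cfg.endpoint_acquisition
    if endpoint > cfg.n_acquisitions:
        warnings.warn(
            f"endpoint acquisition {endpoint} beyond series of "
            f"{cfg.n_acquisitions}; using the last acquisition",
            stacklevel=2,
        )
        endpoint = cfg.n_acquisitions

    # --- phantom, calibrated to this protocol's endpoint dose ----------
    ph_cfg = replace(cfg.phantom, full_protocol_dose=float(dose_true[endpoint - 1]))
    labels, truth = make_phantom(ph_cfg, seed=seeds["phantom"])
    fsf_true_series = simulate_cooling_response(
        truth, dose_true, noise_sd=cfg.fsf_noise_sd, seed=seeds["response"]
    )

    # --- acquisition, separation, registration -------------------------
    amp = ph_cfg.signal_amplitude * (labels.labels > 0)
    noise_sd = ph_cfg.signal_amplitude / cfg.snr
    te_first_ret_s = schedule.te_ms[schedule.n_trains] * 1e-3
    fsf_maps: list[FSFVolume] = []
    fields: list[DeformationField | None] = []
    true_fields: list[DeformationField | None] = []
    water_ref = None
    for k in range(cfg.n_acquisitions):
        series = synthesize_echoes(
            fsf_true_series[k],
            spectrum,
            truth.field_map_hz,
            truth.r2star,
            schedule,
            noise_sd=noise_sd,
            seed=seeds["echoes"][k],
            amplitude=amp,
            acquisition_index=k + 1,
            timestamp_s=starts_min[k] * 60.0,
        )
        if k == 0:
            true_fields.append(None)
        else:
            series, tf = apply_motion(series, cfg.motion, seed=seeds["motion"][k])
            true_fields.append(tf)
        series = drop_leading_train_echoes(series)
        sep = separate_fat_water(series, spectrum, cfg.separation)
        fsf_k = compute_fsf_map(sep, cfg.background_threshold_frac)
        water_k = sep.water * np.exp(-sep.r2star * te_first_ret_s)
        if k == 0:
            water_ref = water_k
            fields.append(None)
            fsf_maps.append(fsf_k)
        else:
            fld = register_nonrigid(water_ref, water_k, cfg.registration)
            fields.append(fld)
            fsf_maps.append(warp_fsf(fsf_k, fld))

    # --- fiducial validation on the final cold-exposure acquisition ----
    fids = phantom_fiducials(labels)
    before_pts = fids.points + _interp_field(true_fields[-1], fids.points)[:, [2, 0, 1]]
    after_pts = _fiducials_after(fids.points, before_pts, fields[-1])
    report = validate_fiducials(
        fids,
        FiducialSet(before_pts, fids.labels),
        FiducialSet(after_pts, fids.labels),
    )

    # --- ROIs on the thermoneutral map ---------------------------------
    fsf_tn = fsf_maps[0]
    seeds_masks = phantom_seed_masks(labels)
    roi = build_roi(
        fsf_tn,
        seeds_masks,
        display_window=cfg.display_window,
        slice_range=cfg.slice_range,
    )
    bat = erode_once(merge_bilateral(roi.masks["bat_left"], roi.masks["bat_right"]))
    sat = erode_once(roi.masks["sat"])
    muscle = erode_once(roi.masks["muscle"])
    threshold_masks = {
        _threshold_label(lo, hi): apply_fsf_threshold(fsf_tn, bat, lo, hi)
        for lo, hi in cfg.fsf_thresholds
    }

    # --- decade tracking and summaries ---------------------------------
    tracks = {
        "bat": assign_decades(fsf_tn, bat),
        "sat": assign_decades(fsf_tn, sat),
        "muscle": assign_decades(fsf_tn, muscle),
    }
    summaries = [
        summarize_decades(
            tracks[t],
            fsf_maps,
            dose_series,
            sensation_series,
            min_voxels=cfg.min_decade_voxels,
            tissue=t,
        )
        for t in ("bat", "sat", "muscle")
    ]
    decade_summary = pd.concat(summaries, ignore_index=True)

    ep = decade_summary[decade_summary.acquisition == endpoint]
    tn = decade_summary[decade_summary.acquisition == 1]
    endpoint_table = tn.merge(
        ep[["tissue", "decade", "mean_fsf"]],
        on=["tissue", "decade"],
        suffixes=("_tn", "_ce"),
    )[["tissue", "decade", "n_voxels", "mean_fsf_tn", "mean_fsf_ce"]]
    endpoint_table["change"] = (
        endpoint_table["mean_fsf_ce"] - endpoint_table["mean_fsf_tn"]
    )

    rows = []
    for name, m in threshold_masks.items():
        idx = np.flatnonzero(m.ravel())
        means = []
        for t in (0, endpoint - 1):
            flat, fv = fsf_maps[t].fsf.ravel(), fsf_maps[t].valid.ravel()
            ok = fv[idx]
            means.append(float(flat[idx][ok].mean()))
        rows.append(
            {
                "threshold": name,
                "n_voxels": int(m.sum()),
                "mean_fsf_tn": means[0],
                "mean_fsf_ce": means[1],
                "change": means[1] - means[0],
            }
        )
    threshold_table = pd.DataFrame(rows)

    corr_rows = []
    bat_summary = decade_summary[decade_summary.tissue == "bat"]
    for d in sorted(bat_summary.decade.unique()):
        sub = bat_summary[bat_summary.decade == d].sort_values("acquisition")
        try:
            r_dose = spearman_rho(sub.mean_fsf.to_numpy(), sub.norm_dose.to_numpy())
            r_sens = spearman_rho(sub.mean_fsf.to_numpy(), sub.sensation.to_numpy())
        except ValueError:
            continue
        corr_rows.append(
            {
                "decade": d,
                "n": len(sub),
                "rho_dose": r_dose.statistic,
                "p_dose": r_dose.pvalue,
                "rho_sensation": r_sens.statistic,
                "p_sensation": r_sens.pvalue,
            }
        )
    correlations = pd.DataFrame(corr_rows)

    result = PipelineResult(
        config=cfg,
        seed=seed,
        labels=labels,
        truth=truth,
        sync=sync,
        dose_series=dose_series,
        sensation_series=sensation_series,
        fsf_true_series=fsf_true_series,
        fsf_maps=fsf_maps,
        fields=fields,
        true_fields=true_fields,
        registration_report=report,
        bat_mask=bat,
        threshold_masks=threshold_masks,
        tracks=tracks,
        decade_summary=decade_summary,
        endpoint_table=endpoint_table,
        threshold_table=threshold_table,
        correlations=correlations,
        endpoint_acquisition=endpoint,
    )
    if outdir is not None:
        result.outdir = _write_report(result, Path(outdir), seeds)
    return result


def _write_report(result: PipelineResult, outdir: Path, seeds: dict) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    tables = {
        "decade_summary.csv": result.decade_summary,
        "endpoint_decades.csv": result.endpoint_table,
        "threshold_comparison.csv": result.threshold_table,
        "correlations.csv": result.correlations,
        "cooling_sync.csv": result.sync,
    }
    reg = pd.DataFrame(
        {
            "label": list(result.registration_report.labels),
            "distance_before_px": result.registration_report.distance_before,
            "distance_after_px": result.registration_report.distance_after,
        }
    )
    tables["registration_report.csv"] = reg
    for name, df in tables.items():
        df.to_csv(outdir / name, index=False)
    if cfg.write_nifti:
        vox = cfg.phantom.voxel_size_mm
        for k, fsf in enumerate(result.fsf_maps):
            io.write_fsf(fsf, outdir / f"fsf_acq{k + 1:02d}.nii.gz", vox)
    if cfg.make_plots:
        _make_plots(result, outdir)
    import scipy
    import SimpleITK as sitk

    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "SimpleITK": sitk.__version__,
        },
        "seed": result.seed,
        "derived_seeds": seeds,
        "endpoint_acquisition": result.endpoint_acquisition,
        "config": _jsonable(cfg.to_dict()),
        "outputs": {name: io.sha256_file(outdir / name) for name in tables},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _make_plots(result: PipelineResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = outdir / "plots"
    plots.mkdir(exist_ok=True)

    # threshold comparison (thermoneutral vs cold exposure)
    tt = result.threshold_table
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(len(tt))
    ax.bar(x - 0.18, tt.mean_fsf_tn, width=0.36, label="thermoneutral", color="#c44")
    ax.bar(x + 0.18, tt.mean_fsf_ce, width=0.36, label="cold exposure", color="#47c")
    ax.set_xticks(x, tt.threshold)
    ax.set_ylabel("mean BAT FSF (%)")
    ax.set_xlabel("FSF threshold (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(plots / "threshold_comparison.png", dpi=110)
    plt.close(fig)

    # per-decade endpoint comparison, BAT
    ep = result.endpoint_table[result.endpoint_table.tissue == "bat"]
    fig, ax = plt.subplots(figsize=(5.5, 3.2))
    x = np.arange(len(ep))
    ax.bar(x - 0.18, ep.mean_fsf_tn, width=0.36, label="thermoneutral", color="#c44")
    ax.bar(x + 0.18, ep.mean_fsf_ce, width=0.36, label="cold exposure", color="#47c")
    ax.set_xticks(x, [f"{d}" for d in ep.decade])
    ax.set_xlabel("FSF decade (%)")
    ax.set_ylabel("mean FSF (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(plots / "decade_endpoint.png", dpi=110)
    plt.close(fig)

    # decade trajectories vs dose and vs sensation
    bat = result.decade_summary[result.decade_summary.tissue == "bat"]
    for xcol, fname, xlabel in (
        ("norm_dose", "decade_vs_dose.png", "normalized cooling dose (degC*min*m$^{-2}$)"),
        ("sensation", "decade_vs_sensation.png", "thermal sensation (0=V.Cold, 50=Neutral)"),
    ):
        fig, ax = plt.subplots(figsize=(5.5, 3.6))
        for d, sub in bat.groupby("decade"):
            sub = sub.sort_values("acquisition")
            ax.plot(sub[xcol], sub.mean_fsf, marker=".", ms=4, lw=1, label=f"{d}%")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("mean FSF (%)")
        ax.legend(frameon=False, fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(plots / fname, dpi=110)
        plt.close(fig)
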