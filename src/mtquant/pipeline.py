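"""End-to-end workflows tying the stages together.

These are the programmatic equivalents of the CLI verbs: soma-calibrated
STED counting, dendrite-intrinsic FlipExM counting, radial profiling with
decomposition, and scene simulation.  Every workflow is deterministic
given the scene seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mtquant import counting, filaments, flipexm, radial
from mtquant.rois import PolylineRoi
from mtquant.simgen import SceneSpec, simulate_scene
from mtquant.stack import ChannelStack
from mtquant.stackio import ReslicedStack

log = logging.getLogger("mtquant")

#: detection threshold strategy per channel; detection is permissive
#: (background/foreground split) — crosstalk-dim filaments detected in the
#: tyr/ac channels are removed later at the segment level
#: (:func:`mtquant.filaments.select_native_singles`).
DETECTION_METHODS = {"total": "otsu", "tyr": "otsu", "ac": "otsu"}


@dataclass
class CalibrationResult:
    fit: filaments.SingleIntensityFit
    crosstalk: filaments.CrosstalkCoefficients
    n_detected: dict[str, int]
    n_singles: dict[str, int]
    #: median rasterized tube area per pixel of segment length; the
    #: centre-distance rule makes a nominal 6-px tube slightly wider, so
    #: dendrite intensities are normalized by this measured width to stay
    #: commensurate with the single-filament intensities
    effective_width: float = 6.0


def soma_calibration(
    stack: ChannelStack,
    z_range: tuple[int, int] | None = None,
    line_width: float = 2.5,
    min_length_um: float = 0.6,
    w_microtubule: float = 6.0,
    w_wide: float = 13.0,
    detection_methods: dict[str, str] | None = None,
    mask: PolylineRoi | None = None,
) -> CalibrationResult:
    """Soma-stage calibration: detection, measurement, fit, crosstalk."""
    methods = detection_methods or DETECTION_METHODS
    if z_range is None:
        z_range = (0, stack.shape[0])
    mips, sums = filaments.select_substack(stack, z_range)
    pixel_size = stack.voxel_size[0] / stack.expansion_factor

    measured_by_channel: dict[str, list[filaments.SegmentIntensity]] = {}
    n_detected = {}
    for ch in stack.channel_names:
        segs = filaments.detect_segments(
            mips[ch],
            pixel_size=pixel_size,
            line_width=line_width,
            min_length_um=min_length_um,
            mask=mask,
            detection_channel=ch,
            threshold_method=methods.get(ch, "otsu"),
        )
        n_detected[ch] = len(segs)
        measured, n_excl = filaments.measure_segments(
            sums, segs, w_microtubule, w_wide
        )
        if n_excl:
            log.info("channel %s: %d border segments excluded", ch, n_excl)
        measured_by_channel[ch] = measured

    pooled = np.array([
        m.i_segm("total")
        for ms in measured_by_channel.values()
        for m in ms
    ])
    fit = filaments.fit_single_intensity(pooled)

    singles_by_channel = {}
    n_singles = {}
    for ch, ms in measured_by_channel.items():
        kept, _ = filaments.filter_singles(ms, fit)
        if ch in ("tyr", "ac"):
            kept = filaments.select_native_singles(kept, ch)
        singles_by_channel[ch] = kept
        n_singles[ch] = len(kept)
    crosstalk = filaments.estimate_crosstalk(singles_by_channel)
    # slope of S_mid vs segment length, so the round end caps (a fixed
    # per-segment offset) do not inflate the width estimate
    lengths = np.array([
        m.segment.length_um / pixel_size
        for ms in measured_by_channel.values()
        for m in ms
    ])
    areas = np.array([
        m.channels["total"].S_mid
        for ms in measured_by_channel.values()
        for m in ms
    ])
    if len(lengths) >= 5 and np.ptp(lengths) > 0:
        effective_width = float(np.polyfit(lengths, areas, 1)[0])
    else:
        effective_width = w_microtubule
    return CalibrationResult(
        fit=fit,
        crosstalk=crosstalk,
        n_detected=n_detected,
        n_singles=n_singles,
        effective_width=effective_width,
    )


def auto_dendrite_line(
    stack: ChannelStack, length_um: float = 2.5
) -> tuple[PolylineRoi, float]:
    """Axis-parallel line ROI through a straight synthetic dendrite.

    Returns the line and a band width (pixels) wide enough to cover the
    dendrite's lateral extent, both derived from the total-channel sum
    image (centre of mass and intensity spread).
    """
    total = stack.channel("total").sum(axis=0)
    ny, nx = total.shape
    col = total.sum(axis=1)
    bg = np.median(col)
    w = np.clip(col - bg, 0, None)
    if w.sum() <= 0:
        raise ValueError("no dendrite signal found")
    ys = np.arange(ny)
    y_c = float((w * ys).sum() / w.sum())
    # full visual thickness: rows carrying > 5 % of the peak excess signal,
    # padded so the widened background ring clears the PSF skirt
    signal_rows = np.nonzero(w > 0.05 * w.max())[0]
    extent = float(signal_rows[-1] - signal_rows[0] + 1)
    w_dendrite = max(4.0, extent + 16.0)
    pixel_size = stack.voxel_size[0]
    half_px = length_um * stack.expansion_factor / pixel_size / 2
    line = PolylineRoi(np.array([
        [nx / 2 - half_px, y_c],
        [nx / 2 + half_px, y_c],
    ]))
    return line, w_dendrite


def count_dendrite_sted(
    dendrite_stack: ChannelStack,
    calibration: CalibrationResult,
    line: PolylineRoi | None = None,
    w_dendrite: float | None = None,
    w_microtubule: float | None = None,
    widen_by: float = 10.0,
    cross_section_area: float | None = None,
) -> tuple[counting.MicrotubuleCounts, counting.DendriteMeasurement]:
    """Soma-calibrated STED counting of one dendrite segment."""
    if w_microtubule is None:
        w_microtubule = calibration.effective_width
    if line is None or w_dendrite is None:
        auto_line, auto_w = auto_dendrite_line(dendrite_stack)
        line = line or auto_line
        w_dendrite = w_dendrite or auto_w
    sums = {
        ch: dendrite_stack.channel(ch).sum(axis=0)
        for ch in dendrite_stack.channel_names
    }
    pixel_size = (
        dendrite_stack.voxel_size[0] / dendrite_stack.expansion_factor
    )
    meas = counting.measure_dendrite(
        sums, line, w_dendrite,
        pixel_size=pixel_size,
        w_microtubule=w_microtubule,
        widen_by=widen_by,
        cross_section_area=cross_section_area,
    )
    cnt = counting.count_dendrite(meas, calibration.fit, calibration.crosstalk)
    return cnt, meas


def yz_slice_series(
    stack: ChannelStack, trim: int = 0, step: int = 1
) -> ReslicedStack:
    """YZ slices of an already axis-aligned (straight) dendrite stack."""
    vox = stack.voxels  # (C, Z, Y, X)
    nx = vox.shape[3]
    idx = np.arange(trim, nx - trim, step)
    slices = np.stack([vox[:, :, :, i] for i in idx], axis=1)
    dx, dy, dz = stack.voxel_size
    return ReslicedStack(
        slices=slices,
        channel_names=stack.channel_names,
        spacing=dx * step,
        pixel_size=(dy, dz),
        expansion_factor=stack.expansion_factor,
    )


@dataclass
class FlipexmResult:
    per_slice: list
    dendrite: counting.MicrotubuleCounts
    fits: dict[str, filaments.SingleIntensityFit]
    alpha: float
    beta: float
    n_spots: int
    n_singles: dict[str, int] = field(default_factory=dict)


def flipexm_workflow(
    resliced: ReslicedStack,
    crosstalk_method: str = "pooled_mean",
    roundness_threshold: float = 0.8,
    **detect_kwargs,
) -> FlipexmResult:
    """Dendrite-intrinsic counting from YZ cross-section spots."""
    spots = flipexm.detect_spots_stack(
        resliced.slices, resliced.channel_names, **detect_kwargs
    )
    fits = {}
    singles_by_channel = {}
    n_singles = {}
    def _geometric_singles(ch: str) -> list[flipexm.Spot]:
        ch_spots = [s for s in spots if s.detection_channel == ch]
        round_ok = flipexm.roundness_filter(ch_spots, roundness_threshold)
        singles, _params = flipexm.area_filter(round_ok)
        return singles

    # total channel first: its singles threshold removes axially
    # overlapping doublets that the geometric filters cannot see
    total_singles = _geometric_singles("total")
    fits["total"] = flipexm.fit_single_crosssection(total_singles, "total")
    singles_by_channel["total"] = total_singles
    n_singles["total"] = len(total_singles)
    total_thr = fits["total"].single_threshold
    for ch in ("tyr", "ac"):
        singles = [
            s for s in _geometric_singles(ch)
            if s.intensities["total"] < total_thr
        ]
        # drop the crosstalk-dim population before calibration, as in the
        # soma stage: detection is permissive, so the other subset's dim
        # cross-sections are also detected here
        singles = flipexm.select_native_spots(singles, ch)
        singles_by_channel[ch] = singles
        n_singles[ch] = len(singles)
        fits[ch] = flipexm.fit_single_crosssection(singles, ch)
    a_levels, b_levels = flipexm.crosstalk_levels(singles_by_channel, fits)
    alpha, beta, _flags = flipexm.estimate_crosstalk_flipexm(
        a_levels, b_levels, method=crosstalk_method
    )
    per_slice, dendrite = flipexm.count_per_slice(
        spots, fits, alpha, beta, n_slices=resliced.n_slices
    )
    return FlipexmResult(
        per_slice=per_slice,
        dendrite=dendrite,
        fits=fits,
        alpha=alpha,
        beta=beta,
        n_spots=len(spots),
        n_singles=n_singles,
    )


def radial_workflow(
    resliced: ReslicedStack,
    params: radial.BoundaryParams | None = None,
    n_grid: int = 50,
) -> dict:
    """Tracked-contour radial profiles per channel plus decomposition."""
    params = params or radial.BoundaryParams()
    ref = params.reference_channel
    if ref not in resliced.channel_names:
        ref = resliced.channel_names[0]
    profiles: dict[str, list[radial.RadialProfile]] = {
        ch: [] for ch in resliced.channel_names
    }
    rect = None
    for s in range(resliced.n_slices):
        ref_img = resliced.channel(ref)[s]
        if not np.any(ref_img):
            continue
        try:
            if rect is None:
                rect = radial.initial_rectangle(ref_img, params)
            else:
                rect = radial.track_rectangle(ref_img, rect, params)
            contour = radial.fit_contour(ref_img, rect, params)
        except ValueError as exc:
            log.warning("slice %d: %s", s, exc)
            continue
        for ch in resliced.channel_names:
            try:
                profiles[ch].append(
                    radial.radial_profile(
                        resliced.channel(ch)[s], contour, channel=ch
                    )
                )
            except ValueError:
                continue
    averaged = {
        ch: radial.average_profiles([profiles[ch]], n_grid=n_grid)
        for ch in resliced.channel_names
        if profiles[ch]
    }
    result: dict = {"profiles": profiles, "averaged": averaged}
    if all(ch in averaged for ch in ("total", "tyr", "ac")):
        result["decomposition"] = radial.decompose_total(
            averaged["total"]["mean"],
            averaged["tyr"]["mean"],
            averaged["ac"]["mean"],
        )
    return result


# ---------------------------------------------------------------------------
# config-driven runs


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_config(cfg: dict, outdir: str | Path) -> dict:
    """Execute one configured workflow; write provenance-stamped outputs.

    ``cfg`` holds ``workflow`` (simulate | soma_sted | flipexm | radial),
    a ``scene`` SceneSpec mapping (synthetic runs) and optional stage
    parameter overrides.  Returns a run report dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    workflow = cfg.get("workflow")
    report: dict = {
        "workflow": workflow,
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("scene", {}).get("seed"),
    }
    try:
        if workflow == "simulate":
            spec = SceneSpec.from_dict(cfg["scene"])
            stack, truth = simulate_scene(spec)
            from mtquant.stackio import write_stack

            write_stack(stack, outdir / "scene.ome.tif")
            truth.to_json(outdir / "ground_truth.json")
            truth.to_csv(outdir / "ground_truth.csv")
            report["n_filaments"] = truth.n_total
        elif workflow == "soma_sted":
            soma_spec = SceneSpec.from_dict(cfg["scene"])
            soma_stack, _ = simulate_scene(soma_spec)
            cal = soma_calibration(soma_stack)
            if abs(1 - cal.crosstalk.alpha * cal.crosstalk.beta) < 1e-6:
                raise counting.UnmixSingularityError(
                    "calibration produced alpha*beta ~ 1"
                )
            den_cfg = dict(cfg.get("dendrite_scene", cfg["scene"]))
            den_cfg.setdefault("scene_kind", "dendrite")
            den_spec = SceneSpec.from_dict(den_cfg)
            den_stack, den_truth = simulate_scene(den_spec)
            cnt, meas = count_dendrite_sted(
                den_stack, cal,
                cross_section_area=den_truth.cross_section_area,
            )
            pd.DataFrame([{
                "area_um2": meas.cross_section_area,
                "n_tot": cnt.n_tot,
                "n_tyr": cnt.n_tyr,
                "n_ac": cnt.n_ac,
                "n_other": cnt.n_other,
                "density": cnt.density,
                "frac_tyr": cnt.fractions["tyr"],
                "frac_ac": cnt.fractions["ac"],
                "frac_other": cnt.fractions["other"],
                "flags": ";".join(cnt.flags),
            }]).to_csv(outdir / "counts.csv", index=False)
            report["alpha"] = cal.crosstalk.alpha
            report["beta"] = cal.crosstalk.beta
            report["n_tot"] = cnt.n_tot
        elif workflow == "flipexm":
            spec = SceneSpec.from_dict(cfg["scene"])
            stack, _ = simulate_scene(spec)
            resliced = yz_slice_series(
                stack, trim=int(cfg.get("trim", 10)),
                step=int(cfg.get("step", 4)),
            )
            res = flipexm_workflow(
                resliced, cfg.get("crosstalk_method", "pooled_mean")
            )
            pd.DataFrame([{
                "slice": i,
                "n_tot": c.n_tot,
                "n_tyr": c.n_tyr,
                "n_ac": c.n_ac,
                "flags": ";".join(c.flags),
            } for i, c in enumerate(res.per_slice)]).to_csv(
                outdir / "per_slice_counts.csv", index=False
            )
            report["alpha"] = res.alpha
            report["beta"] = res.beta
            report["n_tot"] = res.dendrite.n_tot
        elif workflow == "radial":
            spec = SceneSpec.from_dict(cfg["scene"])
            stack, _ = simulate_scene(spec)
            resliced = yz_slice_series(
                stack, trim=int(cfg.get("trim", 10)),
                step=int(cfg.get("step", 4)),
            )
            params = radial.BoundaryParams(
                **cfg.get("boundary", {"reference_channel": "total"})
            )
            res = radial_workflow(resliced, params)
            for ch, av in res["averaged"].items():
                pd.DataFrame(
                    {"r": av["r"], "rho_mean": av["mean"],
                     "rho_sd": av["sd"], "rho_sem": av["sem"]}
                ).to_csv(outdir / f"radial_{ch}.csv", index=False)
            if "decomposition" in res:
                d = res["decomposition"]
                report["w_tyr"] = d.w_tyr
                report["w_ac"] = d.w_ac
                report["weight_sum"] = d.weight_sum
        else:
            raise ValueError(f"unknown workflow {workflow!r}")
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    report["status"] = "ok"
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
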