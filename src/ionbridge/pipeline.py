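"""End-to-end pipelines: image-arm and trajectory-arm orchestration.

Each run writes CSV/JSON artifacts plus a provenance record (inputs,
parameters, seed, package version) sufficient to reproduce it. Plots are
optional, headless-safe artifacts; the CSV/JSON outputs are the contract.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import bridging_frame_fraction, stoichiometry_spectrum
from .imaging import (ROI, SheetImage, autocorr_curve, average_curves,
                      background_corrected_mean, clustered_fraction,
                      detect_clusters, normalize_to_control, radius_from_autocorr,
                      relative_sd)
from .rdf import compute_rdf, first_shell_threshold
from .roles import AtomRole
from .sasa import sasa_trace
from .trajectory import read_frames

log = logging.getLogger("ionbridge")


class DataError(ValueError):
    """Unusable input data (maps to CLI exit code 2)."""


def _provenance(out_dir: Path, config: dict) -> None:
    rec = {
        "package": "ionbridge",
        "version": __version__,
        "python": platform.python_version(),
        "config": config,
    }
    (out_dir / "provenance.json").write_text(json.dumps(rec, indent=1, default=str))


@dataclass
class ImageEntry:
    """One sheet: TIFF path (or array), condition label, ROI and background ROI."""
    path: str
    condition: str
    roi: tuple           # (x0, y0, w, h)
    background_roi: tuple | None = None


def load_tiff(path, pixel_size_nm: float, channel_label: str = "") -> SheetImage:
    import tifffile

    try:
        arr = tifffile.imread(path)
    except (FileNotFoundError, ValueError, OSError) as e:
        raise DataError(f"cannot read TIFF {path}: {e}") from None
    return SheetImage(np.asarray(arr, dtype=float), pixel_size_nm, channel_label)


def run_image_pipeline(entries: list[ImageEntry], pixel_size_nm: float,
                       control_condition: str, noise_level: float,
                       out_dir, k_sigma: float = 2.0, max_shift_px: int = 20,
                       poly_order: int = 4, make_plots: bool = False,
                       seed: int = 0) -> pd.DataFrame:
    """Per-sheet metrics, control-normalised rel. SD, per-condition summary.

    Chains the imaging operations in acquisition-workflow order:
    background-corrected mean, rel. SD, cluster detection, autocorrelation
    radius (per condition, averaged curves), punctate signal fraction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = {e.condition for e in entries}
    if control_condition not in conditions:
        raise DataError(f"control condition {control_condition!r} not among inputs "
                        f"{sorted(conditions)}")
    rows = []
    curves: dict[str, list] = {}
    for e in entries:
        img = load_tiff(e.path, pixel_size_nm)
        roi = ROI(*e.roi)
        bg = 0.0
        if e.background_roi is not None:
            bg_roi = ROI(*e.background_roi)
            bg = float(bg_roi.extract(img).mean())
        mean_bg = float(roi.extract(img).mean()) - bg
        rel = relative_sd(img, roi, background=bg)
        _, density = detect_clusters(img, roi, noise_level)
        frac = clustered_fraction(img, roi, k_sigma=k_sigma, background=bg)
        curves.setdefault(e.condition, []).append(
            autocorr_curve(img, roi, max_shift_px))
        rows.append({"path": e.path, "condition": e.condition,
                     "mean_intensity_bgcorr": mean_bg, "rel_sd": rel,
                     "cluster_density_per_um2": density,
                     "clustered_fraction": frac})
    sheets = pd.DataFrame(rows)
    control_vals = sheets.loc[sheets["condition"] == control_condition, "rel_sd"]
    sheets["rel_sd_normalized"] = normalize_to_control(sheets["rel_sd"],
                                                       control_vals)
    radii = {}
    for cond, cs in sorted(curves.items()):
        try:
            radii[cond] = radius_from_autocorr(average_curves(cs), poly_order)
        except ValueError as err:
            log.warning("condition %s: autocorrelation radius unavailable (%s)",
                        cond, err)
            radii[cond] = np.nan
    sheets["cluster_radius_nm"] = sheets["condition"].map(radii)
    sheets.to_csv(out_dir / "per_sheet_metrics.csv", index=False)

    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    summary = (sheets.groupby("condition")
               [["mean_intensity_bgcorr", "rel_sd", "rel_sd_normalized",
                 "cluster_density_per_um2", "clustered_fraction",
                 "cluster_radius_nm"]]
               .agg(["mean", sem]))
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.to_csv(out_dir / "per_condition_summary.csv")
    if make_plots:
        _plot_rel_sd(summary, out_dir)
    _provenance(out_dir, {"arm": "image", "control": control_condition,
                          "noise_level": noise_level, "k_sigma": k_sigma,
                          "pixel_size_nm": pixel_size_nm, "seed": seed,
                          "n_sheets": len(entries)})
    return sheets


def _plot_rel_sd(summary: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(summary.index, summary["rel_sd_normalized_mean"],
                yerr=summary["rel_sd_normalized_sem"], fmt="o-")
    ax.set_xlabel("condition")
    ax.set_ylabel("rel. SD (normalized to control)")
    fig.tight_layout()
    fig.savefig(out_dir / "rel_sd_vs_condition.png", dpi=150)
    plt.close(fig)


def run_traj_pipeline(traj_path, out_dir, fmt: str | None = None,
                      ion_role: str = "calcium",
                      site_role: str = "carboxylate_carbon",
                      threshold_nm: float = 0.4, last_fraction: float = 0.2,
                      bin_width_nm: float = 0.002, r_max_nm: float = 1.0,
                      run_sasa: bool = True, n_sphere_points: int = 960,
                      seed: int = 0) -> dict:
    """RDF + threshold report + stoichiometry spectra + bridging fraction
    (+ SASA trace) for one trajectory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj = read_frames(traj_path, fmt)
    for role, name in ((ion_role, "ion role"), (site_role, "site role")):
        if len(traj.indices_of_role(role)) == 0:
            raise DataError(f"{name} {role!r} selects no atoms")
    r_max = min(r_max_nm, float(traj.box.min()) / 2 if traj.box is not None else r_max_nm)
    rdf = compute_rdf(traj, ion_role, site_role, bin_width_nm, r_max)
    pd.DataFrame({"r_nm": rdf.r_centers_nm, "g_r": rdf.g_r}).to_csv(
        out_dir / "rdf.csv", index=False)
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        thr, from_rdf = first_shell_threshold(rdf, fallback_role=site_role,
                                              fallback_nm=threshold_nm)
    if not from_rdf:
        log.warning("RDF threshold fell back to %.3f nm", thr)
    spec = stoichiometry_spectrum(traj, last_fraction=last_fraction,
                                  threshold_nm=threshold_nm,
                                  ion_role=ion_role, site_role=site_role)
    pd.DataFrame({
        "i": list(spec.ion_with_i_sites.keys()),
        "ion_with_i_sites_per_frame": list(spec.ion_with_i_sites.values()),
    }).to_csv(out_dir / "stoichiometry_ion.csv", index=False)
    pd.DataFrame({
        "i": list(spec.site_with_i_ions.keys()),
        "site_with_i_ions_per_frame": list(spec.site_with_i_ions.values()),
    }).to_csv(out_dir / "stoichiometry_site.csv", index=False)
    frac1 = bridging_frame_fraction(traj, last_fraction=last_fraction,
                                    threshold_nm=threshold_nm, min_sites=1,
                                    ion_role=ion_role, site_role=site_role)
    frac2 = bridging_frame_fraction(traj, last_fraction=last_fraction,
                                    threshold_nm=threshold_nm, min_sites=2,
                                    ion_role=ion_role, site_role=site_role)
    result = {
        "threshold_nm": thr, "threshold_from_rdf": bool(from_rdf),
        "bridging_frame_fraction_min1": frac1,
        "bridging_frame_fraction_min2": frac2,
        "zero_contact_ions_per_frame": spec.zero_contact_ions,
        "n_frames_analysed": spec.n_frames_analysed,
    }
    if run_sasa:
        trace = sasa_trace(traj, n_sphere_points=n_sphere_points)
        pd.DataFrame({"time_ps": trace.times_ps,
                      "total_sasa_nm2": trace.total_sasa_nm2}).to_csv(
            out_dir / "sasa_trace.csv", index=False)
        m, s = trace.window_stats(last_fraction=last_fraction)
        result["sasa_window_mean_nm2"] = m
        result["sasa_window_sem_nm2"] = s
    (out_dir / "summary.json").write_text(json.dumps(result, indent=1))
    _provenance(out_dir, {"arm": "traj", "traj": str(traj_path),
                          "threshold_nm": threshold_nm,
                          "last_fraction": last_fraction, "seed": seed,
                          "ion_role": ion_role, "site_role": site_role})
    return result
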