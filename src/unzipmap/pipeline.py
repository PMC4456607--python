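"""End-to-end runs: simulate -> analyze -> report.

``run_simulate`` renders a remodeling ensemble to TSV trace files plus the
naked-DNA reference and a manifest; ``run_analyze`` aligns each trace to the
reference, calls the TF and nucleosome positions and writes a calls table
and a summary JSON; ``run_report`` renders the summary to markdown with
figures.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import stats as ustats
from .align import apply_alignment, fit_shift_stretch, select_alignment_regions
from .calling import (call_nucleosome, call_tf, detect_events, estimate_baseline,
                      segment_clusters)
from .config import RunConfig, save_config
from .remodel import simulate_remodeling_ensemble
from .simulate import distort_trace, draw_distortion, simulate_naked_reference
from .templates import TemplateLayout
from .trace import read_trace, write_trace

log = logging.getLogger("unzipmap")

REFERENCE_NAME = "reference.tsv"
MANIFEST_NAME = "manifest.csv"


def _layout_from_row(row: pd.Series) -> TemplateLayout:
    tf_center = row["tf_center"]
    if isinstance(tf_center, str) or (isinstance(tf_center, float)
                                      and math.isnan(tf_center)):
        tf_center = None
    return TemplateLayout(
        template_len=int(row["template_len"]), dyad0=int(row["dyad0_design"]),
        tf_center=None if tf_center is None else int(tf_center),
        tf_footprint=int(row["tf_footprint"]), separation=int(row["separation"]),
        direction=str(row["direction"]), template_seed=int(row["template_seed"]))


def run_simulate(cfg: RunConfig, outdir: Union[str, Path]) -> Path:
    """Write reference, per-molecule traces and the manifest; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = cfg.template.build()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    reference = simulate_naked_reference(layout, cfg.signature, cfg.instrument,
                                         np.random.default_rng(
                                             np.random.SeedSequence([cfg.seed, 2])))
    write_trace(reference, outdir / REFERENCE_NAME)

    ens = simulate_remodeling_ensemble(
        layout, cfg.remodeler, cfg.n_molecules, cfg.duration,
        seed=cfg.seed, tf_bound_fraction=cfg.tf_bound_fraction,
        render=True, signature=cfg.signature, instrument=cfg.instrument)

    rows = []
    for i, trace in enumerate(ens.traces):
        if cfg.distort:
            shift, stretch = draw_distortion(rng)
            trace = distort_trace(trace, shift, stretch)
        name = f"trace_{i:04d}.tsv"
        write_trace(trace, outdir / name)
        rec = ens.table.iloc[i].to_dict()
        rec.update(
            trace_file=name, reference_file=REFERENCE_NAME,
            template_len=layout.template_len, dyad0_design=layout.dyad0,
            tf_center="" if layout.tf_center is None else layout.tf_center,
            tf_footprint=layout.tf_footprint, separation=layout.separation,
            direction=layout.direction, template_seed=layout.template_seed,
            applied_shift_bp=trace.meta["applied_shift_bp"],
            applied_stretch=trace.meta["applied_stretch"],
        )
        rows.append(rec)
    manifest = pd.DataFrame(rows)
    manifest_path = outdir / MANIFEST_NAME
    manifest.to_csv(manifest_path, index=False, float_format="%.6f")
    save_config(cfg, outdir / "config.yaml")
    return manifest_path


def analyze_trace(trace, reference, layout: TemplateLayout, cfg: RunConfig) -> dict:
    """Align one trace and call TF/nucleosome; positions in dyad coordinates."""
    windows = select_alignment_regions(trace, layout, cfg.signature)
    result = fit_shift_stretch(trace, reference, windows)
    aligned = apply_alignment(trace, result, reference)
    baseline = estimate_baseline(aligned, reference, cfg.analysis.k_sd,
                                 cfg.analysis.min_prominence_pN)
    events = detect_events(aligned, baseline)
    clusters = segment_clusters(events, cfg.analysis.gap_bp,
                                cfg.analysis.centroid_mode, aligned, baseline)
    tf = call_tf(events, clusters, layout, cfg.signature,
                 cfg.analysis.tf_window_bp, cfg.analysis.nuc_force_floor_pN)
    nuc = call_nucleosome(clusters, cfg.signature,
                          cfg.analysis.nuc_force_floor_pN)
    out = {
        "align_shift_bp": result.shift_bp,
        "align_stretch": result.stretch,
        "align_score": result.score,
        "tf_bound": tf.bound,
        "tf_masked": tf.masked,
        "tf_center_rel_bp": layout.unzip_to_dyad_frame(tf.called_center)
        if tf.called_center is not None else np.nan,
        "tf_peak_force": tf.peak_force if tf.peak_force is not None else np.nan,
        "nuc_present": nuc.present,
        "dyad_rel_bp": layout.unzip_to_dyad_frame(nuc.called_dyad)
        if nuc.called_dyad is not None else np.nan,
    }
    for key in ("max_force_c1", "max_force_c2", "width_c1", "width_c2",
                "intercluster_distance"):
        out[key] = nuc.features.get(key, np.nan)
    return out


def run_analyze(manifest_path: Union[str, Path], cfg: RunConfig,
                outdir: Union[str, Path]) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        log.warning("empty manifest %s: nothing to analyze", manifest_path)
        pd.DataFrame().to_csv(outdir / "calls.csv", index=False)
        summary = {"n_traces": 0, "n_failed": 0}
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True))
        return summary

    ref_path = manifest_path.parent / str(manifest["reference_file"].iloc[0])
    if not ref_path.exists():
        raise FileNotFoundError(f"missing reference trace {ref_path}")
    reference = read_trace(ref_path)

    rows, failed = [], 0
    for _, mrow in manifest.iterrows():
        layout = _layout_from_row(mrow)
        path = manifest_path.parent / str(mrow["trace_file"])
        try:
            trace = read_trace(path)
            calls = analyze_trace(trace, reference, layout, cfg)
        except Exception as exc:  # keep going; a bad file must not kill the run
            log.error("trace %s failed: %s", path.name, exc)
            failed += 1
            continue
        calls["trace_id"] = mrow["trace_file"]
        for key in ("initial_dyad", "final_dyad", "tf_initial", "tf_final"):
            if key in mrow:
                calls[f"true_{key}"] = mrow[key]
        rows.append(calls)

    calls_df = pd.DataFrame(rows)
    calls_df.to_csv(outdir / "calls.csv", index=False, float_format="%.6f")
    summary = summarize_calls(calls_df, cfg)
    summary["n_failed"] = failed
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary


def summarize_calls(calls: pd.DataFrame, cfg: RunConfig) -> dict:
    layout = cfg.template.build()
    summary: dict = {"n_traces": int(len(calls))}
    if calls.empty:
        return summary
    bound = calls["tf_bound"].astype("boolean")
    summary["tf_bound_fraction"] = float(bound.dropna().astype(bool).mean()) \
        if bound.notna().any() else None
    summary["tf_masked_fraction"] = float(calls["tf_masked"].astype(bool).mean())
    summary["nuc_present_fraction"] = float(calls["nuc_present"].astype(bool).mean())
    summary["alignment"] = {
        "mean_score": float(calls["align_score"].mean()),
        "max_abs_shift_bp": float(calls["align_shift_bp"].abs().max()),
        "max_stretch_dev": float((calls["align_stretch"] - 1).abs().max()),
    }

    dyads = calls["dyad_rel_bp"].dropna().to_numpy()
    if "true_final_dyad" in calls:
        truth_rel = calls["true_final_dyad"] - layout.dyad0
        sel = calls["dyad_rel_bp"].notna()
        if sel.sum() >= 2:
            err = (calls.loc[sel, "dyad_rel_bp"]
                   - truth_rel[sel]).to_numpy()
            summary["dyad_recovery"] = ustats.precision_accuracy(err, 0.0)
    if dyads.size >= 20:
        fit = ustats.fit_double_gaussian(dyads, mode="mle",
                                         bin_bp=cfg.analysis.hist_bin_bp)
        summary["mixture"] = {
            "w_unremodeled": fit.w_unremodeled, "mu1": fit.mu1,
            "sigma1": fit.sigma1, "mu2": fit.mu2, "sigma2": fit.sigma2,
            "converged": fit.converged, "degenerate": fit.degenerate,
        }
        if 0.0 < fit.w_unremodeled < 1.0:
            ev = ustats.poisson_event_fractions(fit.w_unremodeled)
            summary["event_fractions"] = {
                "lambda": ev.lam, "frac_once": ev.frac_once,
                "frac_multi": ev.frac_multi}

    if {"true_initial_dyad", "true_final_dyad"} <= set(calls.columns) \
            and layout.tf_center is not None:
        table = pd.DataFrame({
            "initial_dyad": calls["true_initial_dyad"],
            "final_dyad": calls["dyad_rel_bp"] + layout.dyad0,
            "tf_final": calls["tf_bound"].map(
                lambda v: bool(v) if pd.notna(v) else False),
        }).dropna()
        if len(table):
            summary["directionality"] = ustats.directionality_and_eviction_summary(
                table, float(layout.tf_center))
    return summary


def run_report(summary_path: Union[str, Path], outdir: Union[str, Path],
               calls_path: Optional[Union[str, Path]] = None) -> Path:
    """Render a human-readable markdown report (plus figures if calls exist)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = json.loads(Path(summary_path).read_text())

    lines = ["# Unzipping analysis report", ""]
    lines.append(f"Traces analyzed: {summary.get('n_traces', 0)} "
                 f"(failed: {summary.get('n_failed', 0)})")
    for key in ("tf_bound_fraction", "tf_masked_fraction", "nuc_present_fraction"):
        if summary.get(key) is not None:
            lines.append(f"- {key.replace('_', ' ')}: {summary[key]:.3f}")
    if "alignment" in summary:
        a = summary["alignment"]
        lines.append(f"- alignment: mean score {a['mean_score']:.4f}, "
                     f"max |shift| {a['max_abs_shift_bp']:.2f} bp, "
                     f"max |stretch-1| {a['max_stretch_dev']:.4f}")
    if "dyad_recovery" in summary:
        r = summary["dyad_recovery"]
        lines.append(f"- dyad recovery: bias {r['bias']:.2f} bp, sd {r['sd']:.2f} bp")
    if "mixture" in summary:
        m = summary["mixture"]
        lines.append(f"- mixture: unremodeled weight {m['w_unremodeled']:.3f} "
                     f"(narrow sd {m['sigma1']:.1f} bp, broad sd {m['sigma2']:.1f} bp)")
    if "event_fractions" in summary:
        e = summary["event_fractions"]
        lines.append(f"- of remodeled molecules: {100 * e['frac_once']:.0f}% once, "
                     f"{100 * e['frac_multi']:.0f}% more than once "
                     f"(lambda = {e['lambda']:.3f})")
    if "directionality" in summary:
        d = summary["directionality"]
        lines.append(f"- remodeled n={d['n_remodeled']}: toward TF "
                     f"{d['frac_toward_tf']:.2f}, away {d['frac_away']:.2f}, "
                     f"TF retained {d['frac_tf_retained']:.2f}, "
                     f"passed TF {d['frac_passed_tf']:.2f}")
    lines.append("")

    if calls_path is not None and Path(calls_path).exists():
        calls = pd.read_csv(calls_path)
        if "dyad_rel_bp" in calls and calls["dyad_rel_bp"].notna().sum() > 0:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            dyads = calls["dyad_rel_bp"].dropna().to_numpy()
            fig, ax = plt.subplots(figsize=(6, 3.5))
            counts, edges = ustats.position_histogram(dyads, 5.0)
            ax.stairs(counts, edges, fill=True, alpha=0.6)
            if "mixture" in summary:
                from scipy import stats as sps
                m = summary["mixture"]
                grid = np.linspace(edges[0], edges[-1], 400)
                amp = dyads.size * 5.0
                pdf = (m["w_unremodeled"] * sps.norm.pdf(grid, m["mu1"], m["sigma1"])
                       + (1 - m["w_unremodeled"])
                       * sps.norm.pdf(grid, m["mu2"], m["sigma2"]))
                ax.plot(grid, amp * pdf, "r-", lw=1.5)
            ax.set_xlabel("dyad position relative to designed dyad (bp)")
            ax.set_ylabel("molecules")
            fig.tight_layout()
            fig.savefig(outdir / "dyad_histogram.png", dpi=120)
            plt.close(fig)
            lines.append("![dyad position histogram](dyad_histogram.png)")
            lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path
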