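"""Synthetic unzipping traces from the threshold-ramp model.

Every base pair ``j`` (in bp-unzipped coordinates along the chosen
direction) carries a disruption threshold: the naked-DNA baseline plus, for
protein-bound regions, a Laplace-shaped excess bump.  The loading-rate clamp
ramps the force linearly in time whenever the fork stalls, so the recorded
disruption force at ``j`` is ``max(threshold(j), relaxed entry force)`` —
after each disruption the excess force relaxes exponentially toward the
baseline with bp constant ``relax_bp``, which is why close interactions are
met at a higher initial force.

The trace is reduced to one disruption force per bp; dwell times (stall +
transit) give the arrival-time channel used for dwell histograms.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .models import (SHIFT_BOUND_BP, STRETCH_BOUND, InstrumentModel,
                     SignatureModel, _filtered_white_noise_sd)
from .templates import TemplateLayout
from .trace import UnzipTrace

Occupancy = Union[Dict[str, bool], Tuple[bool, bool]]


def _occupancy_flags(occupancy: Occupancy) -> Tuple[bool, bool]:
    if isinstance(occupancy, dict):
        return bool(occupancy["tf_bound"]), bool(occupancy["nuc_present"])
    tf_bound, nuc_present = occupancy
    return bool(tf_bound), bool(nuc_present)


def baseline_profile(layout: TemplateLayout, signature: SignatureModel) -> np.ndarray:
    """Naked-DNA disruption-force profile in *physical* coordinates.

    Seeded by the template, so all traces of one template (and its naked
    reference) share the same feature landscape; excursions are clipped at
    4 sd so a naked trace never mimics a protein signature.
    """
    n = layout.template_len
    if signature.baseline_sd == 0.0:
        return np.full(n, signature.baseline_mean)
    rng = np.random.default_rng(layout.template_seed)
    wiggle = gaussian_filter1d(rng.standard_normal(n), signature.baseline_corr_bp,
                               mode="reflect")
    wiggle *= signature.baseline_sd / _filtered_white_noise_sd(signature.baseline_corr_bp)
    np.clip(wiggle, -4.0 * signature.baseline_sd, 4.0 * signature.baseline_sd,
            out=wiggle)
    return signature.baseline_mean + wiggle


def _laplace_bump(u: np.ndarray, center: float, amplitude: float,
                  scale: float) -> np.ndarray:
    return amplitude * np.exp(-np.abs(u - center) / scale)


def signature_truth(layout: TemplateLayout, signature: SignatureModel,
                    tf_bound: bool, nuc_present: bool) -> Dict[str, float]:
    """Noise-free geometric truth of the signature, in unzip coordinates."""
    truth: Dict[str, float] = {}
    if tf_bound and layout.tf_center is not None:
        truth["tf_peak_u"] = layout.tf_center_unzip - signature.tf_peak_offset
    if nuc_present:
        d = layout.dyad0_unzip
        truth["cluster1_centroid_u"] = d + signature.nuc_cluster1_offset
        truth["cluster2_centroid_u"] = d + signature.nuc_cluster2_offset
    return truth


def threshold_excess(layout: TemplateLayout, signature: SignatureModel,
                     tf_bound: bool, nuc_present: bool,
                     rng: np.random.Generator) -> Tuple[np.ndarray, Dict[str, float]]:
    """Excess (above baseline) disruption thresholds in unzip coordinates."""
    u = np.arange(layout.template_len, dtype=float)
    excess = np.zeros_like(u)
    truth = signature_truth(layout, signature, tf_bound, nuc_present)

    if tf_bound:
        if layout.tf_center is None:
            raise ValueError("layout has no TF site but tf_bound is True")
        peak_force = rng.uniform(*signature.tf_peak_force_range)
        amp = peak_force - signature.baseline_mean
        np.maximum(excess, _laplace_bump(u, truth["tf_peak_u"], amp,
                                         signature.bump_scale_bp), out=excess)
        truth["tf_peak_force"] = peak_force

    if nuc_present:
        weights = np.asarray(signature.balanced_subpeak_weights)
        offsets = np.asarray(signature.cluster_subpeak_offsets, dtype=float)
        for name, key in (("cluster1", "cluster1_centroid_u"),
                          ("cluster2", "cluster2_centroid_u")):
            peak_force = rng.uniform(*signature.cluster_peak_force_range)
            amp = peak_force - signature.baseline_mean
            for off, w in zip(offsets, weights):
                np.maximum(excess,
                           _laplace_bump(u, truth[key] + off, amp * w,
                                         signature.bump_scale_bp),
                           out=excess)
            truth[f"{name}_max_force"] = peak_force
    return excess, truth


def _recorded_excess(threshold_exc: np.ndarray, relax_bp: float) -> np.ndarray:
    """Disruption-force excess per bp: max(threshold, relaxed carry-over)."""
    r = math.exp(-1.0 / relax_bp)
    out = np.empty_like(threshold_exc)
    carry = 0.0
    for j, t in enumerate(threshold_exc):
        carry = t if t > carry else carry
        out[j] = carry
        carry *= r
    return out


def simulate_trace(layout: TemplateLayout,
                   occupancy: Occupancy,
                   signature: Optional[SignatureModel] = None,
                   instrument: Optional[InstrumentModel] = None,
                   seed: Union[int, np.random.Generator] = 0,
                   include_time: bool = True) -> UnzipTrace:
    """Simulate one force-vs-position unzipping record.

    ``occupancy`` carries the molecular truth: whether the TF site is bound
    and whether the nucleosome is present (at ``layout.dyad0``).  All
    stochastic draws (peak forces, measurement noise) come from ``seed``.
    """
    signature = signature or SignatureModel()
    instrument = instrument or InstrumentModel()
    tf_bound, nuc_present = _occupancy_flags(occupancy)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base_phys = baseline_profile(layout, signature)
    base_u = base_phys if layout.direction == "from_tf_side" else base_phys[::-1].copy()

    t_exc, truth = threshold_excess(layout, signature, tf_bound, nuc_present, rng)
    rec_exc = _recorded_excess(t_exc, signature.relax_bp)
    forces = base_u + rec_exc

    if instrument.force_noise_sd > 0:
        noise = gaussian_filter1d(rng.standard_normal(forces.size),
                                  instrument.noise_corr_bp, mode="reflect")
        noise *= instrument.force_noise_sd / _filtered_white_noise_sd(
            instrument.noise_corr_bp)
        forces = forces + noise

    positions = np.arange(layout.template_len, dtype=float)

    time_s = None
    if include_time:
        r = math.exp(-1.0 / signature.relax_bp)
        entry = np.empty_like(rec_exc)
        entry[0] = 0.0
        entry[1:] = rec_exc[:-1] * r
        stall = np.maximum(0.0, t_exc - entry) / instrument.ramp_rate_pN_s
        dwell = stall + 1.0 / instrument.velocity_bp_s
        time_s = np.concatenate([[0.0], np.cumsum(dwell[:-1])])

    meta = {
        "template_len": layout.template_len,
        "dyad0": layout.dyad0,
        "tf_center": layout.tf_center if layout.tf_center is not None else "None",
        "tf_footprint": layout.tf_footprint,
        "separation": layout.separation,
        "direction": layout.direction,
        "template_seed": layout.template_seed,
        "tf_bound": tf_bound,
        "nuc_present": nuc_present,
        "true_dyad": layout.dyad0,
        "applied_shift_bp": 0.0,
        "applied_stretch": 1.0,
        "synthetic": True,
    }
    for key, value in truth.items():
        meta[f"truth_{key}"] = value
    return UnzipTrace(positions, forces, time_s, meta)


def simulate_naked_reference(layout: TemplateLayout,
                             signature: Optional[SignatureModel] = None,
                             instrument: Optional[InstrumentModel] = None,
                             seed: Union[int, np.random.Generator] = 1
                             ) -> UnzipTrace:
    """The naked-DNA trace of the same template, used as alignment reference."""
    return simulate_trace(layout, (False, False), signature, instrument, seed)


def distort_trace(trace: UnzipTrace, shift_bp: float, stretch: float) -> UnzipTrace:
    """Apply the instrumental distortion x -> stretch * x + shift.

    Emulates drift, bead-size and linker-arm variation; bounds are the
    declared instrument box (|shift| <= 10 bp, |stretch - 1| < 2%) which the
    alignment search must cover.
    """
    if abs(shift_bp) > SHIFT_BOUND_BP + 1e-12:
        raise ValueError(f"|shift_bp| must be <= {SHIFT_BOUND_BP} bp")
    if abs(stretch - 1.0) > STRETCH_BOUND + 1e-12:
        raise ValueError(f"|stretch - 1| must be < {STRETCH_BOUND}")
    out = trace.copy()
    out.positions = stretch * out.positions + shift_bp
    out.meta["applied_shift_bp"] = float(trace.meta.get("applied_shift_bp", 0.0)) \
        + shift_bp
    out.meta["applied_stretch"] = float(trace.meta.get("applied_stretch", 1.0)) \
        * stretch
    return out


def draw_distortion(rng: np.random.Generator,
                    shift_range: float = 8.0,
                    stretch_range: float = 0.015) -> Tuple[float, float]:
    """Draw a random (shift, stretch) inside the declared instrument box."""
    return (float(rng.uniform(-shift_range, shift_range)),
            float(rng.uniform(1.0 - stretch_range, 1.0 + stretch_range)))
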