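"""Force-signature detection and TF / nucleosome position calls.

Positions of protein-DNA interactions are read off an aligned trace as force
peaks above the naked-DNA baseline.  The calling conventions are fixed by
the unzipping geometry: a bound TF produces a single peak 8 bp before the
site center along the unzipping direction, so the called center is the peak
position + 8 bp; a nucleosome produces two clusters of larger peaks and the
called dyad is the mean force location of the first cluster + 43 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .models import SignatureModel
from .templates import TemplateLayout
from .trace import UnzipTrace


@dataclass(frozen=True)
class BaselineEstimate:
    """Per-bp baseline and the global detection threshold above it."""
    positions: np.ndarray
    baseline: np.ndarray
    floor: float           # detection threshold, in pN above the baseline
    resid_sd: float

    @property
    def threshold(self) -> np.ndarray:
        return self.baseline + self.floor


@dataclass(frozen=True)
class ForceEvent:
    position: float
    peak_force: float
    prominence: float      # pN above the local baseline


@dataclass(frozen=True)
class Cluster:
    events: Tuple[ForceEvent, ...]
    span: Tuple[float, float]
    force_centroid: float
    max_force: float

    @property
    def width(self) -> float:
        return self.span[1] - self.span[0]


@dataclass(frozen=True)
class TFCall:
    bound: Optional[bool]          # None when masked by a nucleosome signature
    masked: bool = False
    called_center: Optional[float] = None
    peak_force: Optional[float] = None
    peak_position: Optional[float] = None


@dataclass(frozen=True)
class NucleosomeCall:
    present: bool
    called_dyad: Optional[float] = None
    features: dict = field(default_factory=dict)


def estimate_baseline(trace: UnzipTrace,
                      naked_reference: UnzipTrace,
                      k_sd: float = 3.0,
                      min_prominence_pN: float = 1.0,
                      smooth_bp: float = 1.0) -> BaselineEstimate:
    """Baseline = lightly smoothed naked reference on the common grid.

    The detection threshold is baseline + max(k * residual sd, an absolute
    prominence floor); the residual sd is measured on the reference against
    its own smooth, i.e. the instrument noise level after output filtering.
    """
    if trace.positions.shape != naked_reference.positions.shape or \
            not np.allclose(trace.positions, naked_reference.positions):
        raise ValueError("trace and naked reference must share a position grid; "
                         "align the trace first")
    baseline = gaussian_filter1d(naked_reference.forces, smooth_bp, mode="reflect")
    resid_sd = float(np.std(naked_reference.forces - baseline))
    floor = max(k_sd * resid_sd, min_prominence_pN)
    return BaselineEstimate(naked_reference.positions, baseline, floor, resid_sd)


def _refine_peak(x: np.ndarray, e: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-bp peak location/height by parabolic interpolation around sample i."""
    if i <= 0 or i >= e.size - 1:
        return float(x[i]), float(e[i])
    denom = e[i - 1] - 2.0 * e[i] + e[i + 1]
    if denom >= 0:
        return float(x[i]), float(e[i])
    delta = 0.5 * (e[i - 1] - e[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = e[i] - 0.25 * (e[i - 1] - e[i + 1]) * delta
    step = x[i + 1] - x[i] if delta >= 0 else x[i] - x[i - 1]
    return float(x[i] + delta * step), float(height)


def detect_events(trace: UnzipTrace, baseline: BaselineEstimate) -> List[ForceEvent]:
    """Local maxima of (force - baseline) above the detection threshold."""
    excess = trace.forces - baseline.baseline
    idx, _ = find_peaks(excess, height=baseline.floor)
    events = []
    for i in idx:
        pos, height = _refine_peak(trace.positions, excess, int(i))
        base_at = float(np.interp(pos, baseline.positions, baseline.baseline))
        events.append(ForceEvent(pos, base_at + height, height))
    events.sort(key=lambda ev: ev.position)
    return events


def segment_clusters(events: Sequence[ForceEvent],
                     gap_bp: float = 15.0,
                     centroid_mode: str = "peak",
                     trace: Optional[UnzipTrace] = None,
                     baseline: Optional[BaselineEstimate] = None) -> List[Cluster]:
    """Split position-sorted events into clusters at gaps > ``gap_bp``.

    ``centroid_mode='peak'`` (default) weights refined event-peak positions
    by their prominences; ``'sample'`` integrates all above-threshold samples
    of the trace inside the cluster span (requires ``trace``/``baseline``).
    """
    if centroid_mode not in ("peak", "sample"):
        raise ValueError("centroid_mode must be 'peak' or 'sample'")
    if centroid_mode == "sample" and (trace is None or baseline is None):
        raise ValueError("sample-mode centroid needs the trace and its baseline")
    groups: List[List[ForceEvent]] = []
    for ev in sorted(events, key=lambda e: e.position):
        if groups and ev.position - groups[-1][-1].position <= gap_bp:
            groups[-1].append(ev)
        else:
            groups.append([ev])
    clusters = []
    for group in groups:
        span = (group[0].position, group[-1].position)
        w = np.array([ev.prominence for ev in group])
        p = np.array([ev.position for ev in group])
        if centroid_mode == "peak":
            centroid = float(np.sum(w * p) / np.sum(w))
        else:
            excess = trace.forces - baseline.baseline
            sel = ((trace.positions >= span[0]) & (trace.positions <= span[1])
                   & (excess > baseline.floor))
            if not np.any(sel):
                centroid = float(np.sum(w * p) / np.sum(w))
            else:
                centroid = float(np.sum(excess[sel] * trace.positions[sel])
                                 / np.sum(excess[sel]))
        clusters.append(Cluster(tuple(group), span, centroid,
                                float(max(ev.peak_force for ev in group))))
    return clusters


def call_tf(events: Sequence[ForceEvent],
            clusters: Sequence[Cluster],
            layout: TemplateLayout,
            signature: Optional[SignatureModel] = None,
            window_bp: float = 30.0,
            nuc_force_floor_pN: float = 22.0) -> TFCall:
    """Bound/unbound call and called center at the expected TF site.

    The search window sits around the expected peak (site center - 8 bp
    along the unzipping direction).  If the window overlaps a detected
    nucleosome-strength cluster the call is flagged masked rather than
    unbound — the TF signature cannot be separated from the nucleosome's.
    """
    signature = signature or SignatureModel()
    if layout.tf_center_unzip is None:
        return TFCall(bound=False)
    expected_peak = layout.tf_center_unzip - signature.tf_peak_offset
    lo, hi = expected_peak - window_bp, expected_peak + window_bp

    margin = signature.bump_scale_bp
    for cl in clusters:
        if cl.max_force >= nuc_force_floor_pN and \
                cl.span[0] - margin <= hi and cl.span[1] + margin >= lo:
            return TFCall(bound=None, masked=True)

    in_window = [ev for ev in events
                 if lo <= ev.position <= hi and ev.peak_force < nuc_force_floor_pN]
    if not in_window:
        return TFCall(bound=False)
    peak = max(in_window, key=lambda ev: ev.prominence)
    return TFCall(bound=True, masked=False,
                  called_center=peak.position + signature.tf_peak_offset,
                  peak_force=peak.peak_force, peak_position=peak.position)


def call_nucleosome(clusters: Sequence[Cluster],
                    signature: Optional[SignatureModel] = None,
                    nuc_force_floor_pN: float = 22.0) -> NucleosomeCall:
    """Dyad call from the first-encountered nucleosome-strength cluster.

    called_dyad = force centroid of the first qualifying cluster + 43 bp
    along the unzipping direction; structural features (cluster max forces,
    widths, inter-cluster distance) are filled when two clusters qualify.
    """
    signature = signature or SignatureModel()
    qualifying = [cl for cl in clusters if cl.max_force >= nuc_force_floor_pN]
    if not qualifying:
        return NucleosomeCall(present=False)
    qualifying.sort(key=lambda cl: cl.span[0])
    first = qualifying[0]
    # the convention: shift the first-cluster centroid by +43 bp along the
    # unzipping direction (the cluster leads the dyad by |offset|)
    called_dyad = first.force_centroid + abs(signature.nuc_cluster1_offset)
    features = {"max_force_c1": first.max_force, "width_c1": first.width}
    if len(qualifying) >= 2:
        second = qualifying[1]
        features.update(
            max_force_c2=second.max_force, width_c2=second.width,
            intercluster_distance=second.force_centroid - first.force_centroid)
    return NucleosomeCall(present=True, called_dyad=called_dyad, features=features)


def compute_dwell_histogram(trace: UnzipTrace,
                            bin_bp: float = 2.0) -> Tuple[np.ndarray, np.ndarray]:
    """Total fork residence time per position bin.

    The loading-rate clamp makes the fork dwell longest where it first meets
    each interaction region, so the argmax bin marks the region's leading
    edge.  Requires the trace's arrival-time channel.
    """
    if trace.time_s is None:
        raise ValueError("trace carries no time information")
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    dwell = np.diff(trace.time_s)
    edges = np.arange(trace.positions[0], trace.positions[-1] + bin_bp, bin_bp)
    hist, edges = np.histogram(trace.positions[:-1], bins=edges, weights=dwell)
    return hist, edges
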