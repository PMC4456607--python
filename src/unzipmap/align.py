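"""Cross-correlation alignment of traces to a naked-DNA reference.

A measured trace differs from the reference by a small additive shift
(drift, bead size; |shift| <= 10 bp) and a multiplicative linear stretch
(linker variation; |stretch - 1| < 2%).  The fit is an exhaustive grid
search: stretch in steps of 0.001 and, at each stretch, the
correlation-maximizing shift on a 0.1 bp grid, scored by the normalized
(zero-mean, unit-variance per window) cross-correlation of forces over
protein-free windows, windows entering with equal weight.  Deterministic:
ties break toward smaller |shift|, then stretch closer to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import SHIFT_BOUND_BP, STRETCH_BOUND, SignatureModel
from .templates import TemplateLayout
from .trace import UnzipTrace

Window = Tuple[float, float]


@dataclass(frozen=True)
class AlignmentResult:
    shift_bp: float
    stretch: float
    score: float
    regions_used: Tuple[Window, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if abs(self.shift_bp) > SHIFT_BOUND_BP + 1e-9:
            raise ValueError("shift outside declared bounds")
        if abs(self.stretch - 1.0) > STRETCH_BOUND + 1e-9:
            raise ValueError("stretch outside declared bounds")
        if not -1.0 - 1e-9 <= self.score <= 1.0 + 1e-9:
            raise ValueError("score must be a normalized correlation in [-1, 1]")

    @classmethod
    def identity(cls) -> "AlignmentResult":
        return cls(0.0, 1.0, 1.0)


def select_alignment_regions(trace: Optional[UnzipTrace],
                             layout: TemplateLayout,
                             signature: Optional[SignatureModel] = None,
                             min_len: float = 50.0,
                             guard: Optional[float] = None) -> List[Window]:
    """Protein-free windows flanking the expected signature regions.

    For an internal nucleosome this is the region immediately before the TF
    disruption plus the region after the nucleosome disruption; for an
    end-positioned nucleosome only the pre-signature window survives.
    Windows are given in reference (bp-unzipped) coordinates and shrunk by a
    guard that covers the declared distortion box.
    """
    signature = signature or SignatureModel()
    n = layout.template_len
    if guard is None:
        guard = SHIFT_BOUND_BP + 2.0 + STRETCH_BOUND * n

    pad = 3.0 * signature.bump_scale_bp
    sub_lo = min(signature.cluster_subpeak_offsets)
    sub_hi = max(signature.cluster_subpeak_offsets)
    dyad_u = layout.dyad0_unzip
    nuc_lo = dyad_u + signature.nuc_cluster1_offset + sub_lo - pad
    nuc_hi = dyad_u + signature.nuc_cluster2_offset + sub_hi + pad \
        + signature.relax_bp * 3.0

    if layout.tf_center_unzip is not None:
        tf_peak = layout.tf_center_unzip - signature.tf_peak_offset
        first_lo = min(tf_peak - pad, nuc_lo)
    else:
        first_lo = nuc_lo

    candidates = [(guard, first_lo - guard), (nuc_hi + guard, n - 1 - guard)]
    windows = [(lo, hi) for lo, hi in candidates if hi - lo >= min_len]
    if not windows:
        raise ValueError("no protein-free window of sufficient length; "
                         "signatures cover the whole template")
    return windows


def _window_slices(positions: np.ndarray,
                   windows: Sequence[Window]) -> List[np.ndarray]:
    slices = []
    for lo, hi in windows:
        idx = np.flatnonzero((positions >= lo) & (positions <= hi))
        if idx.size < 3:
            raise ValueError(f"window ({lo}, {hi}) contains too few samples")
        slices.append(idx)
    return slices


def fit_shift_stretch(trace: UnzipTrace,
                      reference: UnzipTrace,
                      windows: Optional[Sequence[Window]] = None,
                      shift_bound: float = SHIFT_BOUND_BP,
                      stretch_bound: float = STRETCH_BOUND,
                      shift_step: float = 0.1,
                      stretch_step: float = 0.001) -> AlignmentResult:
    """Grid-search the (shift, stretch) maximizing windowed correlation.

    The trace model is ``x_trace = stretch * x_reference + shift``; the score
    interpolates the trace at the mapped reference window positions.
    """
    if windows is None:
        windows = [(reference.positions[0], reference.positions[-1])]
    idx_windows = _window_slices(reference.positions, windows)

    ref_z = []
    for idx in idx_windows:
        vals = reference.forces[idx]
        sd = vals.std()
        if sd < 1e-12:
            raise ValueError("degenerate (constant) alignment window")
        ref_z.append((vals - vals.mean()) / sd)

    n_shift = int(round(2 * shift_bound / shift_step)) + 1
    n_stretch = int(round(2 * stretch_bound / stretch_step)) + 1
    shifts = np.linspace(-shift_bound, shift_bound, n_shift)
    stretches = np.linspace(1.0 - stretch_bound, 1.0 + stretch_bound, n_stretch)

    xw = [reference.positions[idx] for idx in idx_windows]
    best = (-np.inf, np.inf, np.inf, 0.0, 1.0)  # score, |shift|, |stretch-1|
    for s in stretches:
        scores = np.zeros(n_shift)
        for x, rz in zip(xw, ref_z):
            pts = (s * x)[None, :] + shifts[:, None]
            vals = np.interp(pts.ravel(), trace.positions, trace.forces)
            vals = vals.reshape(n_shift, x.size)
            vals = vals - vals.mean(axis=1, keepdims=True)
            sd = vals.std(axis=1)
            sd[sd < 1e-12] = np.inf
            scores += (vals @ rz) / (sd * x.size)
        scores /= len(xw)
        j = int(np.argmax(scores))
        # prefer smaller |shift| among ties at this stretch
        ties = np.flatnonzero(scores >= scores[j] - 1e-12)
        j = ties[np.argmin(np.abs(shifts[ties]))]
        cand = (scores[j], abs(shifts[j]), abs(s - 1.0), shifts[j], s)
        if (cand[0] > best[0] + 1e-12
                or (abs(cand[0] - best[0]) <= 1e-12
                    and (cand[1], cand[2]) < (best[1], best[2]))):
            best = cand
    return AlignmentResult(float(best[3]), float(best[4]), float(min(best[0], 1.0)),
                           tuple(windows))


def apply_alignment(trace: UnzipTrace,
                    result: AlignmentResult,
                    reference: Optional[UnzipTrace] = None) -> UnzipTrace:
    """Map positions x -> (x - shift)/stretch and resample onto the reference grid."""
    inv = (trace.positions - result.shift_bp) / result.stretch
    if reference is not None:
        grid = reference.positions
    else:
        grid = np.arange(np.ceil(inv[0]), np.floor(inv[-1]) + 1.0)
    sample_at = result.stretch * grid + result.shift_bp
    forces = np.interp(sample_at, trace.positions, trace.forces)
    time_s = None
    if trace.time_s is not None:
        time_s = np.interp(sample_at, trace.positions, trace.time_s)
    meta = dict(trace.meta)
    meta.update(align_shift_bp=result.shift_bp, align_stretch=result.stretch,
                align_score=result.score)
    return UnzipTrace(np.asarray(grid, dtype=float), forces, time_s, meta)
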