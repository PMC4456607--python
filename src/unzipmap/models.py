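"""Parameter models for the trace generator and the instrument.

The generator is a threshold model: every base pair carries a disruption
threshold (a naked-DNA baseline draw, elevated inside protein-bound regions);
the unzipping fork advances while the applied force exceeds the local
threshold and otherwise the force ramps linearly in time (loading-rate
clamp).  After each disruption the excess force relaxes back toward the
baseline exponentially with a bp constant, so interactions in close vicinity
start from a higher initial force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Tuple

#: hard bounds of the declared instrument distortion box; the alignment
#: search must cover everything the generator can produce.
SHIFT_BOUND_BP = 10.0
STRETCH_BOUND = 0.02


def _filtered_white_noise_sd(sigma_bp: float) -> float:
    """sd of unit white noise after a Gaussian filter of width ``sigma_bp``."""
    return (2.0 * sigma_bp * math.sqrt(math.pi)) ** -0.5


@dataclass(frozen=True)
class SignatureModel:
    """Force-signature parameters of the naked DNA, the TF and the nucleosome.

    The naked baseline is a stationary stochastic surrogate for the
    sequence-dependent unzipping force: mean ~15 pN with smoothed bp-to-bp
    variation (``baseline_sd``, correlation length ``baseline_corr_bp``).
    The TF is one force bump whose peak (18-20 pN) sits ``tf_peak_offset`` bp
    before the site center along the unzipping direction.  The nucleosome is
    two clusters of larger bumps; the prominence-weighted centroid of the
    first cluster sits 43 bp before the dyad, the second 5 bp after it.

    Each cluster is built from Laplace-shaped sub-peaks at integer offsets
    with decreasing relative amplitudes.  The last amplitude is solved so the
    prominence-weighted centroid is exact, and the Laplace decay scale equals
    the relaxation constant so the recorded falling flank coincides with the
    post-disruption relaxation curve — both choices make the 8 bp / 43 bp
    calling conventions exact on noiseless input.
    """

    baseline_mean: float = 15.0
    baseline_sd: float = 1.0
    baseline_corr_bp: float = 3.0
    tf_peak_force_range: Tuple[float, float] = (18.0, 20.0)
    tf_peak_offset: float = 8.0
    nuc_cluster1_offset: float = -43.0
    nuc_cluster2_offset: float = 5.0
    cluster_peak_force_range: Tuple[float, float] = (25.0, 35.0)
    cluster_subpeak_offsets: Tuple[int, ...] = (-9, -4, 1, 6, 11)
    cluster_subpeak_weights: Tuple[float, ...] = (1.0, 0.9, 0.85, 0.8)
    bump_scale_bp: float = 5.0
    relax_bp: float = 5.0

    def __post_init__(self) -> None:
        if self.tf_peak_force_range[0] <= self.baseline_mean:
            raise ValueError("TF peak forces must exceed the naked baseline")
        if self.cluster_peak_force_range[0] <= self.tf_peak_force_range[1]:
            raise ValueError("nucleosome cluster peaks must exceed TF peaks")
        if len(self.cluster_subpeak_offsets) != len(self.cluster_subpeak_weights) + 1:
            raise ValueError("need exactly one more sub-peak offset than weights "
                             "(the last amplitude is solved for centroid balance)")
        w_last = self._solved_last_weight()
        if not 0.0 < w_last < self.cluster_subpeak_weights[-1]:
            raise ValueError("sub-peak layout cannot be balanced with a "
                             "decreasing amplitude profile")
        if self.relax_bp <= 0 or self.bump_scale_bp <= 0:
            raise ValueError("relaxation and bump scales must be positive")

    def _solved_last_weight(self) -> float:
        offs = self.cluster_subpeak_offsets
        w = self.cluster_subpeak_weights
        num = -sum(wk * dk for wk, dk in zip(w, offs[:-1]))
        return num / offs[-1]

    @property
    def balanced_subpeak_weights(self) -> Tuple[float, ...]:
        """Relative sub-peak amplitudes, zero prominence-weighted mean offset."""
        return tuple(self.cluster_subpeak_weights) + (self._solved_last_weight(),)

    def noiseless(self) -> "SignatureModel":
        """Deterministic variant: flat baseline, mid-range peak forces."""
        tf_mid = sum(self.tf_peak_force_range) / 2.0
        cl_mid = sum(self.cluster_peak_force_range) / 2.0
        return replace(self, baseline_sd=0.0,
                       tf_peak_force_range=(tf_mid, tf_mid),
                       cluster_peak_force_range=(cl_mid, cl_mid))


@dataclass(frozen=True)
class InstrumentModel:
    """Loading-rate clamp and acquisition parameters.

    The force ramps at ``ramp_rate_pN_s`` whenever the fork stalls; data are
    acquired at ~12 kHz and low-passed to 60 Hz.  The reduced force-vs-position
    record is modelled directly: measurement noise is applied per bp with sd
    ``force_noise_sd`` (the post-filter level) and correlation length
    ``noise_corr_bp`` emulating the output bandwidth.  ``velocity_bp_s`` is
    the fork speed between stalls and only affects dwell times.
    """

    ramp_rate_pN_s: float = 15.0
    sample_rate_hz: float = 12000.0
    output_bandwidth_hz: float = 60.0
    force_noise_sd: float = 0.15
    noise_corr_bp: float = 2.0
    velocity_bp_s: float = 200.0
    shift_bp: float = 0.0
    stretch: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ramp_rate_pN_s", "sample_rate_hz", "output_bandwidth_hz",
                     "velocity_bp_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.force_noise_sd < 0:
            raise ValueError("force_noise_sd must be non-negative")
        if abs(self.shift_bp) > SHIFT_BOUND_BP:
            raise ValueError(f"|shift_bp| must be <= {SHIFT_BOUND_BP} bp")
        if abs(self.stretch - 1.0) > STRETCH_BOUND + 1e-12:
            raise ValueError(f"|stretch - 1| must be < {STRETCH_BOUND}")

    def noiseless(self) -> "InstrumentModel":
        return replace(self, force_noise_sd=0.0)


@dataclass(frozen=True)
class RemodelerModel:
    """Phenomenological remodeler rules.

    Remodeling is a sequence of K ~ Poisson(lambda) events per molecule.
    ISW1a events pull the dyad toward the midpoint of the accessible segment
    (between the TF footprint edge, if a TF is bound, and the template end)
    and never place the nucleosome footprint across a bound TF footprint or
    off a template end.  SWI/SNF events are unbounded Gaussian displacements
    inside the template that ignore the TF; the TF is evicted the first time
    the swept footprint overlaps its own footprint.
    """

    kind: str = "none"  # none | isw1a | swisnf
    event_rate_short: float = -math.log(0.55)
    event_rate_long: float = 8.0
    step_sd_bp: float = 7.0
    isw1a_center_sd_bp: float = 8.0
    isw1a_pull: float = 0.5
    swisnf_asymmetry: float = 0.65
    evict_on_overlap: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("none", "isw1a", "swisnf"):
            raise ValueError("kind must be 'none', 'isw1a' or 'swisnf'")
        if self.event_rate_short < 0 or self.event_rate_long < 0:
            raise ValueError("event rates (Poisson means) must be >= 0")
        if not 0.0 <= self.swisnf_asymmetry <= 1.0:
            raise ValueError("swisnf_asymmetry is a probability")
        if not 0.0 < self.isw1a_pull <= 1.0:
            raise ValueError("isw1a_pull must be in (0, 1]")

    def event_rate(self, duration_class: str) -> float:
        if duration_class == "short":
            return self.event_rate_short
        if duration_class == "long":
            return self.event_rate_long
        raise ValueError("duration_class must be 'short' or 'long'")

    @classmethod
    def none(cls) -> "RemodelerModel":
        return cls(kind="none", event_rate_short=0.0, event_rate_long=0.0)

    @classmethod
    def isw1a(cls, **kw) -> "RemodelerModel":
        return cls(kind="isw1a", step_sd_bp=kw.pop("step_sd_bp", 7.0), **kw)

    @classmethod
    def swisnf(cls, **kw) -> "RemodelerModel":
        # long reactions turn over enough rounds to randomize nucleosome
        # positions along the whole template (~60 bp steps x ~30 rounds)
        return cls(kind="swisnf", step_sd_bp=kw.pop("step_sd_bp", 60.0),
                   event_rate_long=kw.pop("event_rate_long", 30.0), **kw)
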