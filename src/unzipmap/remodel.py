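"""Remodeling-ensemble simulation: Poisson event counts + displacement rules.

A remodeling reaction applies K ~ Poisson(lambda) sequential events to each
molecule; lambda depends on the reaction duration (short ~1 min reactions
leave most nucleosomes unremodeled, long ~10 min reactions drive multiple
rounds).  ISW1a treats a bound TF and the template ends as barriers and
pulls the dyad toward the midpoint of the accessible segment; SWI/SNF takes
unbounded Gaussian steps, ignores the TF and evicts it the first time the
swept nucleosome footprint overlaps the TF footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .models import InstrumentModel, RemodelerModel, SignatureModel
from .simulate import simulate_trace
from .templates import NUC_HALF_FOOTPRINT, TemplateLayout
from .trace import UnzipTrace


@dataclass
class EnsembleDataset:
    """Per-molecule truth (and, optionally, rendered traces) of one reaction."""
    layout: TemplateLayout
    remodeler: RemodelerModel
    duration_class: str
    table: pd.DataFrame                      # one row per molecule
    event_logs: List[List[dict]] = field(default_factory=list)
    traces: Optional[List[UnzipTrace]] = None

    def __len__(self) -> int:
        return len(self.table)


def _allowed_dyad_interval(layout: TemplateLayout, tf_bound: bool):
    lo = float(NUC_HALF_FOOTPRINT)
    hi = float(layout.template_len - 1 - NUC_HALF_FOOTPRINT)
    if tf_bound and layout.tf_center is not None:
        tf_lo, tf_hi = layout.tf_edges
        if layout.dyad0 >= layout.tf_center:
            lo = max(lo, tf_hi + NUC_HALF_FOOTPRINT + 1)
        else:
            hi = min(hi, tf_lo - NUC_HALF_FOOTPRINT - 1)
    return lo, hi


def accessible_midpoint(layout: TemplateLayout, tf_bound: bool = True) -> float:
    """Midpoint of the DNA segment between the TF footprint edge and the
    template end on the nucleosome's side (the whole template without a TF)."""
    if tf_bound and layout.tf_center is not None:
        tf_lo, tf_hi = layout.tf_edges
        if layout.dyad0 >= layout.tf_center:
            return 0.5 * (tf_hi + (layout.template_len - 1))
        return 0.5 * (0 + tf_lo)
    return 0.5 * (layout.template_len - 1)


def _sweep_overlaps_tf(layout: TemplateLayout, d_from: float, d_to: float) -> bool:
    if layout.tf_center is None:
        return False
    tf_lo, tf_hi = layout.tf_edges
    lo = min(d_from, d_to) - NUC_HALF_FOOTPRINT
    hi = max(d_from, d_to) + NUC_HALF_FOOTPRINT
    return lo <= tf_hi and hi >= tf_lo


def _isw1a_event(layout: TemplateLayout, dyad: float, tf_bound: bool,
                 model: RemodelerModel, rng: np.random.Generator) -> float:
    lo, hi = _allowed_dyad_interval(layout, tf_bound)
    target = accessible_midpoint(layout, tf_bound)
    target = float(np.clip(target, lo, hi))
    for _ in range(100):
        cand = dyad + model.isw1a_pull * (target - dyad) \
            + rng.normal(0.0, model.step_sd_bp)
        if lo <= cand <= hi and not (
                tf_bound and _sweep_overlaps_tf(layout, dyad, cand)):
            return float(cand)
    return float(np.clip(dyad + model.isw1a_pull * (target - dyad), lo, hi))


def _swisnf_event(layout: TemplateLayout, dyad: float, tf_bound: bool,
                  model: RemodelerModel, rng: np.random.Generator) -> float:
    # Each event is a fresh remodeler binding; while a TF is bound nearby the
    # linker-sensing subunit orients sliding toward it with probability
    # ``swisnf_asymmetry``, otherwise steps are direction-symmetric.
    lo = float(NUC_HALF_FOOTPRINT)
    hi = float(layout.template_len - 1 - NUC_HALF_FOOTPRINT)
    for _ in range(100):
        step = abs(rng.normal(0.0, model.step_sd_bp))
        if tf_bound and layout.tf_center is not None:
            toward = -1.0 if layout.tf_center < dyad else 1.0
            sign = toward if rng.random() < model.swisnf_asymmetry else -toward
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        cand = dyad + sign * step
        if lo <= cand <= hi:
            return float(cand)
    return float(np.clip(dyad, lo, hi))


def simulate_remodeling_ensemble(layout: TemplateLayout,
                                 remodeler: RemodelerModel,
                                 n: int,
                                 duration_class: str = "short",
                                 seed: int = 0,
                                 tf_bound_fraction: float = 1.0,
                                 render: bool = False,
                                 signature: Optional[SignatureModel] = None,
                                 instrument: Optional[InstrumentModel] = None
                                 ) -> EnsembleDataset:
    """Simulate ``n`` molecules through one remodeling reaction.

    ``tf_bound_fraction`` sets the initial TF occupancy (the experiments ran
    at ~95% site occupancy; 1.0 when every molecule starts bound, 0.0 for
    TF-free controls on a TF-site template).  Each molecule gets a sub-seed
    spawned from ``seed`` and is recorded with its event log.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = remodeler.event_rate(duration_class)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)

    rows = []
    logs: List[List[dict]] = []
    traces: Optional[List[UnzipTrace]] = [] if render else None
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        tf_initial = bool(rng.random() < tf_bound_fraction) \
            if layout.tf_center is not None else False
        tf_now = tf_initial
        dyad = float(layout.dyad0)
        k = int(rng.poisson(lam)) if remodeler.kind != "none" else 0
        log: List[dict] = []
        for ev in range(k):
            if remodeler.kind == "isw1a":
                new = _isw1a_event(layout, dyad, tf_now, remodeler, rng)
                overlapped = False
            else:
                new = _swisnf_event(layout, dyad, tf_now, remodeler, rng)
                overlapped = _sweep_overlaps_tf(layout, dyad, new)
                if overlapped and tf_now and remodeler.evict_on_overlap:
                    tf_now = False
            log.append({"event": ev, "dyad_from": dyad, "dyad_to": new,
                        "overlapped_tf": overlapped})
            dyad = new
        rows.append({
            "molecule_id": i,
            "initial_dyad": float(layout.dyad0),
            "final_dyad": dyad,
            "tf_initial": tf_initial,
            "tf_final": tf_now,
            "n_events": k,
            "sub_seed": int(child.generate_state(1)[0] % (2 ** 31)),
        })
        logs.append(log)
        if render:
            mol_layout = layout.with_dyad(dyad)
            traces.append(simulate_trace(mol_layout, (tf_now, True),
                                         signature, instrument, rng))
    table = pd.DataFrame(rows)
    return EnsembleDataset(layout, remodeler, duration_class, table, logs, traces)
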