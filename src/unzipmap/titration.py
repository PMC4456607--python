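"""Equilibrium binding titration: synthetic fraction-bound data.

Each molecule at ligand concentration c is bound with probability
c / (c + Kd) (single-site isotherm), so per-concentration bound counts are
binomial draws.  This is the generative model behind the fitted dissociation
constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np


@dataclass(frozen=True)
class TitrationDataset:
    concentrations_nM: np.ndarray
    n_per_conc: np.ndarray
    bound_counts: np.ndarray
    true_kd_nM: float

    @property
    def fractions(self) -> np.ndarray:
        return self.bound_counts / self.n_per_conc

    @property
    def binomial_se(self) -> np.ndarray:
        f = self.fractions
        return np.sqrt(np.clip(f * (1.0 - f), 0.0, None) / self.n_per_conc)


def isotherm(c, kd):
    """Fraction bound c/(c + Kd); at c = Kd exactly one half."""
    c = np.asarray(c, dtype=float)
    return c / (c + kd)


def simulate_binding_titration(concentrations_nM: Sequence[float],
                               true_kd_nM: float,
                               n_per_conc: Union[int, Sequence[int]] = 30,
                               seed: int = 0) -> TitrationDataset:
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if true_kd_nM < 0:
        raise ValueError("Kd must be non-negative")
    n = np.broadcast_to(np.asarray(n_per_conc, dtype=int), conc.shape).copy()
    if np.any(n < 1):
        raise ValueError("n_per_conc must be >= 1")
    rng = np.random.default_rng(seed)
    p = isotherm(conc, true_kd_nM)
    counts = rng.binomial(n, p)
    return TitrationDataset(conc, n, counts, float(true_kd_nM))
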