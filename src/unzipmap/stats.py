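"""Population-level statistics over per-molecule calls.

Covers the quantities a remodeling unzipping study reports: position
histograms in dyad coordinates, the double-Gaussian decomposition of dyad
distributions into unremodeled (narrow) and remodeled (broad) fractions,
conditional Poisson event fractions (remodeled once vs more than once),
binding-isotherm (Kd) fits, occupancy-vs-time stability, detection
precision/accuracy, barrier-centering statistics and
directionality/eviction summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator

from .titration import TitrationDataset, isotherm


# --------------------------------------------------------------------------
# histograms
# --------------------------------------------------------------------------

def position_histogram(positions: Sequence[float],
                       bin_bp: float = 5.0,
                       origin: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Counts per bin in dyad-origin coordinates.

    Bins are centered so that ``origin`` falls at a bin center: a 5 bp bin
    collects [-2.5, 2.5) around the origin.
    """
    positions = np.asarray(positions, dtype=float) - origin
    if positions.size == 0:
        return np.array([]), np.array([])
    lo = math.floor((positions.min() + bin_bp / 2) / bin_bp) - 1
    hi = math.floor((positions.max() + bin_bp / 2) / bin_bp) + 1
    edges = (np.arange(lo, hi + 1) - 0.5) * bin_bp + origin
    counts, edges = np.histogram(positions + origin, bins=edges)
    return counts, edges


# --------------------------------------------------------------------------
# double-Gaussian mixture (unremodeled / remodeled decomposition)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureFit:
    w_unremodeled: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    converged: bool
    loglik: float
    degenerate: bool = False


class DoubleGaussianMixture(BaseEstimator):
    """Two-component 1-D normal mixture with the narrow component first.

    The narrow component (sigma1 <= sigma2 by relabeling) represents
    unremodeled nucleosomes scattered only by measurement noise; the broad
    one represents remodeled nucleosomes.  Fitting is maximum likelihood by
    EM from a fixed list of starts (mu1 initialized at 0, the designed dyad),
    so the result is deterministic given the data.  A ``hist`` mode fits the
    same model by least squares on a binned histogram instead.

    Attributes (after ``fit``): ``weights_``, ``means_``, ``sigmas_`` (narrow
    first), ``weight_narrow_``, ``converged_``, ``loglik_``, ``degenerate_``.
    """

    def __init__(self, mode: str = "mle", bin_bp: float = 5.0,
                 max_iter: int = 500, tol: float = 1e-10,
                 degenerate_sigma_ratio: float = 1.5,
                 min_sigma: float = 0.5):
        self.mode = mode
        self.bin_bp = bin_bp
        self.max_iter = max_iter
        self.tol = tol
        self.degenerate_sigma_ratio = degenerate_sigma_ratio
        # positions are measurement-limited to a fraction of a bp; a
        # component narrower than this is a numerical spike, not a population
        self.min_sigma = min_sigma

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _loglik(x, w, m1, s1, m2, s2):
        pdf = w * sps.norm.pdf(x, m1, s1) + (1 - w) * sps.norm.pdf(x, m2, s2)
        return float(np.sum(np.log(np.clip(pdf, 1e-300, None))))

    def _em(self, x, start):
        w, m1, s1, m2, s2 = start
        s_floor = max(self.min_sigma, 1e-3 * np.std(x))
        prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            p1 = w * sps.norm.pdf(x, m1, s1)
            p2 = (1 - w) * sps.norm.pdf(x, m2, s2)
            tot = np.clip(p1 + p2, 1e-300, None)
            r1 = p1 / tot
            n1 = r1.sum()
            n2 = x.size - n1
            if n1 < 1e-10 or n2 < 1e-10:
                break
            w = n1 / x.size
            m1 = float(np.sum(r1 * x) / n1)
            m2 = float(np.sum((1 - r1) * x) / n2)
            s1 = max(s_floor, math.sqrt(float(np.sum(r1 * (x - m1) ** 2) / n1)))
            s2 = max(s_floor, math.sqrt(float(np.sum((1 - r1) * (x - m2) ** 2) / n2)))
            ll = self._loglik(x, w, m1, s1, m2, s2)
            if abs(ll - prev) < self.tol * (1 + abs(ll)):
                converged = True
                prev = ll
                break
            prev = ll
        return (w, m1, s1, m2, s2), prev, converged

    def _fit_hist(self, x):
        counts, edges = position_histogram(x, self.bin_bp, origin=0.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        scale = max(np.std(x), 1e-6)
        amp = x.size * self.bin_bp

        def model(c, w, m1, ls1, m2, ls2):
            return amp * (w * sps.norm.pdf(c, m1, np.exp(ls1))
                          + (1 - w) * sps.norm.pdf(c, m2, np.exp(ls2)))

        p0 = (0.5, 0.0, math.log(max(scale / 5, 1e-3)),
              float(np.mean(x)), math.log(scale))
        bounds = ([0.0, -np.inf, -np.inf, -np.inf, -np.inf],
                  [1.0, np.inf, np.inf, np.inf, np.inf])
        try:
            popt, _ = optimize.curve_fit(model, centers, counts, p0=p0,
                                         bounds=bounds, maxfev=20000)
            w, m1, ls1, m2, ls2 = popt
            return (w, m1, math.exp(ls1), m2, math.exp(ls2)), True
        except RuntimeError:
            return p0[:2] + (math.exp(p0[2]), p0[3], math.exp(p0[4])), False

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        if x.size < 20:
            raise ValueError("need at least 20 positions for a mixture fit")
        if self.mode not in ("mle", "hist"):
            raise ValueError("mode must be 'mle' or 'hist'")

        if self.mode == "hist":
            (w, m1, s1, m2, s2), converged = self._fit_hist(x)
            ll = self._loglik(x, w, m1, s1, m2, s2)
        else:
            scale = max(np.std(x), 1e-6)
            mean = float(np.mean(x))
            starts = [
                (0.5, 0.0, scale / 10, mean, scale),
                (0.7, 0.0, scale / 4, mean, 1.5 * scale),
                (0.3, 0.0, scale / 2, mean, 2.0 * scale),
                (0.9, 0.0, scale / 10, mean, 2.0 * scale),
            ]
            best, ll, converged = None, -np.inf, False
            for start in starts:
                params, cur, conv = self._em(x, start)
                if cur > ll:
                    best, ll, converged = params, cur, conv
            w, m1, s1, m2, s2 = best

        if s1 > s2:  # narrow component first
            w, m1, s1, m2, s2 = 1 - w, m2, s2, m1, s1
        # a second component is degenerate when a single Gaussian explains
        # the data at least as well (BIC), or it carries no weight
        single_ll = self._loglik(x, 1.0, float(np.mean(x)),
                                 max(float(np.std(x)), 1e-6), 0.0, 1.0)
        bic_single = 2 * math.log(x.size) - 2 * single_ll
        bic_mixture = 5 * math.log(x.size) - 2 * ll
        self.degenerate_ = bool(bic_single <= bic_mixture
                                or (1 - w) < 1e-3
                                or s2 < self.degenerate_sigma_ratio * s1)
        self.weight_narrow_ = 1.0 if self.degenerate_ else float(w)
        self.weights_ = np.array([w, 1 - w])
        self.means_ = np.array([m1, m2])
        self.sigmas_ = np.array([s1, s2])
        self.converged_ = bool(converged)
        self.loglik_ = float(ll)
        return self

    def predict_proba(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        p1 = self.weights_[0] * sps.norm.pdf(x, self.means_[0], self.sigmas_[0])
        p2 = self.weights_[1] * sps.norm.pdf(x, self.means_[1], self.sigmas_[1])
        tot = np.clip(p1 + p2, 1e-300, None)
        return np.column_stack([p1 / tot, p2 / tot])

    def predict(self, X):
        """0 = unremodeled (narrow), 1 = remodeled (broad)."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def result(self) -> MixtureFit:
        return MixtureFit(
            w_unremodeled=self.weight_narrow_,
            mu1=float(self.means_[0]), sigma1=float(self.sigmas_[0]),
            mu2=float(self.means_[1]), sigma2=float(self.sigmas_[1]),
            converged=self.converged_, loglik=self.loglik_,
            degenerate=self.degenerate_)


def fit_double_gaussian(positions: Sequence[float],
                        mode: str = "mle",
                        bin_bp: float = 5.0) -> MixtureFit:
    est = DoubleGaussianMixture(mode=mode, bin_bp=bin_bp).fit(positions)
    return est.result()


# --------------------------------------------------------------------------
# conditional Poisson event fractions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EventFractions:
    p0: float
    lam: float
    frac_once: float
    frac_multi: float


def poisson_event_fractions(p0: float) -> EventFractions:
    """Fractions remodeled once / more than once from the unremodeled fraction.

    With event counts K ~ Poisson(lambda), P(K=0) = p0 fixes
    lambda = -ln(p0); among remodeled molecules (K >= 1),
    P(K=1 | K>=1) = lambda e^-lambda / (1 - e^-lambda).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    lam = -math.log(p0)
    frac_once = lam * math.exp(-lam) / (1.0 - math.exp(-lam))
    return EventFractions(p0, lam, frac_once, 1.0 - frac_once)


# --------------------------------------------------------------------------
# binding isotherm (Kd)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KdFit:
    kd_nM: float
    stderr_nM: float
    fractions: pd.DataFrame  # concentration, fraction, binomial se


class BindingIsotherm(BaseEstimator):
    """Least-squares fit of the single-site isotherm f = c / (c + Kd).

    ``fit(concentrations, fractions)``; fitted attributes ``kd_``
    (nM) and ``kd_stderr_`` (from the Jacobian).
    """

    def __init__(self, p0_nM: Optional[float] = None):
        self.p0_nM = p0_nM

    def fit(self, X, y, sample_weight=None):
        c = np.asarray(X, dtype=float).reshape(-1)
        f = np.asarray(y, dtype=float).reshape(-1)
        if c.size < 3:
            raise ValueError("need at least 3 concentrations")
        if f.min() > 0.95 or f.max() < 0.05:
            raise ValueError("Kd unidentifiable: fractions do not span the "
                             "binding transition")
        p0 = self.p0_nM if self.p0_nM is not None else float(np.median(c))
        popt, pcov = optimize.curve_fit(isotherm, c, f, p0=[p0],
                                        bounds=(0.0, np.inf), maxfev=10000,
                                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
        self.kd_ = float(popt[0])
        self.kd_stderr_ = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) \
            else float("nan")
        return self

    def predict(self, X):
        return isotherm(np.asarray(X, dtype=float), self.kd_)


def fit_binding_isotherm(titration: TitrationDataset) -> KdFit:
    est = BindingIsotherm().fit(titration.concentrations_nM, titration.fractions)
    frame = pd.DataFrame({
        "concentration_nM": titration.concentrations_nM,
        "fraction_bound": titration.fractions,
        "binomial_se": titration.binomial_se,
    })
    return KdFit(est.kd_, est.kd_stderr_, frame)


# --------------------------------------------------------------------------
# occupancy stability over time
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyTrend:
    slope_per_s: float
    intercept: float
    slope_ci: Tuple[float, float]
    stable: bool   # True when the 95% CI of the slope covers zero


def fit_occupancy_vs_time(times: Sequence[float],
                          fractions: Sequence[float],
                          alpha: float = 0.05) -> OccupancyTrend:
    t = np.asarray(times, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    res = sps.linregress(t, f)
    if t.size > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        half = sps.t.ppf(1 - alpha / 2, t.size - 2) * res.stderr
    else:
        half = float("inf") if t.size <= 2 else 0.0
    ci = (res.slope - half, res.slope + half)
    return OccupancyTrend(float(res.slope), float(res.intercept),
                          (float(ci[0]), float(ci[1])),
                          bool(ci[0] <= 0.0 <= ci[1]))


# --------------------------------------------------------------------------
# precision / accuracy, centering, directionality
# --------------------------------------------------------------------------

def precision_accuracy(calls: Sequence[float], expected_position: float) -> dict:
    """Accuracy = mean(call) - expected (bias); precision = sample sd."""
    calls = np.asarray(calls, dtype=float)
    if calls.size < 2:
        raise ValueError("need at least 2 calls")
    return {"bias": float(np.mean(calls) - expected_position),
            "sd": float(np.std(calls, ddof=1))}


def bootstrap_se(values: Sequence[float],
                 stat: Callable[[np.ndarray], float] = np.mean,
                 n_boot: int = 1000, seed: int = 0) -> float:
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    reps = [stat(values[rng.integers(0, values.size, values.size)])
            for _ in range(n_boot)]
    return float(np.std(reps, ddof=1))


@dataclass(frozen=True)
class CenteringSummary:
    midpoint: float
    mean_deviation: float
    se_deviation: float
    mean_distance_moved: float
    se_distance_moved: float
    deviations: np.ndarray = field(repr=False)
    distances_moved: np.ndarray = field(repr=False)
    outlier_mask: np.ndarray = field(repr=False)


def centering_statistic(dyad_calls: Sequence[float],
                        tf_edge: float,
                        template_end: float,
                        initial_dyads: Optional[Sequence[float]] = None,
                        tf_bound: Optional[Sequence[bool]] = None,
                        exclude_outliers: bool = False,
                        seed: int = 0) -> CenteringSummary:
    """How far final dyads sit from the accessible-segment midpoint.

    The accessible segment runs from the TF footprint edge to the template
    end on the nucleosome side.  Outliers are molecules whose dyad passed the
    TF barrier or that lack a bound TF (in the experiments these are the ~5%
    of templates that never bound the TF); they are kept by default and only
    flagged.  Standard errors are seeded bootstrap.
    """
    final = np.asarray(dyad_calls, dtype=float)
    midpoint = 0.5 * (tf_edge + template_end)
    toward_end = 1.0 if template_end >= tf_edge else -1.0
    passed = toward_end * (final - tf_edge) < 0
    outlier = passed.copy()
    if tf_bound is not None:
        outlier |= ~np.asarray(tf_bound, dtype=bool)
    keep = ~outlier if exclude_outliers else np.ones_like(outlier, dtype=bool)
    dev = final - midpoint
    if initial_dyads is not None:
        moved = np.abs(final - np.asarray(initial_dyads, dtype=float))
    else:
        moved = np.full_like(final, np.nan)
    dev_k, moved_k = dev[keep], moved[keep]
    moved_k = moved_k[~np.isnan(moved_k)]
    return CenteringSummary(
        midpoint=float(midpoint),
        mean_deviation=float(np.mean(dev_k)),
        se_deviation=bootstrap_se(dev_k, seed=seed),
        mean_distance_moved=float(np.mean(moved_k)) if moved_k.size else float("nan"),
        se_distance_moved=bootstrap_se(moved_k, seed=seed + 1)
        if moved_k.size else float("nan"),
        deviations=dev, distances_moved=moved, outlier_mask=outlier)


def directionality_and_eviction_summary(table: pd.DataFrame,
                                        tf_center: float,
                                        moved_tol_bp: float = 2.0) -> dict:
    """Classify remodeled molecules by displacement relative to the TF.

    ``table`` needs columns ``initial_dyad``, ``final_dyad`` and ``tf_final``
    (per-molecule TF state after the reaction, from calls or truth).
    Fractions are over remodeled molecules (|final - initial| > tolerance).
    """
    initial = table["initial_dyad"].to_numpy(dtype=float)
    final = table["final_dyad"].to_numpy(dtype=float)
    tf_final = table["tf_final"].to_numpy(dtype=bool)
    remodeled = np.abs(final - initial) > moved_tol_bp
    n_rem = int(remodeled.sum())
    if n_rem == 0:
        return {"n_remodeled": 0, "frac_toward_tf": float("nan"),
                "frac_away": float("nan"), "frac_tf_retained": float("nan"),
                "frac_passed_tf": float("nan")}
    d0 = np.abs(initial - tf_center)
    d1 = np.abs(final - tf_center)
    toward = (d1 < d0)[remodeled]
    passed = (np.sign(final - tf_center) != np.sign(initial - tf_center))[remodeled]
    return {
        "n_remodeled": n_rem,
        "frac_toward_tf": float(np.mean(toward)),
        "frac_away": float(np.mean(~toward)),
        "frac_tf_retained": float(np.mean(tf_final[remodeled])),
        "frac_passed_tf": float(np.mean(passed)),
    }
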