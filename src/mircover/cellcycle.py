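"""Cell-cycle phase fractions from propidium-iodide DNA-content histograms.

PI fluorescence is proportional to DNA content, so a cycling population
shows a 2N peak (G0/G1), a 4N peak (G2/M) at roughly twice the G1 mean,
and a plateau of S-phase cells replicating between the two.  The model
fitted here is a three-component mixture:

* G1: Normal(μ1, cv·μ1);
* G2/M: Normal(μ2, cv·μ2) with μ2 constrained to 2·μ1 within ±15%;
* S: uniform on [μ1, μ2] — cells between the peaks not attributable to
  either Gaussian.

The coefficient of variation cv is shared (stain noise scales with
intensity).  Fitting is by a safeguarded EM: the mixture-weight update is
always applied (it can only improve the likelihood), and the joint
location/shape update is accepted only when it does not decrease the
log-likelihood, so the likelihood trace is monotone by construction.
Initialisation is moment/histogram based and the whole fit is
deterministic, with fixed tolerance 1e-8 and at most 500 iterations.
Debris and doublets are handled by one trim-and-refit pass: after a
provisional fit, events outside [0.3·μ1, 1.3·μ2] are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .expression import anova_tukey

RATIO_BOUNDS = (1.7, 2.3)  # 4N/2N peak ratio constraint
EM_TOL = 1e-8
EM_MAX_ITER = 500
PHASES = ("g0g1", "s", "g2m")


@dataclass
class IntensityEvents:
    """Per-cell PI intensities for one condition."""

    condition: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 1-D array")
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be strictly positive")


@dataclass(frozen=True)
class PhaseFractions:
    """Estimated G0/G1, S and G2/M fractions plus the fitted mixture."""

    g0g1: float
    s: float
    g2m: float
    mu1: float
    mu2: float
    cv: float
    degenerate: bool = False
    log_likelihood_trace: Tuple[float, ...] = field(default=(), repr=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.g0g1, self.s, self.g2m])


def _initial_mu1(x: np.ndarray) -> float:
    """Locate the G1 peak: histogram mode, disambiguated against the 4N peak."""
    lo, hi = np.percentile(x, [1, 99])
    if hi <= lo:
        return float(np.median(x))
    hist, edges = np.histogram(x, bins=128, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[np.argmax(hist)])

    def events_near(v: float) -> int:
        w = 0.08 * v
        return int(np.sum((x > v - w) & (x < v + w)))

    # if the mode is the 4N peak, there is more mass at half the mode than
    # at twice the mode
    return mode / 2.0 if events_near(mode / 2.0) > events_near(2.0 * mode) else mode


def _log_likelihood(
    x: np.ndarray, w: np.ndarray, mu1: float, ratio: float, cv: float
) -> Tuple[float, Tuple[np.ndarray, ...]]:
    mu2 = ratio * mu1
    f1 = stats.norm.pdf(x, mu1, cv * mu1)
    f2 = stats.norm.pdf(x, mu2, cv * mu2)
    fs = np.where((x >= mu1) & (x <= mu2), 1.0 / (mu2 - mu1), 0.0)
    dens = np.maximum(w[0] * f1 + w[1] * fs + w[2] * f2, 1e-300)
    return float(np.sum(np.log(dens))), (f1, fs, f2, dens)


def _em_fit(x: np.ndarray) -> Tuple[np.ndarray, float, float, float, List[float]]:
    mu1 = _initial_mu1(x)
    ratio, cv = 2.0, 0.05
    w = np.array([0.5, 0.25, 0.25])
    ll, parts = _log_likelihood(x, w, mu1, ratio, cv)
    trace = [ll]
    for _ in range(EM_MAX_ITER):
        f1, fs, f2, dens = parts
        g1 = w[0] * f1 / dens
        gs = w[1] * fs / dens
        g2 = w[2] * f2 / dens
        w = np.array([g1.mean(), gs.mean(), g2.mean()])
        w = w / w.sum()

        n1, n2 = g1.sum(), g2.sum()
        m1 = float(np.sum(g1 * x) / max(n1, 1e-12))
        m2 = float(np.sum(g2 * x) / max(n2, 1e-12))
        ratio_new = float(np.clip(m2 / max(m1, 1e-12), *RATIO_BOUNDS))
        # joint weighted least-squares location under mu2 = ratio * mu1
        mu1_new = float(
            (np.sum(g1 * x) + ratio_new * np.sum(g2 * x)) / (n1 + ratio_new**2 * n2)
        )
        mu2_new = ratio_new * mu1_new
        var = float(
            (np.sum(g1 * (x - mu1_new) ** 2) / mu1_new**2 + np.sum(g2 * (x - mu2_new) ** 2) / mu2_new**2)
            / (n1 + n2)
        )
        cv_new = float(np.sqrt(max(var, 1e-12)))

        ll_weights, parts_weights = _log_likelihood(x, w, mu1, ratio, cv)
        ll_moved, parts_moved = _log_likelihood(x, w, mu1_new, ratio_new, cv_new)
        if ll_moved >= ll_weights:  # safeguarded generalized-EM step
            mu1, ratio, cv = mu1_new, ratio_new, cv_new
            ll, parts = ll_moved, parts_moved
        else:
            ll, parts = ll_weights, parts_weights
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < EM_TOL * (1.0 + abs(trace[-1])):
            break
    return w, mu1, ratio * mu1, cv, trace


DEGENERATE_G2M = 0.005  # below this fitted weight the 4N peak is called absent


def fit_phases(events: IntensityEvents) -> PhaseFractions:
    """Fit the constrained mixture and return phase fractions summing to 1.

    Requires at least 100 events.  A population without a resolvable 4N
    peak (including zero-variance input) is reported with ``g2m = 0`` and
    the ``degenerate`` flag set.
    """
    x = events.intensities
    if x.size < 100:
        raise ValueError(f"need >= 100 events to fit phases, got {x.size}")
    if np.ptp(x) == 0:  # single population at one intensity
        v = float(x[0])
        return PhaseFractions(1.0, 0.0, 0.0, v, 2 * v, 0.0, degenerate=True)

    w, mu1, mu2, cv, _ = _em_fit(x)
    keep = (x >= 0.3 * mu1) & (x <= 1.3 * mu2)  # debris / doublet trim
    if 100 <= keep.sum() < x.size:
        x = x[keep]
    w, mu1, mu2, cv, trace = _em_fit(x)

    degenerate = bool(w[2] < DEGENERATE_G2M)
    if degenerate:
        w = np.array([w[0], w[1], 0.0])
    w = w / w.sum()
    return PhaseFractions(
        g0g1=float(w[0]),
        s=float(w[1]),
        g2m=float(w[2]),
        mu1=float(mu1),
        mu2=float(mu2),
        cv=float(cv),
        degenerate=degenerate,
        log_likelihood_trace=tuple(trace),
    )


def compare_conditions(
    replicates: Dict[str, Sequence[PhaseFractions]],
) -> Dict[str, Tuple[float, Dict[Tuple[str, str], float]]]:
    """Per-phase one-way ANOVA (+ Tukey HSD) of replicate fraction estimates.

    ``replicates`` maps condition labels to >=3 :class:`PhaseFractions`
    each.  Returns phase → (ANOVA p, Tukey p per condition pair).
    """
    if len(replicates) < 2:
        raise ValueError("need at least two conditions to compare")
    for cond, reps in replicates.items():
        if len(reps) < 3:
            raise ValueError(f"condition {cond!r} needs >= 3 replicates, got {len(reps)}")
    out = {}
    for phase in PHASES:
        groups = {cond: [getattr(r, phase) for r in reps] for cond, reps in replicates.items()}
        out[phase] = anova_tukey(groups)
    return out
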