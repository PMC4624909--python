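"""Survey-design analysis: minimum detectable concentration and protocol
comparison.

The minimum detectable concentration (MDC) at a sensitivity goal ``g`` is
the smallest ambient concentration whose event sensitivity reaches ``g``.
Because sensitivity is strictly increasing in concentration, the MDC is
found by root bracketing on a log-concentration scale.  Protocol changes
are scored either as a sensitivity difference on a concentration grid
(paired Monte Carlo with common random numbers) or as a reduction in MDC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .model import (ExtractionModel, SamplingProtocol, BIGHEAD_CARP,
                    event_sensitivity, sample_positive_prob)
from .simulate import simulate_event

__all__ = [
    "DesignGoal",
    "StrategyComparison",
    "min_detectable_concentration",
    "delta_sensitivity",
    "mdc_reduction",
    "unit_increase_strategies",
]


@dataclass(frozen=True)
class DesignGoal:
    """Target event sensitivity, e.g. 0.95."""

    sensitivity_goal: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity_goal < 1:
            raise ValueError("sensitivity_goal must lie strictly in (0, 1)")


@dataclass
class StrategyComparison:
    """MDC comparison of a modified protocol against a baseline."""

    baseline: SamplingProtocol
    modified: SamplingProtocol
    goal: float
    mdc_baseline: float
    mdc_modified: float

    @property
    def reduction(self) -> float:
        """MDC(baseline) - MDC(modified); positive when the change helps."""
        return self.mdc_baseline - self.mdc_modified


def _sensitivity(concentration, protocol, assay, extraction, mode):
    p = sample_positive_prob(concentration, protocol, assay, extraction, mode=mode)
    return event_sensitivity(p, protocol.n_samples)


def min_detectable_concentration(goal=None, protocol=None, assay=BIGHEAD_CARP,
                                 extraction=None, mode="expected",
                                 bracket=(1e-2, 1e6), rtol=5e-3,
                                 method="semi-analytic", n_draws=50_000,
                                 seed=None) -> float:
    """Smallest concentration (copies/L) detected with probability >= goal.

    Parameters
    ----------
    goal : DesignGoal or float, default 0.95
    bracket : (low, high)
        Concentration search bracket; an error with a diagnostic is raised
        if the goal is not crossed inside it.
    rtol : float
        Relative tolerance on the returned concentration.
    method : {"semi-analytic", "mc"}
        "semi-analytic" performs deterministic bisection (Brent) on the
        closed-model sensitivity.  "mc" estimates sensitivity on a log
        grid with a shared seed (common random numbers), enforces
        monotonicity by isotonic pooling, and interpolates the goal
        crossing -- useful to mimic a purely simulation-based workflow.
    """
    if goal is None:
        goal = DesignGoal()
    elif not isinstance(goal, DesignGoal):
        goal = DesignGoal(float(goal))
    g = goal.sensitivity_goal
    protocol = protocol if protocol is not None else SamplingProtocol.baseline()
    extraction = extraction if extraction is not None else ExtractionModel()
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError(f"invalid bracket {bracket!r}")

    if method == "semi-analytic":
        f = lambda logc: _sensitivity(10.0 ** logc, protocol, assay, extraction, mode) - g
        f_lo, f_hi = f(np.log10(lo)), f(np.log10(hi))
        if f_lo >= 0:
            return lo  # goal already met at the lower bracket edge
        if f_hi < 0:
            raise ValueError(
                f"sensitivity at bracket top {hi:g} copies/L is {f_hi + g:.4f} "
                f"< goal {g}; widen the bracket or lower the goal")
        logc = optimize.brentq(f, np.log10(lo), np.log10(hi),
                               xtol=rtol / np.log(10.0) / 2)
        c = 10.0 ** logc
        # guarantee sensitivity(c) >= goal despite root-finding tolerance
        while _sensitivity(c, protocol, assay, extraction, mode) < g:
            c *= 1.0 + rtol / 4
        return float(c)

    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    grid = np.geomspace(lo, hi, 25)
    est = np.array([simulate_event(c, protocol, assay, extraction,
                                   n_draws=n_draws, seed=seed, mode=mode)[0]
                    for c in grid])
    # isotonic pooling (PAVA) to suppress Monte Carlo non-monotonicity
    iso = est.copy()
    for i in range(1, iso.size):
        if iso[i] < iso[i - 1]:
            iso[i] = iso[i - 1]
    if iso[0] >= g:
        return float(grid[0])
    if iso[-1] < g:
        raise ValueError(
            f"MC sensitivity at bracket top {hi:g} copies/L is {iso[-1]:.4f} "
            f"< goal {g}; widen the bracket or increase n_draws")
    j = int(np.searchsorted(iso, g))
    x0, x1 = np.log10(grid[j - 1]), np.log10(grid[j])
    y0, y1 = iso[j - 1], iso[j]
    frac = 0.0 if y1 == y0 else (g - y0) / (y1 - y0)
    return float(10.0 ** (x0 + frac * (x1 - x0)))


def delta_sensitivity(baseline, modified, assay=BIGHEAD_CARP, extraction=None,
                      grid=None, n_draws=50_000, seed=None,
                      mode="expected") -> pd.DataFrame:
    """Paired sensitivity difference (modified - baseline) per grid point.

    Both protocols are simulated with the same seed (common random
    numbers) so shared sampling noise cancels from the difference.  The
    reported ``se_delta`` combines the two binomial standard errors and is
    therefore conservative under positive coupling.
    """
    if grid is None:
        grid = np.geomspace(10.0, 1e4, 25)
    extraction = extraction if extraction is not None else ExtractionModel()
    rows = []
    for c in np.asarray(grid, dtype=float):
        e0, s0 = simulate_event(c, baseline, assay, extraction,
                                n_draws=n_draws, seed=seed, mode=mode)
        e1, s1 = simulate_event(c, modified, assay, extraction,
                                n_draws=n_draws, seed=seed, mode=mode)
        rows.append((c, e0, e1, e1 - e0, float(np.hypot(s0, s1))))
    return pd.DataFrame(rows, columns=["concentration", "estimate_baseline",
                                       "estimate_modified", "delta", "se_delta"])


def mdc_reduction(baseline, modified, goal=None, assay=BIGHEAD_CARP,
                  extraction=None, mode="expected", **kwargs) -> StrategyComparison:
    """MDC reduction achieved by a protocol change.

    Returns a :class:`StrategyComparison`; ``reduction`` is positive when
    the modification lowers the detectable concentration.
    """
    if goal is None:
        goal = DesignGoal()
    elif not isinstance(goal, DesignGoal):
        goal = DesignGoal(float(goal))
    m0 = min_detectable_concentration(goal, baseline, assay, extraction,
                                      mode=mode, **kwargs)
    m1 = min_detectable_concentration(goal, modified, assay, extraction,
                                      mode=mode, **kwargs)
    return StrategyComparison(baseline, modified, goal.sensitivity_goal, m0, m1)


def unit_increase_strategies(protocol=None) -> dict[str, SamplingProtocol]:
    """The canonical one-unit protocol changes and their combinations.

    "samples" adds one water sample, "volume" adds one litre to the sample
    volume, "replicates" adds one PCR replicate; composite keys such as
    "samples+volume" apply both.
    """
    p = protocol if protocol is not None else SamplingProtocol.baseline()
    singles = {
        "samples": p.replace(n_samples=p.n_samples + 1),
        "volume": p.replace(sample_volume_l=p.sample_volume_l + 1.0),
        "replicates": p.replace(n_replicates=p.n_replicates + 1),
    }
    out = dict(singles)
    names = list(singles)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[f"{a}+{b}"] = _merge(p, singles[a], singles[b])
    out["samples+volume+replicates"] = _merge(
        p, singles["samples"], _merge(p, singles["volume"], singles["replicates"]))
    return out


def _merge(base: SamplingProtocol, a: SamplingProtocol, b: SamplingProtocol):
    changes = {}
    for f in ("n_samples", "sample_volume_l", "elution_volume_ul",
              "aliquot_volume_ul", "n_replicates"):
        va, vb, v0 = getattr(a, f), getattr(b, f), getattr(base, f)
        changes[f] = va if va != v0 else vb
    return SamplingProtocol(**changes)
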