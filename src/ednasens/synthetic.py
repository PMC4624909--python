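"""Synthetic dilution experiments and ready-made survey scenarios.

The generator emulates the structure of a serial-dilution calibration
experiment: a set of dilution levels, each with a fixed number of PCR
replicates and a known *expected* template copy number.  The realized copy
number of each replicate is Poisson around the level mean (pipetting a
small aliquot from a dilution samples a random copy count), and the binary
outcome is Bernoulli with probability given by a known gamma detection
curve evaluated at the realized count.  Calibration against such data
recovers the generating curve as replication grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .calibrate import DilutionTrial
from .model import (AssayCalibration, ExtractionModel, SamplingProtocol,
                    BIGHEAD_CARP, SILVER_CARP)

__all__ = ["ExperimentDesign", "generate_dilution_experiment", "baseline_scenarios"]

#: Default dilution levels, matching the span used for assay calibration.
DEFAULT_LEVELS = tuple(float(v) for v in range(1, 16))


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic dilution experiment with a known truth."""

    levels: tuple = DEFAULT_LEVELS
    replicates_per_level: int = 200
    true_alpha: float = 2.0
    true_beta: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if len(levels) == 0:
            raise ValueError("levels must not be empty")
        if any(v < 0 for v in levels):
            raise ValueError("levels must be >= 0")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")
        if self.true_alpha <= 0 or self.true_beta <= 0:
            raise ValueError("true gamma parameters must be positive")
        object.__setattr__(self, "levels", levels)


def generate_dilution_experiment(design: ExperimentDesign) -> list[DilutionTrial]:
    """Generate one synthetic dilution experiment; reproducible by seed.

    For each level and replicate: realized copies ~ Poisson(level), then
    outcome ~ Bernoulli(gamma CDF at the realized count).
    """
    rng = np.random.default_rng(design.seed)
    trials: list[DilutionTrial] = []
    for level in design.levels:
        realized = rng.poisson(level, size=design.replicates_per_level)
        p = special.gammainc(design.true_alpha, realized / design.true_beta)
        outcomes = rng.random(design.replicates_per_level) < p
        trials.extend(DilutionTrial(level, bool(o)) for o in outcomes)
    return trials


def trials_to_dataframe(trials) -> pd.DataFrame:
    return pd.DataFrame({
        "expected_copies": [t.expected_copies for t in trials],
        "outcome": [t.outcome for t in trials],
    })


def baseline_scenarios() -> dict:
    """The reference survey scenario used throughout the package.

    Returns the baseline sampling protocol (ten 2 L samples, 100 ul
    elution, 1 ul aliquots, eight replicates), both carp assay
    calibrations, and the default triangular extraction model.
    """
    return {
        "protocol": SamplingProtocol.baseline(),
        "assays": {"bighead": BIGHEAD_CARP, "silver": SILVER_CARP},
        "extraction": ExtractionModel(),
    }
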