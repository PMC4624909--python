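"""Calibration of gamma detection curves from dilution-series data.

A dilution experiment exposes PCR replicates to known *expected* template
copy numbers and records a binary outcome (fluorescence observed, or
sequencing confirmed).  The detection curve is the gamma CDF whose
parameters are estimated by the method of moments over the expected copy
numbers of the *positive* trials:

    alpha = xbar**2 / s**2,    beta = s**2 / xbar

where ``xbar`` and ``s`` are the mean and (n-1 denominator) standard
deviation of expected counts among positives.  Fit quality is summarized
by the RMSE between the empirical positive fraction per dilution level and
the fitted CDF, levels equally weighted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .model import AssayCalibration

__all__ = [
    "DilutionTrial",
    "CalibrationFit",
    "CalibrationError",
    "GammaDetectionModel",
    "fit_gamma_moments",
    "fit_rmse",
    "read_trials",
    "write_trials",
]


class CalibrationError(ValueError):
    """Raised when the dilution data cannot identify the detection curve."""


@dataclass(frozen=True)
class DilutionTrial:
    """One PCR replicate of a dilution experiment."""

    expected_copies: float
    outcome: bool

    def __post_init__(self) -> None:
        if self.expected_copies < 0:
            raise ValueError("expected_copies must be >= 0")


@dataclass(frozen=True)
class CalibrationFit:
    """Method-of-moments gamma fit to one detection outcome."""

    alpha: float
    beta: float
    n_trials: int
    n_positive: int
    rmse: float | None = None

    def predict(self, n_copies):
        """Fitted detection probability at ``n_copies`` expected copies."""
        return special.gammainc(self.alpha, np.asarray(n_copies, float) / self.beta)

    def moments(self) -> tuple[float, float]:
        """(mean, variance) of the fitted gamma: (alpha*beta, alpha*beta**2)."""
        return self.alpha * self.beta, self.alpha * self.beta ** 2


def _as_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        x = trials["expected_copies"].to_numpy(dtype=float)
        y = trials["outcome"].to_numpy()
    else:
        trials = list(trials)
        x = np.array([t.expected_copies for t in trials], dtype=float)
        y = np.array([t.outcome for t in trials])
    if x.size == 0:
        raise CalibrationError("no dilution trials supplied")
    if np.any(x < 0):
        raise CalibrationError("expected_copies must be >= 0")
    return x, y.astype(bool)


def fit_gamma_moments(trials) -> CalibrationFit:
    """Method-of-moments gamma fit over the positive trials.

    Raises :class:`CalibrationError` when fewer than two positive trials
    exist or the positive expected counts have zero spread (the moments
    are then degenerate and the curve unidentifiable).
    """
    x, y = _as_arrays(trials)
    pos = x[y]
    if pos.size < 2:
        raise CalibrationError(
            f"need >= 2 positive trials to compute moments, got {pos.size}")
    xbar = float(pos.mean())
    s2 = float(pos.var(ddof=1))
    if s2 == 0 or xbar == 0:
        raise CalibrationError(
            "positive trials have zero variance of expected_copies; "
            "gamma moments are degenerate")
    return CalibrationFit(alpha=xbar ** 2 / s2, beta=s2 / xbar,
                          n_trials=int(x.size), n_positive=int(pos.size))


def fit_rmse(fit: CalibrationFit, trials) -> float:
    """RMSE between per-level empirical positive fractions and the fit.

    Trials are grouped by unique ``expected_copies`` value; each level
    contributes one squared difference regardless of its replicate count.
    """
    x, y = _as_arrays(trials)
    levels = np.unique(x)
    frac = np.array([y[x == lv].mean() for lv in levels])
    return float(np.sqrt(np.mean((frac - fit.predict(levels)) ** 2)))


class GammaDetectionModel:
    """Detection-curve model for dilution-trial data.

    Statsmodels-style: construct from data, then ``fit()`` returns a
    :class:`GammaDetectionResults` with estimates, fit diagnostics and a
    ``summary()`` table.

    Parameters
    ----------
    expected_copies : array-like
        Expected template copies per trial.
    outcome : array-like of bool
        Whether the trial was positive.
    """

    def __init__(self, expected_copies, outcome):
        self.expected_copies = np.asarray(expected_copies, dtype=float)
        self.outcome = np.asarray(outcome).astype(bool)
        if self.expected_copies.shape != self.outcome.shape:
            raise ValueError("expected_copies and outcome must have equal length")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, copies_col="expected_copies",
                       outcome_col="outcome") -> "GammaDetectionModel":
        return cls(df[copies_col], df[outcome_col])

    @classmethod
    def from_trials(cls, trials) -> "GammaDetectionModel":
        x, y = _as_arrays(trials)
        return cls(x, y)

    def fit(self) -> "GammaDetectionResults":
        df = pd.DataFrame({"expected_copies": self.expected_copies,
                           "outcome": self.outcome})
        base = fit_gamma_moments(df)
        rmse = fit_rmse(base, df)
        return GammaDetectionResults(self, CalibrationFit(
            base.alpha, base.beta, base.n_trials, base.n_positive, rmse))


class GammaDetectionResults:
    """Fitted gamma detection curve with diagnostics."""

    def __init__(self, model: GammaDetectionModel, fit: CalibrationFit):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> pd.Series:
        return pd.Series({"alpha": self.fit_result.alpha,
                          "beta": self.fit_result.beta})

    @property
    def rmse(self) -> float:
        return self.fit_result.rmse

    def predict(self, n_copies):
        return self.fit_result.predict(n_copies)

    def to_assay(self, marker_name: str, sequencing: "GammaDetectionResults"
                 ) -> AssayCalibration:
        """Combine this fluorescence fit with a sequencing fit."""
        return AssayCalibration(
            marker_name, self.fit_result.alpha, self.fit_result.beta,
            sequencing.fit_result.alpha, sequencing.fit_result.beta)

    def summary(self) -> str:
        f = self.fit_result
        lines = [
            "Gamma detection curve (method of moments)",
            "=" * 44,
            f"trials:            {f.n_trials}",
            f"positive trials:   {f.n_positive}",
            f"shape (alpha):     {f.alpha:.4f}",
            f"scale (beta):      {f.beta:.4f}",
            f"implied mean:      {f.alpha * f.beta:.4f} copies",
            f"RMSE (per level):  {f.rmse:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "yes", "y", "positive", "pos"}
_FALSE = {"0", "false", "no", "n", "negative", "neg", "0.0"}


def read_trials(path) -> pd.DataFrame:
    """Read dilution trials from delimited text.

    Expects columns ``expected_copies`` and ``outcome`` (comma, tab or
    semicolon separated; '#' comments allowed).  Malformed rows are
    reported with their line numbers.
    """
    text = Path(path).read_text()
    data_lines = []
    line_nos = []
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        data_lines.append(line)
        line_nos.append(i)
    if not data_lines:
        raise CalibrationError(f"{path}: no data rows found")
    sep = "\t" if "\t" in data_lines[0] else (";" if ";" in data_lines[0] else ",")
    header = [h.strip() for h in data_lines[0].split(sep)]
    for col in ("expected_copies", "outcome"):
        if col not in header:
            raise CalibrationError(
                f"{path}: missing required column {col!r} (found {header})")
    ix_c, ix_o = header.index("expected_copies"), header.index("outcome")
    copies, outcomes, bad = [], [], []
    for line_no, line in zip(line_nos[1:], data_lines[1:]):
        parts = [p.strip() for p in line.split(sep)]
        try:
            c = float(parts[ix_c])
            raw = parts[ix_o].lower()
            if raw in _TRUE:
                o = True
            elif raw in _FALSE:
                o = False
            else:
                o = bool(int(float(raw)))
            if c < 0:
                raise ValueError("negative expected_copies")
            copies.append(c)
            outcomes.append(o)
        except (ValueError, IndexError) as exc:
            bad.append(f"line {line_no}: {line!r} ({exc})")
    if bad:
        raise CalibrationError(f"{path}: malformed rows:\n" + "\n".join(bad))
    return pd.DataFrame({"expected_copies": copies, "outcome": outcomes})


def write_trials(df, path) -> None:
    """Write trials in the same delimited format :func:`read_trials` reads."""
    if not isinstance(df, pd.DataFrame):
        x, y = _as_arrays(df)
        df = pd.DataFrame({"expected_copies": x, "outcome": y})
    out = df.copy()
    out["outcome"] = out["outcome"].astype(bool).astype(int)
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())
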