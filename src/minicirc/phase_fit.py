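"""Fixed-period sinusoid fitting of positional series and phase-lag extraction.

Series of (insert position, value, sd) points are fitted by weighted least
squares to C + A*cos(2*pi*(p - p*)/T) with the period T fixed (default 10.5 bp
per helical turn).  The fit is solved in the linear basis {1, sin, cos} with
weights 1/sd^2, then converted to amplitude / peak position / offset.  Peak
lags between two fits and their conversion to a phase angle in degrees follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComparabilityError, FitError

DEFAULT_PERIOD_BP = 10.5  # helical period h, bp per turn


@dataclass(frozen=True)
class SeriesPoint:
    """One point of a positional series: insert position, central value, sd."""

    position_bp: float
    value_nm: float
    sd_nm: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.sd_nm < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class SinusoidFit:
    """A fixed-period cosine fit: value(p) = C + A*cos(2*pi*(p - peak)/T)."""

    amplitude: float      # A >= 0
    peak_bp: float        # p* in [0, T)
    offset: float         # C
    period_bp: float      # T, fixed during the fit
    weighted_residual: float  # sum of w * (model - value)^2

    def predict(self, positions_bp) -> np.ndarray:
        p = np.asarray(positions_bp, dtype=float)
        return self.offset + self.amplitude * np.cos(
            2.0 * math.pi * (p - self.peak_bp) / self.period_bp)


def fit_sinusoid(series: list[SeriesPoint],
                 period_bp: float = DEFAULT_PERIOD_BP) -> SinusoidFit:
    """Weighted least-squares fixed-period sinusoid fit.

    Weights are 1/sd^2; points with sd = 0 receive the series' median positive
    weight (or 1 if all sds are 0).  Needs >= 3 distinct positions.
    """
    if period_bp <= 0:
        raise ValueError("period must be > 0")
    p = np.array([s.position_bp for s in series], dtype=float)
    y = np.array([s.value_nm for s in series], dtype=float)
    sd = np.array([s.sd_nm for s in series], dtype=float)
    if len(np.unique(p)) < 3:
        raise FitError("need >= 3 distinct positions for a 3-parameter fit")

    w = np.zeros_like(sd)
    pos = sd > 0
    w[pos] = 1.0 / sd[pos] ** 2
    fill = float(np.median(w[pos])) if np.any(pos) else 1.0
    w[~pos] = fill

    omega = 2.0 * math.pi / period_bp
    basis = np.column_stack([np.ones_like(p), np.cos(omega * p), np.sin(omega * p)])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(basis * sw[:, None], y * sw, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient design (positions collapse on the period)")
    c0, a_cos, a_sin = coef

    amplitude = math.hypot(a_cos, a_sin)
    peak = (math.atan2(a_sin, a_cos) / omega) % period_bp
    resid = basis @ coef - y
    return SinusoidFit(
        amplitude=float(amplitude),
        peak_bp=float(peak),
        offset=float(c0),
        period_bp=float(period_bp),
        weighted_residual=float(np.sum(w * resid ** 2)),
    )


def peak_lag(fit_a: SinusoidFit, fit_b: SinusoidFit) -> float:
    """Lag of fit_b's peak behind fit_a's peak, bp, in [0, T)."""
    if not math.isclose(fit_a.period_bp, fit_b.period_bp, rel_tol=1e-12):
        raise ComparabilityError(
            f"periods differ: {fit_a.period_bp} vs {fit_b.period_bp}")
    return (fit_b.peak_bp - fit_a.peak_bp) % fit_a.period_bp


def lag_to_degrees(lag_bp: float, period_bp: float = DEFAULT_PERIOD_BP) -> float:
    """Convert a lag in bp to a phase shift in degrees, [0, 360).

    A lag outside [0, period) is reduced modulo the period first.
    """
    if period_bp <= 0:
        raise ValueError("period must be > 0")
    return 360.0 * ((lag_bp % period_bp) / period_bp)


# ---------------------------------------------------------------------------
# series I/O
# ---------------------------------------------------------------------------

def read_series_csv(path: str | Path) -> list[SeriesPoint]:
    """Read a series CSV with columns position, value, sd[, n]."""
    df = pd.read_csv(path)
    required = {"position", "value", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"series CSV must have columns {sorted(required)}")
    n_col = df["n"] if "n" in df.columns else np.ones(len(df), dtype=int)
    return [SeriesPoint(float(r.position), float(r.value), float(r.sd), int(nv))
            for r, nv in zip(df.itertuples(), n_col)]


def write_series_csv(series: list[SeriesPoint], path: str | Path) -> None:
    pd.DataFrame({
        "position": [s.position_bp for s in series],
        "value": [s.value_nm for s in series],
        "sd": [s.sd_nm for s in series],
        "n": [s.n for s in series],
    }).to_csv(path, index=False)


def fit_to_dict(fit: SinusoidFit) -> dict:
    return {
        "amplitude": fit.amplitude,
        "peak": fit.peak_bp,
        "offset": fit.offset,
        "period": fit.period_bp,
        "weighted_residual": fit.weighted_residual,
    }
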