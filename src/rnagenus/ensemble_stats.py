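"""Ensemble-level genus analytics.

A Monte-Carlo fold is a statistical ensemble of suboptimal structures,
so its topology is summarized statistically: the per-position mean /
mode / spread of the members' genus traces (with optional 1-D Gaussian
smoothing of mean and standard deviation), and an ordinary least-squares
regression of mean genus against sequence length across many molecules.
Non-integer mean genus is deliberate — it captures the ensemble's
topological variability even though a single structure's genus is an
integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .folding_mc import FoldEnsemble
from .genus_engine import genus_trace
from .structure_io import SecondaryStructure

__all__ = ["TraceSummary", "RegressionFit", "ensemble_trace_summary",
           "fit_length_genus"]


@dataclass(frozen=True)
class TraceSummary:
    """Per-position statistics over the genus traces of an ensemble.

    All arrays have one entry per backbone position; NaN marks missing
    data, which is excluded from smoothing windows.  ``mean_smooth`` and
    ``std_smooth`` carry the Gaussian-filtered mean/std (equal to the raw
    ones when sigma = 0); mode ties are broken toward the smaller genus.
    """

    mean: np.ndarray
    mode: np.ndarray
    std: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    mean_smooth: np.ndarray
    std_smooth: np.ndarray
    sigma: float

    @property
    def length(self) -> int:
        return len(self.mean)

    @property
    def mean_genus(self) -> float:
        """Ensemble mean genus = unsmoothed mean trace at the last position."""
        return float(self.mean[-1])


def _smooth_with_gaps(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian filter with reflection padding, applied per valid segment.

    NaN runs split the signal; each contiguous valid run is smoothed
    independently so missing data never bleeds into its neighbors.
    """
    if sigma <= 0:
        return values.copy()
    out = np.full_like(values, np.nan, dtype=float)
    valid = ~np.isnan(values)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for start, stop in idx.reshape(-1, 2):
        out[start:stop] = gaussian_filter1d(
            values[start:stop], sigma=sigma, mode="reflect"
        )
    return out


def ensemble_trace_summary(
    ensemble: FoldEnsemble | Sequence[SecondaryStructure],
    sigma: float = 1.0,
) -> TraceSummary:
    """Summarize the genus traces of an ensemble's members.

    Accepts a :class:`FoldEnsemble` or any sequence of structures sharing
    one backbone length.  Smoothing (a 1-D Gaussian filter of width
    ``sigma``, reflection padding at the boundaries) is applied to the
    mean and standard deviation only; ``sigma=0`` disables it.
    """
    if isinstance(ensemble, FoldEnsemble):
        members = ensemble.secondary_structures()
    else:
        members = list(ensemble)
    if not members:
        raise ValueError("ensemble has no members")
    lengths = {s.length for s in members}
    if len(lengths) > 1:
        raise ValueError(f"members have mixed backbone lengths: {sorted(lengths)}")
    traces = np.array([genus_trace(s).values for s in members], dtype=float)
    mean = traces.mean(axis=0)
    std = traces.std(axis=0)
    minimum = traces.min(axis=0)
    maximum = traces.max(axis=0)
    # mode with ties toward the smaller genus: iterate candidate values
    # in ascending order and keep the first with maximal count
    mode = np.empty_like(mean)
    for col in range(traces.shape[1]):
        vals, counts = np.unique(traces[:, col], return_counts=True)
        mode[col] = vals[np.argmax(counts)]  # np.unique sorts ascending
    return TraceSummary(
        mean=mean, mode=mode, std=std, minimum=minimum, maximum=maximum,
        mean_smooth=_smooth_with_gaps(mean, sigma),
        std_smooth=_smooth_with_gaps(std, sigma),
        sigma=float(sigma),
    )


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of mean genus g against sequence length d: g = slope*d + b."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    zero_intercept: bool
    n: int


def fit_length_genus(
    records: Sequence[tuple[float, float]],
    zero_intercept: bool = False,
) -> RegressionFit:
    """Least-squares genus-vs-length fit over (length, mean genus) records.

    The free-intercept variant is ordinary least squares; the
    zero-intercept variant regresses through the origin, with r^2
    computed against the uncentered total sum of squares (the standard
    convention for through-origin fits).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for a regression")
    d = np.asarray([r[0] for r in records], dtype=float)
    g = np.asarray([r[1] for r in records], dtype=float)
    if np.any(d <= 0):
        raise ValueError("lengths must be positive")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate input: all lengths equal")
    if zero_intercept:
        sxx = float(d @ d)
        slope = float(d @ g) / sxx
        resid = g - slope * d
        ss_res = float(resid @ resid)
        ss_tot = float(g @ g)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(d) - 1
        stderr = float(np.sqrt((ss_res / dof) / sxx)) if dof > 0 else 0.0
        return RegressionFit(slope=slope, intercept=0.0, r_squared=r2,
                             slope_stderr=stderr, zero_intercept=True,
                             n=len(d))
    res = stats.linregress(d, g)
    return RegressionFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), slope_stderr=float(res.stderr),
        zero_intercept=False, n=len(d),
    )
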