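"""AFM height-profile analysis: D-period and overlap-gap step height.

Works on 1-D (position, height) series in nm.  The pipeline is: remove the
instrument tilt (polynomial detrend), estimate the banding period from the
first dominant autocorrelation peak with parabolic sub-sample refinement,
then measure the per-period peak-to-valley difference -- the step height
between the overlap plateau and the gap valley -- on a lightly smoothed
profile, reporting mean and standard deviation over complete periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax


@dataclass
class HeightProfile:
    """A 1-D height profile; positions strictly increasing, in nm."""

    positions: np.ndarray
    heights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have equal length")
        if len(self.positions) > 1 and not np.all(
            np.diff(self.positions) > 0
        ):
            raise ValueError("positions must be strictly increasing")

    @property
    def pixel_size(self) -> float:
        return float(np.median(np.diff(self.positions)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_nm": self.positions, "height_nm": self.heights}
        )


@dataclass
class HeightProfileStats:
    period: float            # nm
    step_height_mean: float  # nm
    step_height_sd: float    # nm
    n_periods_used: int

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.step_height_sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_periods_used < 2:
            raise ValueError("need at least two periods")


def detrend(profile: HeightProfile, order: int = 1) -> HeightProfile:
    """Subtract a least-squares polynomial of the given order (0 or 1)."""
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    coef = np.polyfit(profile.positions, profile.heights, order)
    resid = profile.heights - np.polyval(coef, profile.positions)
    return HeightProfile(profile.positions, resid, dict(profile.metadata))


def estimate_period(
    profile: HeightProfile,
    min_lag: float | None = None,
    min_peak_corr: float = 0.2,
) -> float:
    """Dominant period (nm) from the autocorrelation of the profile.

    The profile is mean-removed (after linear detrending) and its
    normalized autocorrelation scanned for the first local maximum above
    ``min_peak_corr``; the lag is refined by parabolic interpolation.
    Raises when no dominant period exists (e.g. white noise).
    """
    p = detrend(profile, order=1)
    h = p.heights - p.heights.mean()
    n = len(h)
    if n < 8:
        raise ValueError("profile too short")
    ac = np.correlate(h, h, mode="full")[n - 1:]
    ac = ac / ac[0]
    dx = p.pixel_size
    start = max(2, int((min_lag or 2 * dx) / dx))
    peaks = argrelmax(ac[start:], order=2)[0] + start
    peaks = peaks[ac[peaks] >= min_peak_corr]
    if len(peaks) == 0:
        raise ValueError("no dominant period found")
    k = int(peaks[np.argmax(ac[peaks])])
    k = int(peaks[0]) if ac[peaks[0]] >= 0.8 * ac[k] else k
    # parabolic sub-sample refinement
    if 1 <= k < n - 1:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        shift = float(np.clip(shift, -1.0, 1.0))
    else:
        shift = 0.0
    return (k + shift) * dx


def step_height(
    profile: HeightProfile,
    period: float,
    smooth_fraction: float = 0.05,
) -> HeightProfileStats:
    """Per-period peak-minus-valley statistics on the detrended profile.

    The profile is smoothed with a Gaussian of sigma = period *
    ``smooth_fraction`` (period/20 by default) and split into phase-aligned
    windows of one period; each complete window contributes max - min.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    p = detrend(profile, order=1)
    dx = p.pixel_size
    h = p.heights
    sigma_px = period * smooth_fraction / dx
    if sigma_px > 0.3:
        h = gaussian_filter1d(h, sigma_px, mode="nearest")
    x = p.positions - p.positions[0]
    # phase-align windows to start at the global minimum's phase
    phase0 = x[int(np.argmin(h))] % period
    steps = []
    k0 = 0
    while True:
        lo = phase0 + k0 * period
        hi = lo + period
        m = (x >= lo) & (x < hi)
        if hi > x[-1] + 0.5 * dx:
            break
        if m.sum() >= max(4, int(0.8 * period / dx)):
            w = h[m]
            steps.append(w.max() - w.min())
        k0 += 1
    if len(steps) < 2:
        raise ValueError("fewer than two usable periods")
    steps = np.asarray(steps)
    return HeightProfileStats(
        period=float(period),
        step_height_mean=float(steps.mean()),
        step_height_sd=float(steps.std(ddof=1)),
        n_periods_used=len(steps),
    )


def analyze_profile(profile: HeightProfile) -> HeightProfileStats:
    """Full pipeline: detrend, estimate period, measure step height."""
    period = estimate_period(profile)
    return step_height(profile, period)


def sample_line(
    height_matrix: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    pixel_size: float = 1.0,
    n_samples: int | None = None,
) -> HeightProfile:
    """Nearest-pixel sampling of a 2-D height map along a line segment.

    ``height_matrix`` is row-major (row, col) in nm; ``start``/``end`` are
    (row, col) pixel coordinates.  Returns the 1-D profile along the line
    with positions in nm.
    """
    h = np.asarray(height_matrix, dtype=float)
    r0, c0 = start
    r1, c1 = end
    length_px = float(np.hypot(r1 - r0, c1 - c0))
    n = n_samples or max(2, int(np.ceil(length_px)) + 1)
    rows = np.rint(np.linspace(r0, r1, n)).astype(int)
    cols = np.rint(np.linspace(c0, c1, n)).astype(int)
    if (rows.min() < 0 or cols.min() < 0 or rows.max() >= h.shape[0]
            or cols.max() >= h.shape[1]):
        raise ValueError("line endpoints outside the height matrix")
    pos = np.linspace(0.0, length_px * pixel_size, n)
    return HeightProfile(pos, h[rows, cols],
                         {"source": "2d-matrix", "pixel_size": pixel_size})
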