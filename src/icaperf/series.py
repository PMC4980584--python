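"""In-memory containers for dynamic susceptibility contrast (DSC) MRI series.

A :class:`DynamicSeries` holds raw signal intensities on a ``(time, *spatial)``
grid together with the acquisition metadata the perfusion pipeline needs:
the sampling interval ``dt`` (the repetition time for single-slice EPI),
the echo time ``te``, the injection time point, and the baseline window used
to estimate the pre-contrast signal ``S0``.

Time-point indices are 1-based at the interface (matching the radiological
convention "the 7th time point") and converted to 0-based indices internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

__all__ = ["DynamicSeries", "ConcentrationSeries"]


@dataclass
class DynamicSeries:
    """A 4D (or 2D+time) dynamic MR signal series.

    Parameters
    ----------
    data
        Signal intensities, shape ``(n_timepoints, *spatial_shape)``.
    dt
        Sampling interval in seconds (TR for single-shot EPI).
    te
        Echo time in seconds.
    injection_tp
        1-based time point of contrast injection.
    baseline_window
        1-based inclusive ``(first, last)`` time points used for the
        pre-contrast baseline.  Defaults to everything before injection.
    """

    data: np.ndarray
    dt: float
    te: float
    injection_tp: int = 7
    baseline_window: Optional[Tuple[int, int]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise ValueError("series data must be at least (time, voxels)")
        if self.dt <= 0 or self.te <= 0:
            raise ValueError("dt and te must be positive")
        if not (1 <= self.injection_tp <= self.n_timepoints):
            raise ValueError("injection_tp outside the time axis")
        if self.baseline_window is None:
            self.baseline_window = (1, max(1, self.injection_tp - 1))
        lo, hi = self.baseline_window
        if not (1 <= lo <= hi <= self.n_timepoints):
            raise ValueError(f"invalid baseline_window {self.baseline_window}")

    # -- geometry ---------------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.data.shape[1:]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds, starting at 0."""
        return np.arange(self.n_timepoints) * self.dt

    # -- index helpers ----------------------------------------------------
    @property
    def baseline_slice(self) -> slice:
        lo, hi = self.baseline_window
        return slice(lo - 1, hi)

    @property
    def injection_index(self) -> int:
        """0-based index of the injection time point."""
        return self.injection_tp - 1

    def as_matrix(self) -> np.ndarray:
        """Return a ``(n_timepoints, n_voxels)`` view (C-order flattening)."""
        return self.data.reshape(self.n_timepoints, -1)

    def discard_leading(self, n: int) -> "DynamicSeries":
        """Drop ``n`` leading dummy frames and re-zero the time axis."""
        if n < 0 or n >= self.n_timepoints:
            raise ValueError("cannot discard that many frames")
        if n == 0:
            return self
        lo, hi = self.baseline_window
        new_inj = max(1, self.injection_tp - n)
        new_win = (max(1, lo - n), max(1, hi - n))
        return replace(
            self,
            data=self.data[n:],
            injection_tp=new_inj,
            baseline_window=new_win,
        )


@dataclass
class ConcentrationSeries(DynamicSeries):
    """Same grid as :class:`DynamicSeries`, in contrast-agent concentration.

    Values are in the (relaxivity-scaled) concentration units produced by the
    signal model; voxels whose signal was non-positive are NaN.
    ``meta`` records the conversion constants used.
    """
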