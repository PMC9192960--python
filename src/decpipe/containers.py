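"""Core in-memory containers shared across pipeline stages.

Two signal levels are distinguished: :class:`NeuralTimeSeries` holds
latent neural activity (e.g. the output of hemodynamic deconvolution or
a simulated VAR process), while :class:`BoldTimeSeries` holds observed
BOLD signal sampled at the scanner repetition time (TR).  Both are thin
validated wrappers around a ``time x region`` float matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeuralTimeSeries", "BoldTimeSeries"]


def _as_time_by_region(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D (time x region) array, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise ValueError("time series contains non-finite values")
    return arr


@dataclass
class NeuralTimeSeries:
    """Multi-region neural-level signal with sampling-interval metadata.

    Parameters
    ----------
    values : array-like, shape (n_samples, n_regions)
        Signal amplitudes, arbitrary units.
    dt : float
        Sampling interval in seconds (> 0).
    region_labels : list of str, optional
        One label per region; defaults to ``r0, r1, ...``.
    """

    values: np.ndarray
    dt: float
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_time_by_region(self.values)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.region_labels is None:
            self.region_labels = [f"r{i}" for i in range(self.values.shape[1])]
        else:
            self.region_labels = list(self.region_labels)
            if len(self.region_labels) != self.values.shape[1]:
                raise ValueError("region_labels length does not match number of regions")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "NeuralTimeSeries":
        """Return a copy with each region demeaned and scaled to unit variance."""
        v = self.values - self.values.mean(axis=0)
        sd = v.std(axis=0)
        sd[sd == 0] = 1.0
        return NeuralTimeSeries(v / sd, self.dt, list(self.region_labels))


@dataclass
class BoldTimeSeries:
    """Observed BOLD signal, ``time x region``, sampled at the TR.

    ``meta`` carries provenance set by producers (e.g. ROI mask sizes,
    whether per-region standardization was applied).
    """

    values: np.ndarray
    tr: float
    region_labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_time_by_region(self.values)
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.region_labels is None:
            self.region_labels = [f"r{i}" for i in range(self.values.shape[1])]
        else:
            self.region_labels = list(self.region_labels)
            if len(self.region_labels) != self.values.shape[1]:
                raise ValueError("region_labels length does not match number of regions")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]
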