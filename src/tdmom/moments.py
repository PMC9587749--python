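"""Temporal moments of photon time-of-flight distributions and their covariance.

A time-domain NIRS measurement for one channel, wavelength and time sample is
a histogram of photon arrival times (DTOF).  The analysis stack in this
package works with three summary statistics of that histogram:

* ``M0 = -log(sum_i N_i)`` — the log of the total count, the time-domain
  analogue of the optical density used in continuous-wave NIRS;
* ``M1 = sum_i tau_i N_i / sum_i N_i`` — the mean time of flight;
* ``M2 = <tau^2> - M1^2`` — the variance of the DTOF.

Higher moments weight late (deep-travelling) photons more strongly, which is
the source of their increased brain sensitivity.

Two covariance models for the moment vector are provided: a theoretical
shot-noise model (delta-method propagation of independent Poisson bin counts
through the moment definitions) and an empirical model (sample covariance of
a measured moment time series).  Everywhere a stacked 3*Nc moment object
appears, the ordering is moment-major: all M0 rows (one per channel), then
all M1 rows, then all M2 rows.

All times are SI seconds internally.  Delimited-text DTOF files use
nanoseconds for readability and are converted on read/write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "DTOF",
    "MomentVector",
    "MomentTimeSeries",
    "MomentCovariance",
    "compute_moments",
    "shot_noise_covariance",
    "empirical_covariance",
    "fisher_transform",
    "classify_separation",
    "MOMENT_SCALES",
]

#: Default diagonal scaling that brings (M0, M1, M2) changes to a common
#: order of magnitude: 1 for M0 (dimensionless), 1e12 for M1 (picosecond
#: scale changes), 1e24 for M2.
MOMENT_SCALES = np.array([1.0, 1e12, 1e24])


@dataclass(frozen=True)
class DTOF:
    """Binned distribution of photon times of flight.

    ``bin_times`` are bin centers in seconds (monotone increasing, uniform
    width); ``counts`` are photons per bin (weighted counts allowed).
    """

    bin_times: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        bt = np.asarray(self.bin_times, float)
        ct = np.asarray(self.counts, float)
        if bt.ndim != 1 or bt.shape != ct.shape:
            raise ValueError("bin_times and counts must be 1-D and equal length")
        if bt.size > 1 and np.any(np.diff(bt) <= 0):
            raise ValueError("bin_times must be strictly increasing")
        if np.any(ct < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_times", bt)
        object.__setattr__(self, "counts", ct)

    @property
    def total_photons(self) -> float:
        return float(self.counts.sum())

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_text(cls, path) -> "DTOF":
        """Read a two-column delimited text file: bin time [ns], counts."""
        data = np.loadtxt(path, ndmin=2)
        return cls(bin_times=data[:, 0] * 1e-9, counts=data[:, 1])

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_times * 1e9, self.counts]),
            header="bin_time_ns counts",
        )

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "DTOF":
        return cls(bin_times=group["bin_times"][()], counts=group["counts"][()])

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("bin_times", data=self.bin_times)
        group.create_dataset("counts", data=self.counts)


@dataclass(frozen=True)
class MomentVector:
    """(M0, M1, M2) for a single DTOF: dimensionless, seconds, seconds^2."""

    M0: float
    M1: float
    M2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M0, self.M1, self.M2])


def classify_separation(separation_mm: float) -> str:
    """Channel class from source–detector separation.

    SS < 10 mm, MS 21–27 mm, LS 28–34 mm, VLS > 34 mm; separations in the
    (10, 21) mm gap are "other".
    """
    rho = float(separation_mm)
    if rho < 10.0:
        return "SS"
    if 21.0 <= rho <= 27.0:
        return "MS"
    if 28.0 <= rho <= 34.0:
        return "LS"
    if rho > 34.0:
        return "VLS"
    return "other"


@dataclass
class MomentTimeSeries:
    """Moment time series for a set of channels at two (or more) wavelengths.

    ``values`` has shape (Nc, Nw, 3, Nt) with axis 2 indexing (M0, M1, M2).
    ``detector_ids`` groups channels that share a detector (an SS channel and
    an LS channel on the same detector see the same patch of scalp).
    """

    values: np.ndarray
    separations: np.ndarray  # mm, (Nc,)
    wavelengths: np.ndarray  # nm, (Nw,)
    sample_rate: float  # Hz
    detector_ids: np.ndarray = None  # (Nc,)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 4 or self.values.shape[2] != 3:
            raise ValueError("values must have shape (Nc, Nw, 3, Nt)")
        self.separations = np.asarray(self.separations, float)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.separations.shape[0] != self.values.shape[0]:
            raise ValueError("one separation per channel required")
        if self.wavelengths.shape[0] != self.values.shape[1]:
            raise ValueError("one wavelength per values column required")
        if self.detector_ids is None:
            self.detector_ids = np.arange(self.values.shape[0])
        self.detector_ids = np.asarray(self.detector_ids)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[3]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.sample_rate

    @property
    def channel_class(self) -> list[str]:
        return [classify_separation(rho) for rho in self.separations]

    def stacked(self, channels, wavelength_index: int) -> np.ndarray:
        """Moment-major stack (3*Nc, Nt) for a channel subset at one wavelength.

        Rows are ordered [M0 ch0..chN, M1 ch0..chN, M2 ch0..chN], matching the
        canonical ordering used by every covariance and inversion here.
        """
        channels = np.atleast_1d(channels)
        sub = self.values[channels, wavelength_index]  # (Nc, 3, Nt)
        return np.concatenate([sub[:, n, :] for n in range(3)], axis=0)

    # -- I/O -----------------------------------------------------------
    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("values", data=self.values)
        group.create_dataset("separations", data=self.separations)
        group.create_dataset("wavelengths", data=self.wavelengths)
        group.create_dataset("detector_ids", data=self.detector_ids)
        group.attrs["sample_rate"] = self.sample_rate

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "MomentTimeSeries":
        return cls(
            values=group["values"][()],
            separations=group["separations"][()],
            wavelengths=group["wavelengths"][()],
            detector_ids=group["detector_ids"][()],
            sample_rate=float(group.attrs["sample_rate"]),
        )


@dataclass
class MomentCovariance:
    """Symmetric PSD covariance of a moment-major stacked moment vector.

    ``source`` records whether the matrix came from the theoretical
    shot-noise model ("theoretical") or from data ("empirical").
    """

    matrix: np.ndarray
    source: str = "theoretical"
    rank_deficient: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        scale = np.max(np.abs(m)) or 1.0
        if np.max(np.abs(m - m.T)) > 1e-10 * scale:
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(m) < -1e-15 * scale):
            raise ValueError("covariance diagonal must be non-negative")
        self.matrix = 0.5 * (m + m.T)


def compute_moments(dtof: DTOF) -> MomentVector:
    """Moments (M0, M1, M2) of a DTOF.

    Raises ``ValueError`` for an all-zero histogram rather than propagating
    NaNs.  M2 is clipped at zero against roundoff for near-degenerate
    histograms.
    """
    counts = dtof.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute moments of an empty DTOF (zero total counts)")
    tau = dtof.bin_times
    m0 = float(total)
    m1 = float((tau * counts).sum() / total)
    m2raw = float((tau**2 * counts).sum() / total)
    return MomentVector(M0=-np.log(m0), M1=m1, M2=max(m2raw - m1**2, 0.0))


def _central_moments(dtof: DTOF, k_max: int = 4) -> np.ndarray:
    """Central moments mu_1..mu_k of the normalized DTOF (mu_1 = mean)."""
    p = dtof.counts / dtof.counts.sum()
    mean = float((dtof.bin_times * p).sum())
    out = np.empty(k_max)
    out[0] = mean
    d = dtof.bin_times - mean
    for k in range(2, k_max + 1):
        out[k - 1] = float(((d**k) * p).sum())
    return out


def shot_noise_covariance(dtof: DTOF, total_photons: float | None = None) -> MomentCovariance:
    """Theoretical covariance of (M0, M1, M2) under Poisson counting noise.

    First-order (delta-method) error propagation assuming independent
    Poisson bin counts with means proportional to the DTOF shape and total
    expected count ``total_photons`` (defaults to the DTOF's own total).
    The result is

        Var(M0) = 1/N            Cov(M0, M1) = Cov(M0, M2) = 0
        Var(M1) = mu2/N          Cov(M1, M2) = mu3/N
        Var(M2) = (mu4 - mu2^2)/N

    with mu_k the k'th central moment of the normalized DTOF — the
    cross-covariances of M0 with the normalized-shape moments vanish exactly
    at first order.  Every entry scales as 1/N.
    """
    if total_photons is None:
        total_photons = dtof.total_photons
    if total_photons <= 0:
        raise ValueError("total_photons must be positive")
    mu = _central_moments(dtof, 4)
    mu2, mu3, mu4 = mu[1], mu[2], mu[3]
    n = float(total_photons)
    cov = np.array(
        [
            [1.0 / n, 0.0, 0.0],
            [0.0, mu2 / n, mu3 / n],
            [0.0, mu3 / n, (mu4 - mu2**2) / n],
        ]
    )
    return MomentCovariance(matrix=cov, source="theoretical")


def shot_noise_covariance_from_central_moments(
    mu2: float, mu3: float, mu4: float, total_photons: float
) -> MomentCovariance:
    """Shot-noise covariance from precomputed DTOF central moments.

    Same model as :func:`shot_noise_covariance` for callers that store the
    central moments (e.g. a Monte Carlo lookup table) instead of histograms.
    """
    n = float(total_photons)
    if n <= 0:
        raise ValueError("total_photons must be positive")
    cov = np.array(
        [
            [1.0 / n, 0.0, 0.0],
            [0.0, mu2 / n, mu3 / n],
            [0.0, mu3 / n, max(mu4 - mu2**2, 0.0) / n],
        ]
    )
    return MomentCovariance(matrix=cov, source="theoretical")


def empirical_covariance(
    series: MomentTimeSeries | np.ndarray,
    channels=None,
    wavelength_index: int = 0,
) -> MomentCovariance:
    """Sample covariance of a moment-major stacked moment time series.

    Accepts either a :class:`MomentTimeSeries` (with a channel subset and a
    wavelength) or a pre-stacked (3*Nc, Nt) array.  The series is
    mean-subtracted internally.  A constant (or otherwise rank-deficient)
    series yields a zero/rank-deficient matrix and a warning; callers that
    invert the matrix are expected to use a pseudo-inverse.
    """
    if isinstance(series, MomentTimeSeries):
        if channels is None:
            channels = np.arange(series.n_channels)
        stacked = series.stacked(channels, wavelength_index)
    else:
        stacked = np.asarray(series, float)
    if stacked.ndim != 2 or stacked.shape[1] < 2:
        raise ValueError("need a (rows, Nt) stack with at least 2 time samples")
    centered = stacked - stacked.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (stacked.shape[1] - 1)
    cov = 0.5 * (cov + cov.T)
    # rank-check the correlation matrix: the raw covariance spans tens of
    # orders of magnitude across moment orders, which a single relative
    # tolerance would misread as rank deficiency
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        rank = int(np.count_nonzero(d > 0))
        deficient = True
    else:
        corr = cov / d[:, None] / d[None, :]
        rank = int(np.linalg.matrix_rank(corr, tol=1e-10))
        deficient = rank < cov.shape[0]
    if deficient:
        warnings.warn(
            f"empirical moment covariance is rank deficient ({rank}/{cov.shape[0]}); "
            "downstream inversions will use a pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
    return MomentCovariance(matrix=cov, source="empirical", rank_deficient=deficient)


def fisher_transform(r) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Raises for |r| >= 1; use :func:`tdmom.evaluation.clipped_fisher` when a
    noise-free comparison can hit exactly +/-1.
    """
    r_arr = np.asarray(r, float)
    if np.any(np.abs(r_arr) >= 1.0):
        raise ValueError("Fisher transform requires |r| < 1")
    z = np.arctanh(r_arr)
    return float(z) if np.isscalar(r) or z.ndim == 0 else z
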