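"""Hemodynamic response recovery from moment time series.

Four method families operate on the same synthetic sessions:

* **CW block average** (``CW-BA``): treat M0 like a continuous-wave optical
  density — low-pass filter, Beer-Lambert inversion with an effective
  pathlength, epoch averaging.  ``CW-SS`` is the same estimator applied to
  the short-separation channel.
* **CW GLM** (``CW-GLM``): per-wavelength ordinary least squares of the LS
  M0 series on onset-locked Gaussian temporal bases plus the SS M0 series
  as a superficial regressor.
* **TD multidistance moment inversion** (``TD-SS``, ``TD-LS``,
  ``TD-LS+SS``): per time sample, weighted least squares separating scalp
  and brain absorption changes from the stacked (M0, M1, M2) of one or two
  channels, with a scaled estimator for numerical stability; brain series
  are then block-averaged and unmixed to hemoglobin.
* **TD moment GLM** (``TD-GLM``): a joint linear model over both
  wavelengths and all three moments in which the SS M0 series models the
  scalp contribution of every moment (scaled by the scalp-sensitivity
  ratio) and onset-locked temporal bases model the brain HbO/HbR response
  directly in concentration units.  The 6Nt x 6Nt measurement covariance
  Z (x) I(Nt) is never materialized: the normal equations are assembled
  blockwise from the 6 x 6 moment covariance.

Stacked-moment conventions follow :mod:`tdmom.moments` (moment-major).  The
TD GLM's six row blocks are ordered [M0 l1, M0 l2, M1 l1, M1 l2, M2 l1,
M2 l2] — moments outermost, wavelengths innermost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import chromophores
from .moments import (
    MOMENT_SCALES,
    MomentCovariance,
    MomentTimeSeries,
    empirical_covariance,
    shot_noise_covariance_from_central_moments,
)
from .synth import CanonicalHRF, StimulusTrain, SyntheticSession
from .transport import SensitivityTable, TwoLayerSensitivity, baseline_absorption, interp_two_layer

__all__ = [
    "LayerAbsorptionSeries",
    "RecoveredHRF",
    "RecoveryResult",
    "METHODS",
    "EPOCH_WINDOW",
    "scaled_wls_estimator",
    "td_multidistance",
    "block_average",
    "epoch_average",
    "cw_block_average",
    "cw_glm",
    "td_glm",
    "td_glm_design",
    "gaussian_basis",
    "basis_regressors",
    "theoretical_moment_covariance",
    "run_method_suite",
]

#: epoch window (s) relative to stimulus onset; baseline is [-2, 0]
EPOCH_WINDOW = (-2.0, 18.0)
BASELINE_WINDOW = (-2.0, 0.0)
#: Gaussian temporal basis: spacing and standard deviation (s)
BASIS_SPACING = 1.0
BASIS_STD = 1.0
#: CW low-pass cutoff (Hz) and filter order
CW_CUTOFF = 0.7
CW_FILTER_ORDER = 4
#: relative pseudo-inverse cutoff used by every solver here
PINV_RCOND = 1e-12

METHODS = ("CW-BA", "CW-SS", "CW-GLM", "TD-SS", "TD-LS", "TD-LS+SS", "TD-GLM")


@dataclass
class LayerAbsorptionSeries:
    """Scalp/brain absorption-change time courses (mm^-1) at one wavelength."""

    scalp: np.ndarray
    brain: np.ndarray
    wavelength: float
    sample_rate: float


@dataclass
class RecoveredHRF:
    """A recovered hemodynamic response on an epoch time base.

    ``hbo``/``hbr`` in uM; baseline (mean over [-2, 0] s) is zero by
    construction.  ``covariance_source`` is "ZT", "ZE" or "identity" for TD
    methods and "none" for CW methods.
    """

    time_base: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    method: str
    covariance_source: str = "none"
    meta: dict = field(default_factory=dict)


@dataclass
class RecoveryResult:
    """One (detector, method) outcome of a suite run."""

    detector: int
    method: str
    hrf: RecoveredHRF | None
    channels: dict
    error: str | None = None


# ---------------------------------------------------------------------------
# core linear algebra
# ---------------------------------------------------------------------------


def _pinv(a: np.ndarray) -> np.ndarray:
    return np.linalg.pinv(a, rcond=PINV_RCOND)


def _psd_pinv(a: np.ndarray) -> np.ndarray:
    """Pseudo-inverse of a symmetric matrix with negative eigenvalues clipped.

    A plain SVD pseudo-inverse would invert a slightly negative eigenvalue
    with its sign, turning a numerically indefinite covariance into an
    indefinite weight matrix; clipping to the PSD cone is the safe reading.
    """
    ev, vec = np.linalg.eigh(0.5 * (a + a.T))
    cut = PINV_RCOND * max(ev[-1], 0.0)
    inv = np.where(ev > cut, 1.0 / np.where(ev > cut, ev, 1.0), 0.0)
    return (vec * inv) @ vec.T


def scaled_wls_estimator(X: np.ndarray, Z: np.ndarray, k=None) -> np.ndarray:
    """Weighted-least-squares estimator with diagonal pre-scaling.

    Computes ``X* = ((kX)^T (kZk)^-1 kX)^-1 (kX)^T (kZk)^-1 k`` — the scaling
    ``k`` improves conditioning but leaves the estimator algebraically
    unchanged.  ``X`` has 3*Nc rows stacked moment-major; the default ``k``
    applies (1, 1e12, 1e24) per moment block.  Raises with a condition-number
    report if the scaled covariance is singular beyond the pseudo-inverse
    tolerance.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    m = X.shape[0]
    if Z.shape != (m, m):
        raise ValueError(f"Z must be {m}x{m} to match X rows, got {Z.shape}")
    if k is None:
        if m % 3:
            raise ValueError("default scaling requires a 3*Nc row count")
        k = np.repeat(MOMENT_SCALES, m // 3)
    k = np.asarray(k, float)
    if k.ndim == 2:
        k = np.diag(k)
    if k.shape != (m,) or np.any(k <= 0):
        raise ValueError("k must be a positive diagonal of matching size")
    Xs = k[:, None] * X
    Zs = k[:, None] * Z * k[None, :]
    ev = np.linalg.eigvalsh(Zs)
    if ev[-1] <= 0 or not np.isfinite(ev[-1]):
        raise np.linalg.LinAlgError(
            f"scaled covariance is singular (eigenvalues in [{ev[0]:.3g}, "
            f"{ev[-1]:.3g}], condition number undefined)"
        )
    Zinv = _pinv(Zs)
    A = Xs.T @ Zinv @ Xs
    rank = np.linalg.matrix_rank(A, tol=PINV_RCOND * max(np.abs(A).max(), 1e-300))
    if rank < X.shape[1]:
        cond = ev[-1] / max(ev[0], 1e-300)
        raise np.linalg.LinAlgError(
            f"normal matrix rank {rank} < {X.shape[1]} unknowns "
            f"(scaled covariance condition number {cond:.3g})"
        )
    return _pinv(A) @ Xs.T @ Zinv @ np.diag(k)


def td_multidistance(
    series: MomentTimeSeries,
    channels,
    sens: list[TwoLayerSensitivity],
    Z: MomentCovariance | np.ndarray,
    wavelength_index: int = 0,
) -> LayerAbsorptionSeries:
    """Two-layer absorption separation from stacked channel moments.

    ``channels`` is one or two channel indices ({SS}, {LS} or {LS, SS});
    ``sens`` the matching two-layer sensitivities at the series' wavelength
    ``wavelength_index``.  Per time sample the scaled WLS estimator maps the
    moment-major stack to (scalp, brain) absorption changes.  The input
    moments are differenced against their temporal mean.
    """
    channels = np.atleast_1d(channels)
    if len(sens) != channels.size:
        raise ValueError("one TwoLayerSensitivity per channel required")
    if channels.size not in (1, 2):
        raise ValueError("channel set must be {SS}, {LS} or {LS, SS}")
    nc = channels.size
    # moment-major stacked sensitivities: for each moment, one row per channel
    X = np.zeros((3 * nc, 2))
    for n in range(3):
        for c in range(nc):
            X[n * nc + c, 0] = sens[c].scalp[n]
            X[n * nc + c, 1] = sens[c].brain[n]
    Zm = Z.matrix if isinstance(Z, MomentCovariance) else np.asarray(Z, float)
    est = scaled_wls_estimator(X, Zm)  # (2, 3Nc)
    stacked = series.stacked(channels, wavelength_index)
    dm = stacked - stacked.mean(axis=1, keepdims=True)
    layers = est @ dm  # (2, Nt)
    return LayerAbsorptionSeries(
        scalp=layers[0],
        brain=layers[1],
        wavelength=float(series.wavelengths[wavelength_index]),
        sample_rate=series.sample_rate,
    )


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------


def epoch_average(
    signal: np.ndarray,
    sample_rate: float,
    onsets,
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Onset-locked average of ``signal`` rows on a common epoch time base.

    ``signal`` is (Nt,) or (rows, Nt).  Epochs are sampled by linear
    interpolation at onset-relative times, so onsets need not fall on the
    sample grid.  Only epochs fully inside the recording count.  Returns
    (epoch time base, averaged rows with the [-2, 0] s baseline mean
    removed, number of epochs).  Raises if no complete epoch exists.
    """
    sig = np.atleast_2d(np.asarray(signal, float))
    nt = sig.shape[1]
    t_end = (nt - 1) / sample_rate
    w0, w1 = epoch_window
    tb = np.arange(round(w0 * sample_rate), round(w1 * sample_rate) + 1) / sample_rate
    t = np.arange(nt) / sample_rate
    epochs = []
    for onset in np.atleast_1d(onsets):
        if onset + tb[0] < 0 or onset + tb[-1] > t_end:
            continue
        tq = onset + tb
        epochs.append(np.stack([np.interp(tq, t, row) for row in sig]))
    if not epochs:
        raise ValueError(
            f"no complete [{w0}, {w1}] s epoch fits the {t_end:.1f} s recording"
        )
    avg = np.mean(epochs, axis=0)
    base = tb <= BASELINE_WINDOW[1]
    avg = avg - avg[:, base].mean(axis=1, keepdims=True)
    out = avg if np.asarray(signal).ndim > 1 else avg[0]
    return tb, out, len(epochs)


def block_average(
    hbo: np.ndarray,
    hbr: np.ndarray,
    sample_rate: float,
    onsets,
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
    method: str = "BA",
    covariance_source: str = "none",
) -> RecoveredHRF:
    """Block-average HbO/HbR time courses into a baseline-adjusted HRF."""
    tb, avg, n_epochs = epoch_average(
        np.stack([hbo, hbr]), sample_rate, onsets, epoch_window
    )
    return RecoveredHRF(
        time_base=tb,
        hbo=avg[0],
        hbr=avg[1],
        method=method,
        covariance_source=covariance_source,
        meta={"n_epochs": n_epochs},
    )


# ---------------------------------------------------------------------------
# CW methods
# ---------------------------------------------------------------------------


def _lowpass(x: np.ndarray, sample_rate: float, cutoff: float = CW_CUTOFF) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis."""
    nyq = sample_rate / 2.0
    if cutoff >= nyq:
        return x
    b, a = sps.butter(CW_FILTER_ORDER, cutoff / nyq)
    return sps.filtfilt(b, a, x, axis=-1)


def _m0_to_concentration(
    dm0: np.ndarray, pathlengths: np.ndarray, wavelengths
) -> tuple[np.ndarray, np.ndarray]:
    """CW conversion: (Nw, Nt) dM0 -> (HbO, HbR) via effective pathlengths.

    ``dM0 = L_eff * dmua`` with ``L_eff`` the total M0 sensitivity (mm) at
    each wavelength, followed by the two-wavelength Beer-Lambert inversion.
    The homogeneous pathlength underestimates focal brain changes (partial
    volume), which is inherent to the CW treatment.
    """
    dmua = dm0 / pathlengths[:, None]
    return chromophores.absorption_to_concentration(dmua, wavelengths)


def cw_block_average(
    series: MomentTimeSeries,
    channel: int,
    onsets,
    sens: list[TwoLayerSensitivity],
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
    cutoff: float = CW_CUTOFF,
    method: str = "CW-BA",
) -> RecoveredHRF:
    """CW estimator: low-pass M0, Beer-Lambert inversion, block average."""
    if series.wavelengths.size < 2:
        raise ValueError("CW inversion needs two wavelengths")
    dm0 = series.values[channel, :, 0, :]  # (Nw, Nt)
    dm0 = dm0 - dm0.mean(axis=1, keepdims=True)
    dm0 = _lowpass(dm0, series.sample_rate, cutoff)
    pathlengths = np.array([tl.total[0] for tl in sens])
    hbo, hbr = _m0_to_concentration(dm0, pathlengths, series.wavelengths)
    return block_average(
        hbo, hbr, series.sample_rate, onsets, epoch_window, method=method
    )


def gaussian_basis(
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
    spacing: float = BASIS_SPACING,
    std: float = BASIS_STD,
) -> np.ndarray:
    """Centers (s) of the Gaussian temporal basis over the epoch window."""
    w0, w1 = epoch_window
    n = int(np.ceil((w1 - w0) / spacing)) + 1
    return w0 + spacing * np.arange(n)


def _basis_curves(tau: np.ndarray, centers: np.ndarray, std: float = BASIS_STD):
    """(Nb, len(tau)) Gaussian curves evaluated at epoch-relative times."""
    return np.exp(-0.5 * ((tau[None, :] - centers[:, None]) / std) ** 2)


def basis_regressors(
    times: np.ndarray,
    onsets,
    centers: np.ndarray,
    std: float = BASIS_STD,
) -> np.ndarray:
    """Onset-locked basis regressors on the recording grid, shape (Nb, Nt).

    Regressor k is ``sum_onsets phi_k(t - onset)`` so its coefficient is the
    HRF's amplitude on basis k; overlapping epochs superpose linearly.
    """
    out = np.zeros((centers.size, np.asarray(times).size))
    for onset in np.atleast_1d(onsets):
        out += _basis_curves(np.asarray(times, float) - onset, centers, std)
    return out


def cw_glm(
    series: MomentTimeSeries,
    ls_channel: int,
    ss_channel: int,
    onsets,
    sens: list[TwoLayerSensitivity],
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
) -> RecoveredHRF:
    """CW GLM: per-wavelength OLS of LS M0 on temporal bases + SS regressor.

    No drift terms and no lag on the SS regressor.  Basis coefficients are
    reassembled into an epoch-domain M0 response per wavelength and
    converted to concentration exactly as the CW block average.
    """
    centers = gaussian_basis(epoch_window)
    t = series.times
    reg = basis_regressors(t, onsets, centers)  # (Nb, Nt)
    nw = series.wavelengths.size
    if nw < 2:
        raise ValueError("CW GLM needs two wavelengths")
    tb = np.arange(
        round(epoch_window[0] * series.sample_rate),
        round(epoch_window[1] * series.sample_rate) + 1,
    ) / series.sample_rate
    curves = _basis_curves(tb, centers)  # (Nb, len(tb))
    dm0_hrf = np.zeros((nw, tb.size))
    for wi in range(nw):
        y = series.values[ls_channel, wi, 0, :]
        y = y - y.mean()
        ss = series.values[ss_channel, wi, 0, :]
        ss = ss - ss.mean()
        # demean the regressor columns as well: with the data mean removed,
        # an un-demeaned design would absorb the offset into the coefficients
        reg_d = reg - reg.mean(axis=1, keepdims=True)
        D = np.column_stack([reg_d.T, ss])  # (Nt, Nb+1)
        rank = np.linalg.matrix_rank(D, tol=PINV_RCOND * np.abs(D).max())
        if rank < D.shape[1]:
            norms = np.linalg.norm(D, axis=0)
            bad = [int(i) for i in np.flatnonzero(norms <= PINV_RCOND * norms.max())]
            raise np.linalg.LinAlgError(
                f"rank-deficient CW design (rank {rank}/{D.shape[1]}; "
                f"degenerate columns {bad})"
            )
        beta, *_ = np.linalg.lstsq(D, y, rcond=PINV_RCOND)
        dm0_hrf[wi] = beta[:-1] @ curves
    pathlengths = np.array([tl.total[0] for tl in sens])
    hbo, hbr = _m0_to_concentration(dm0_hrf, pathlengths, series.wavelengths)
    base = tb <= BASELINE_WINDOW[1]
    hbo = hbo - hbo[base].mean()
    hbr = hbr - hbr[base].mean()
    return RecoveredHRF(
        time_base=tb, hbo=hbo, hbr=hbr, method="CW-GLM", covariance_source="none"
    )


# ---------------------------------------------------------------------------
# TD moment GLM
# ---------------------------------------------------------------------------


def td_glm_design(
    series: MomentTimeSeries,
    ls_channel: int,
    ss_channel: int,
    onsets,
    sens_ls: list[TwoLayerSensitivity],
    sens_ss: list[TwoLayerSensitivity],
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
):
    """Design blocks and data blocks for the TD moment GLM.

    Returns ``(blocks, y, centers)`` where ``blocks`` is a list of six
    (Nt, 2 + 2*Nb) design matrices and ``y`` the matching list of six (Nt,)
    data vectors, both ordered [M0 l1, M0 l2, M1 l1, M1 l2, M2 l1, M2 l2].
    Column layout: [scalp(l1), scalp(l2), b1_HbO, b1_HbR, b2_HbO, ...].
    The scalp regressor for moment n at wavelength l is the SS M0 series
    scaled by S_n_scalp(l, rho_LS) / S0_scalp(l, rho_SS); the brain columns
    are the onset-locked bases scaled by S_n_brain(l, rho_LS) times the
    molar absorption of each hemoglobin species, so the basis coefficients
    are concentrations in uM.
    """
    nw = series.wavelengths.size
    if nw != 2:
        raise ValueError("the TD GLM is formulated for exactly two wavelengths")
    centers = gaussian_basis(epoch_window)
    reg = basis_regressors(series.times, onsets, centers)  # (Nb, Nt)
    # demean the regressors: the data blocks are mean-subtracted, so leaving
    # the regressor means in would bias the coefficients by the missing
    # intercept
    reg = reg - reg.mean(axis=1, keepdims=True)
    nb = centers.size
    nt = series.n_times
    kappa = chromophores.molar_absorption_matrix(series.wavelengths)  # (2, 2)
    blocks, y = [], []
    for n in range(3):
        for wi in range(nw):
            dm = series.values[ls_channel, wi, n, :]
            y.append(dm - dm.mean())
            ss = series.values[ss_channel, wi, 0, :]
            ss = ss - ss.mean()
            U = np.zeros((nt, 2 + 2 * nb))
            s0_ss_scalp = sens_ss[wi].scalp[0]
            U[:, wi] = sens_ls[wi].scalp[n] / s0_ss_scalp * ss
            sb = sens_ls[wi].brain[n]
            for k in range(nb):
                U[:, 2 + 2 * k] = sb * kappa[wi, 0] * reg[k]  # HbO
                U[:, 2 + 2 * k + 1] = sb * kappa[wi, 1] * reg[k]  # HbR
            blocks.append(U)
    return blocks, y, centers


def _interleaved_moment_covariance(cov3_per_wavelength: list[np.ndarray]) -> np.ndarray:
    """6x6 Z in [M0 l1, M0 l2, M1 l1, ...] order from per-wavelength 3x3s."""
    z = np.zeros((6, 6))
    for wi, c in enumerate(cov3_per_wavelength):
        for n in range(3):
            for m in range(3):
                z[2 * n + wi, 2 * m + wi] = c[n, m]
    return z


def solve_kronecker_wls(
    blocks, y, Z: np.ndarray, dense: bool = False, row_scales=None
) -> np.ndarray:
    """Solve the stacked WLS system with C = Z (x) I(Nt).

    ``blocks``/``y`` are the per-row-block design matrices and data vectors
    (list length q, each with Nt rows); Z is the q x q covariance of one
    multivariate sample.  The structured path assembles the normal equations
    as ``sum_ab Zinv[a,b] * U_a^T U_b`` without materializing the q*Nt
    square covariance; ``dense=True`` builds everything explicitly (test
    oracle for small Nt).

    ``row_scales`` (length q, e.g. the per-moment scales) conditions the
    covariance inversion through the exact identity
    ``Z^-1 = k (k Z k)^-1 k``: without it, a pseudo-inverse with a relative
    cutoff silently truncates the small-magnitude (M1, M2) blocks, whose
    entries sit tens of orders of magnitude below Var(M0).  Columns of the
    normal matrix are norm-equilibrated before the solve; both scalings
    leave the solution algebraically unchanged.
    """
    q = len(blocks)
    if Z.shape != (q, q):
        raise ValueError(f"Z must be {q}x{q}")
    ev = np.linalg.eigvalsh(Z)
    if ev[0] <= 0:
        warnings.warn(
            f"moment covariance not positive definite (min eigenvalue {ev[0]:.3g}); "
            "using pseudo-inverse with eigenvalue clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    if row_scales is None:
        Zinv = _psd_pinv(Z)
    else:
        k = np.asarray(row_scales, float)
        if k.shape != (q,) or np.any(k <= 0):
            raise ValueError("row_scales must be a positive vector of length q")
        Zinv = (k[:, None] * _psd_pinv(k[:, None] * Z * k[None, :])) * k[None, :]
    p = blocks[0].shape[1]
    if dense:
        U = np.vstack(blocks)
        Y = np.concatenate(y)
        nt = blocks[0].shape[0]
        Cinv = np.kron(Zinv, np.eye(nt))
        A = U.T @ Cinv @ U
        rhs = U.T @ Cinv @ Y
    else:
        A = np.zeros((p, p))
        rhs = np.zeros(p)
        # cache cross products; Zinv is symmetric so (a,b) and (b,a) pair up
        for a in range(q):
            Ua = blocks[a]
            for b in range(a, q):
                w = Zinv[a, b]
                if w == 0.0:
                    continue
                cross = Ua.T @ blocks[b]
                if b == a:
                    A += w * cross
                else:
                    A += w * (cross + cross.T)
            rhs_a = np.zeros(p)
            for b in range(q):
                if Zinv[a, b] != 0.0:
                    rhs_a += Zinv[a, b] * (Ua.T @ y[b])
            rhs += rhs_a
    # column equilibration for conditioning (exactly undone afterwards)
    d = np.sqrt(np.abs(np.diag(A)))
    d[d <= 0] = 1.0
    As = A / d[:, None] / d[None, :]
    beta = (_pinv(As) @ (rhs / d)) / d
    return beta


def td_glm(
    series: MomentTimeSeries,
    ls_channel: int,
    ss_channel: int,
    onsets,
    sens_ls: list[TwoLayerSensitivity],
    sens_ss: list[TwoLayerSensitivity],
    C: MomentCovariance | np.ndarray | None = None,
    covariance_source: str = "ZE",
    photon_budget: float | None = None,
    table: SensitivityTable | None = None,
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
    dense: bool = False,
) -> tuple[RecoveredHRF, np.ndarray]:
    """TD moment GLM over both wavelengths and all three moments.

    ``C`` may be a prebuilt 6x6 moment covariance; otherwise it is derived
    per ``covariance_source``: "ZE" (sample covariance of the six fitted
    series, white-noise assumption), "ZT" (theoretical shot-noise covariance
    at ``photon_budget`` photons/sample, needs ``table``), or "identity".
    Returns the recovered HRF and the full coefficient vector
    [bSS(l1), bSS(l2), b1_HbO, b1_HbR, ...].
    """
    blocks, y, centers = td_glm_design(
        series, ls_channel, ss_channel, onsets, sens_ls, sens_ss, epoch_window
    )
    if C is not None:
        Z = C.matrix if isinstance(C, MomentCovariance) else np.asarray(C, float)
    elif covariance_source.upper() == "ZE":
        Z = np.cov(np.stack(y))
    elif covariance_source.upper() == "ZT":
        if table is None or photon_budget is None:
            raise ValueError("ZT needs the sensitivity table and a photon budget")
        covs = []
        for wi, lam in enumerate(series.wavelengths):
            mua = baseline_absorption(float(lam))
            m1, mu2, mu3, mu4 = table.interp_central_moments(
                float(series.separations[ls_channel]), mua
            )
            covs.append(
                shot_noise_covariance_from_central_moments(
                    mu2, mu3, mu4, photon_budget
                ).matrix
            )
        Z = _interleaved_moment_covariance(covs)
    elif covariance_source.lower() == "identity":
        Z = np.eye(6)
    else:
        raise ValueError(f"unknown covariance source {covariance_source!r}")
    beta = solve_kronecker_wls(
        blocks, y, Z, dense=dense, row_scales=np.repeat(MOMENT_SCALES, 2)
    )
    tb = np.arange(
        round(epoch_window[0] * series.sample_rate),
        round(epoch_window[1] * series.sample_rate) + 1,
    ) / series.sample_rate
    curves = _basis_curves(tb, centers)
    hbo = beta[2::2] @ curves
    hbr = beta[3::2] @ curves
    base = tb <= BASELINE_WINDOW[1]
    hbo = hbo - hbo[base].mean()
    hbr = hbr - hbr[base].mean()
    hrf = RecoveredHRF(
        time_base=tb,
        hbo=hbo,
        hbr=hbr,
        method="TD-GLM",
        covariance_source=covariance_source.upper()
        if covariance_source.lower() != "identity"
        else "identity",
    )
    return hrf, beta


# ---------------------------------------------------------------------------
# covariances and the method suite
# ---------------------------------------------------------------------------


def theoretical_moment_covariance(
    table: SensitivityTable,
    separations,
    wavelength: float,
    photon_budgets,
) -> MomentCovariance:
    """Shot-noise (3Nc x 3Nc) moment-major covariance for a channel stack.

    Channels are independent; each 3x3 per-channel block comes from the
    lookup table's DTOF central moments at the channel's separation and the
    wavelength's baseline absorption, scaled by that channel's photon budget
    per sample.
    """
    separations = np.atleast_1d(np.asarray(separations, float))
    budgets = np.broadcast_to(np.asarray(photon_budgets, float), separations.shape)
    nc = separations.size
    mua = baseline_absorption(wavelength)
    out = np.zeros((3 * nc, 3 * nc))
    for c, (rho, n_ph) in enumerate(zip(separations, budgets)):
        m1, mu2, mu3, mu4 = table.interp_central_moments(float(rho), mua)
        cov3 = shot_noise_covariance_from_central_moments(mu2, mu3, mu4, n_ph).matrix
        for n in range(3):
            for m in range(3):
                out[n * nc + c, m * nc + c] = cov3[n, m]
    return MomentCovariance(matrix=out, source="theoretical")


def _detector_channels(series: MomentTimeSeries, detector: int):
    """(ss_channel, ls_channel) for one detector, either may be None.

    LS rule: usable channel with separation in [10, 34) mm closest to
    30 mm; ties break toward the smaller separation.  SS rule: smallest
    separation < 10 mm.
    """
    idx = np.flatnonzero(series.detector_ids == detector)
    ss = ls = None
    ss_best = np.inf
    ls_key = None
    for ci in idx:
        rho = series.separations[ci]
        if rho < 10.0:
            if rho < ss_best:
                ss, ss_best = int(ci), rho
        elif rho < 34.0:
            key = (abs(rho - 30.0), rho)
            if ls_key is None or key < ls_key:
                ls, ls_key = int(ci), key
    return ss, ls


def _brain_to_hrf(
    brain_by_wavelength: list[LayerAbsorptionSeries],
    wavelengths,
    onsets,
    method: str,
    covariance_source: str,
    epoch_window=EPOCH_WINDOW,
) -> RecoveredHRF:
    """Unmix brain absorption series to hemoglobin and block-average."""
    dmua = np.stack([b.brain for b in brain_by_wavelength])
    hbo, hbr = chromophores.absorption_to_concentration(dmua, wavelengths)
    return block_average(
        hbo,
        hbr,
        brain_by_wavelength[0].sample_rate,
        onsets,
        epoch_window,
        method=method,
        covariance_source=covariance_source,
    )


def run_method_suite(
    session: SyntheticSession,
    table: SensitivityTable,
    methods=METHODS,
    covariance_source: str = "ZE",
    epoch_window: tuple[float, float] = EPOCH_WINDOW,
) -> list[RecoveryResult]:
    """Apply every requested method to every eligible detector.

    Per-method failures are isolated into the result's ``error`` field.
    TD covariance handling: "ZE" estimates the stacked-moment covariance
    from the series being fit; "ZT" uses the theoretical shot-noise model at
    the session's photon budgets; "identity" uses the identity (after the
    solver's own moment scaling).
    """
    series = session.augmented
    params = session.generator_params or {}
    noise = params.get("noise_config", {})
    ss_budget = float(noise.get("ss_photons", 1e6))
    ls_budget = float(noise.get("ls_photons", 1e5))
    scalp_thickness = session.scalp_thickness
    wavelengths = series.wavelengths
    results: list[RecoveryResult] = []
    detectors = np.unique(series.detector_ids)
    cov_up = covariance_source.upper()

    def sens_for(ci):
        return [
            interp_two_layer(
                table,
                float(series.separations[ci]),
                baseline_absorption(float(lam)),
                scalp_thickness,
                wavelength=float(lam),
            )
            for lam in wavelengths
        ]

    def md_cov(chs, budgets, wi):
        if cov_up == "ZT":
            return theoretical_moment_covariance(
                table, series.separations[list(chs)], float(wavelengths[wi]), budgets
            )
        if cov_up == "ZE":
            return empirical_covariance(series, channels=list(chs), wavelength_index=wi)
        if cov_up == "IDENTITY":
            return MomentCovariance(np.eye(3 * len(chs)), source="identity")
        raise ValueError(f"unknown covariance source {covariance_source!r}")

    for det in detectors:
        ss, ls = _detector_channels(series, int(det))
        for method in methods:
            res = RecoveryResult(
                detector=int(det),
                method=method,
                hrf=None,
                channels={"ss": ss, "ls": ls},
            )
            try:
                target = ss if method in ("CW-SS", "TD-SS") else ls
                if target is None:
                    raise ValueError(
                        f"detector {det} lacks the channel class for {method}"
                    )
                train = session.trains.get(target)
                if train is None:
                    raise ValueError(
                        f"channel {target} was not augmented; no ground-truth onsets"
                    )
                onsets = train.onsets
                if method in ("CW-BA", "CW-SS"):
                    res.hrf = cw_block_average(
                        series, target, onsets, sens_for(target), epoch_window,
                        method=method,
                    )
                elif method == "CW-GLM":
                    if ss is None:
                        raise ValueError(f"detector {det} lacks an SS channel")
                    res.hrf = cw_glm(
                        series, ls, ss, onsets, sens_for(ls), epoch_window
                    )
                elif method in ("TD-SS", "TD-LS", "TD-LS+SS"):
                    if method == "TD-SS":
                        chs, budgets = [ss], [ss_budget]
                    elif method == "TD-LS":
                        chs, budgets = [ls], [ls_budget]
                    else:
                        if ss is None:
                            raise ValueError(f"detector {det} lacks an SS channel")
                        chs, budgets = [ls, ss], [ls_budget, ss_budget]
                    sens_all = {ci: sens_for(ci) for ci in chs}
                    layers = []
                    for wi in range(wavelengths.size):
                        Z = md_cov(chs, budgets, wi)
                        layers.append(
                            td_multidistance(
                                series,
                                chs,
                                [sens_all[ci][wi] for ci in chs],
                                Z,
                                wavelength_index=wi,
                            )
                        )
                    res.hrf = _brain_to_hrf(
                        layers, wavelengths, onsets, method, cov_up, epoch_window
                    )
                elif method == "TD-GLM":
                    if ss is None:
                        raise ValueError(f"detector {det} lacks an SS channel")
                    res.hrf, _ = td_glm(
                        series,
                        ls,
                        ss,
                        onsets,
                        sens_for(ls),
                        sens_for(ss),
                        covariance_source=cov_up
                        if cov_up != "IDENTITY"
                        else "identity",
                        photon_budget=ls_budget,
                        table=table,
                        epoch_window=epoch_window,
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:  # isolate per-method failures
                res.error = f"{type(exc).__name__}: {exc}"
            results.append(res)
    return results
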