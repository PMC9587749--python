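"""Synthetic moment time series with known hemodynamic ground truth.

The generator emulates the statistical structure of resting-state
time-domain NIRS recordings: superficial (scalp) hemodynamic fluctuations —
cardiac, respiratory and low-frequency oscillations plus slow drift —
dominate every channel, smaller fluctuations originate in the brain layer,
and photon-counting (shot) noise rides on top of each moment.  A known
hemodynamic response function (HRF) convolved with a randomized stimulus
train is then injected into the brain layer of selected channels through
the same layered forward model used for recovery, so every recovery method
can be scored against exact ground truth.

Conventions: concentrations in micromolar (uM), absorption in mm^-1,
times in seconds.  A "detector" carries one short-separation (SS) channel
and one long-separation (LS) channel that see the same patch of scalp, so
the SS channel is an informative regressor for superficial physiology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import chromophores
from .moments import MomentTimeSeries, shot_noise_covariance_from_central_moments
from .transport import SensitivityTable, baseline_absorption, interp_two_layer

__all__ = [
    "CanonicalHRF",
    "StimulusTrain",
    "ProbeGeometry",
    "NoiseConfig",
    "SyntheticSession",
    "make_hrf",
    "make_stimulus_train",
    "simulate_resting",
    "augment",
    "simulate_session",
]


@dataclass(frozen=True)
class CanonicalHRF:
    """Canonical double-gamma HRF sampled on ``time_base`` (s, covers -2..18).

    ``hbo``/``hbr`` are concentration changes in uM; at scale 1 the HbO peak
    is 0.6 uM and the HbR trough -0.2 uM; both are identically zero for
    t <= 0.
    """

    time_base: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    scale: float

    def sample(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(HbO, HbR) linearly interpolated at times ``t``, zero outside."""
        t = np.asarray(t, float)
        hbo = np.interp(t, self.time_base, self.hbo, left=0.0, right=0.0)
        hbr = np.interp(t, self.time_base, self.hbr, left=0.0, right=0.0)
        return hbo, hbr


@dataclass(frozen=True)
class StimulusTrain:
    """Randomized stimulus onsets within one recording."""

    onsets: np.ndarray  # s, strictly increasing
    mean_isi: float = 21.0
    sd_isi: float = 3.0
    seed: int = 0

    def __post_init__(self):
        onsets = np.asarray(self.onsets, float)
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        object.__setattr__(self, "onsets", onsets)

    @property
    def n_onsets(self) -> int:
        return self.onsets.size


# double-gamma shape parameters: peak ~6 s, small undershoot around 12-16 s
_HRF_PEAK_SHAPE = 6.0
_HRF_UNDER_SHAPE = 16.0
_HRF_TIMESCALE = 1.0
_HRF_UNDER_RATIO = 0.1
#: peak amplitudes at scale 1 (uM); HbR has the same shape at -1/3 amplitude
HRF_HBO_PEAK = 0.6
HRF_HBR_PEAK = -0.2


def make_hrf(
    scale: float = 1.0, sample_rate: float = 7.0, t_start: float = -2.0, t_end: float = 18.0
) -> CanonicalHRF:
    """Canonical HRF: difference of two gamma densities, peak-normalized.

    At scale 1 the HbO curve peaks at 0.6 uM and the HbR curve (same shape,
    amplitude ratio -1/3) troughs at -0.2 uM.  The shape returns to within
    5% of its peak magnitude by t = 18 s.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = int(round((t_end - t_start) * sample_rate)) + 1
    t = t_start + np.arange(n) / sample_rate
    shape = _double_gamma(t)
    hbo = HRF_HBO_PEAK * scale * shape
    hbr = HRF_HBR_PEAK * scale * shape
    return CanonicalHRF(time_base=t, hbo=hbo, hbr=hbr, scale=float(scale))


def _double_gamma(t: np.ndarray) -> np.ndarray:
    """Double-gamma shape, zero for t <= 0, peak exactly 1 on the given grid.

    Normalizing over the evaluation grid (rather than the continuous
    maximum) makes the stated peak amplitudes exact on the returned curves;
    the grid-dependence of the scaling is ~1e-7 at 7 Hz sampling.
    """
    t = np.asarray(t, float)
    shape = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / _HRF_TIMESCALE
    g1 = tp ** (_HRF_PEAK_SHAPE - 1) * np.exp(-tp)
    g2 = tp ** (_HRF_UNDER_SHAPE - 1) * np.exp(-tp)
    from math import gamma as _gamma

    g1 /= _gamma(_HRF_PEAK_SHAPE)
    g2 /= _gamma(_HRF_UNDER_SHAPE)
    shape[pos] = g1 - _HRF_UNDER_RATIO * g2
    peak = shape.max()
    if peak <= 0:
        return np.zeros_like(t)
    return shape / peak


def make_stimulus_train(
    duration: float,
    mean_isi: float = 21.0,
    sd_isi: float = 3.0,
    seed: int = 0,
    first_onset_window: tuple[float, float] = (5.0, None),
) -> StimulusTrain:
    """Random onset train with truncated-normal inter-stimulus intervals.

    The first onset is uniform in [5 s, mean_isi] (avoiding edge epochs);
    subsequent intervals are normal(mean_isi, sd_isi) truncated at zero
    (non-positive draws rejected).  ``sd_isi = 0`` gives exactly uniform
    spacing.  All randomness comes from ``seed``.
    """
    if duration <= mean_isi:
        raise ValueError("duration must exceed mean_isi")
    if sd_isi < 0:
        raise ValueError("sd_isi must be non-negative")
    if mean_isi <= 0:
        raise ValueError("mean_isi must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = first_onset_window
    if hi is None:
        hi = mean_isi
    onsets = [rng.uniform(lo, hi)]
    while True:
        if sd_isi == 0:
            isi = mean_isi
        else:
            isi = rng.normal(mean_isi, sd_isi)
            while isi <= 0:
                isi = rng.normal(mean_isi, sd_isi)
        nxt = onsets[-1] + isi
        if nxt >= duration:
            break
        onsets.append(nxt)
    return StimulusTrain(
        onsets=np.asarray(onsets), mean_isi=mean_isi, sd_isi=sd_isi, seed=int(seed)
    )


@dataclass(frozen=True)
class ProbeGeometry:
    """SS/LS channel layout: each detector pairs one SS and one LS channel."""

    n_detectors: int = 20
    ss_separation: float = 8.0  # mm
    ls_separation: float = 30.0  # mm
    wavelengths: tuple[float, ...] = (690.0, 850.0)

    def channel_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(separations, detector_ids) with channels ordered SS, LS per detector."""
        seps = np.tile([self.ss_separation, self.ls_separation], self.n_detectors)
        dets = np.repeat(np.arange(self.n_detectors), 2)
        return seps, dets


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes of the resting physiology and the photon budget.

    Concentration amplitudes are uM of HbO in the scalp layer; HbR tracks
    HbO with ``hbr_ratio`` plus an independent component.  ``shared_fraction``
    mixes a per-detector process (seen by both SS and LS channel) with a
    channel-specific process; it is chosen so SS and LS M0 on one detector
    correlate strongly but not perfectly.  The default amplitudes make
    LS-channel M0 physiology clearly larger than a scale-1 HRF footprint,
    which is what makes CW recovery hard.
    """

    cardiac_freq: float = 1.1  # Hz
    cardiac_amp: float = 0.7  # uM HbO in scalp
    resp_freq: float = 0.25  # Hz
    resp_amp: float = 0.3
    lf_freq: float = 0.1  # Hz (Mayer-wave band)
    lf_amp: float = 0.5
    drift_step: float = 0.011  # uM per sample, random walk
    shared_fraction: float = 0.98  # weight of the per-detector shared process
    hbr_ratio: float = -0.3  # scalp HbR tracks HbO with this factor
    hbr_indep_amp: float = 0.15  # uM, independent scalp HbR component
    brain_lf_amp: float = 0.08  # uM, brain-layer low-frequency fluctuation
    brain_white_amp: float = 0.02  # uM, brain-layer white component
    ss_photons: float = 1e6  # photons per sample, SS channels
    ls_photons: float = 1e5  # photons per sample, LS channels
    shot_noise: bool = True

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """All physiological amplitudes zero and shot noise off."""
        return cls(
            cardiac_amp=0.0,
            resp_amp=0.0,
            lf_amp=0.0,
            drift_step=0.0,
            hbr_indep_amp=0.0,
            brain_lf_amp=0.0,
            brain_white_amp=0.0,
            shot_noise=False,
        )


def _oscillation(rng, t, freq, amp):
    """Sinusoid with random phase and slowly wandering amplitude."""
    if amp == 0:
        return np.zeros_like(t)
    phase = rng.uniform(0, 2 * np.pi)
    # +/-20% amplitude modulation at one tenth of the carrier frequency
    mod = 1.0 + 0.2 * np.sin(2 * np.pi * 0.1 * freq * t + rng.uniform(0, 2 * np.pi))
    return amp * mod * np.sin(2 * np.pi * freq * t + phase)


def _drift(rng, n, step):
    if step == 0:
        return np.zeros(n)
    walk = np.cumsum(rng.normal(0.0, step, n))
    return walk - walk.mean()


def _scalp_concentration(rng, t, cfg: NoiseConfig):
    """One realization of the scalp (HbO, HbR) concentration process."""
    hbo = (
        _oscillation(rng, t, cfg.cardiac_freq, cfg.cardiac_amp)
        + _oscillation(rng, t, cfg.resp_freq, cfg.resp_amp)
        + _oscillation(rng, t, cfg.lf_freq, cfg.lf_amp)
        + _drift(rng, t.size, cfg.drift_step)
    )
    hbr = cfg.hbr_ratio * hbo + _oscillation(rng, t, cfg.lf_freq, cfg.hbr_indep_amp)
    return hbo, hbr


def _brain_concentration(rng, t, cfg: NoiseConfig):
    hbo = _oscillation(rng, t, cfg.lf_freq, cfg.brain_lf_amp)
    if cfg.brain_white_amp > 0:
        hbo = hbo + rng.normal(0.0, cfg.brain_white_amp, t.size)
    hbr = cfg.hbr_ratio * hbo
    return hbo, hbr


def channel_sensitivities(
    table: SensitivityTable,
    separations,
    wavelengths,
    scalp_thickness: float = 13.0,
):
    """Two-layer sensitivities for every (channel, wavelength) pair.

    Returns a dict ``(channel_index, wavelength_index) -> TwoLayerSensitivity``
    and a list of (channel_index, reason) failures for channels whose
    separation or baseline absorption falls outside the table.
    """
    sens = {}
    failures = []
    for ci, rho in enumerate(np.asarray(separations, float)):
        try:
            for wi, lam in enumerate(wavelengths):
                mua = baseline_absorption(lam)
                sens[(ci, wi)] = interp_two_layer(
                    table, float(rho), mua, scalp_thickness, wavelength=float(lam)
                )
        except ValueError as exc:
            failures.append((ci, str(exc)))
            for wi in range(len(wavelengths)):
                sens.pop((ci, wi), None)
    return sens, failures


def simulate_resting(
    geometry: ProbeGeometry,
    table: SensitivityTable,
    duration: float,
    sample_rate: float = 7.0,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    scalp_thickness: float = 13.0,
) -> MomentTimeSeries:
    """Resting moment time series with scalp-dominant physiology.

    Per detector, one shared scalp concentration process drives both the SS
    and the LS channel (mixed with a channel-specific process per
    ``NoiseConfig.shared_fraction``); smaller independent fluctuations occur
    in the brain layer.  Concentrations become absorption changes via
    Beer-Lambert and moment changes via the two-layer sensitivities; shot
    noise is added per sample from the theoretical covariance at the
    configured photon budget.  Fully determined by (seed, parameters).
    """
    cfg = noise_config if noise_config is not None else NoiseConfig()
    if sample_rate <= 2 * cfg.cardiac_freq:
        warnings.warn(
            f"sample rate {sample_rate} Hz aliases the {cfg.cardiac_freq} Hz "
            "cardiac oscillation",
            RuntimeWarning,
            stacklevel=2,
        )
    nt = int(round(duration * sample_rate))
    if nt < 2:
        raise ValueError("duration too short for the sample rate")
    t = np.arange(nt) / sample_rate
    seps, dets = geometry.channel_arrays()
    nc, nw = seps.size, len(geometry.wavelengths)
    kappa = chromophores.molar_absorption_matrix(geometry.wavelengths)  # (Nw, 2)

    sens, failures = channel_sensitivities(
        table, seps, geometry.wavelengths, scalp_thickness
    )
    if failures:
        raise ValueError(
            "sensitivity table does not cover all channels: "
            + "; ".join(f"channel {ci}: {msg}" for ci, msg in failures)
        )

    rng = np.random.default_rng(seed)
    values = np.zeros((nc, nw, 3, nt))
    w_mix = cfg.shared_fraction
    w_own = np.sqrt(max(1.0 - w_mix**2, 0.0))
    for d in range(geometry.n_detectors):
        shared = _scalp_concentration(rng, t, cfg)
        for ci in np.flatnonzero(dets == d):
            own = _scalp_concentration(rng, t, cfg)
            scalp_hbo = w_mix * shared[0] + w_own * own[0]
            scalp_hbr = w_mix * shared[1] + w_own * own[1]
            brain_hbo, brain_hbr = _brain_concentration(rng, t, cfg)
            for wi in range(nw):
                tl = sens[(ci, wi)]
                dmua_scalp = kappa[wi, 0] * scalp_hbo + kappa[wi, 1] * scalp_hbr
                dmua_brain = kappa[wi, 0] * brain_hbo + kappa[wi, 1] * brain_hbr
                base = _baseline_moments(table, tl)
                for n in range(3):
                    values[ci, wi, n] = (
                        base[n]
                        + tl.scalp[n] * dmua_scalp
                        + tl.brain[n] * dmua_brain
                    )
                if cfg.shot_noise:
                    budget = (
                        cfg.ss_photons if seps[ci] < 10.0 else cfg.ls_photons
                    )
                    values[ci, wi] += _shot_noise_draws(
                        rng, table, tl, budget, nt
                    )
    return MomentTimeSeries(
        values=values,
        separations=seps,
        wavelengths=np.asarray(geometry.wavelengths, float),
        sample_rate=float(sample_rate),
        detector_ids=dets,
    )


def _baseline_moments(table: SensitivityTable, tl) -> np.ndarray:
    """Baseline (M0, M1, M2) at a channel's separation and wavelength."""
    mua = baseline_absorption(tl.wavelength)
    cm = table.interp_central_moments(tl.separation, mua)  # (M1, mu2, mu3, mu4)
    # M0 baseline uses the table's relative detected intensity; the overall
    # normalization is arbitrary and cancels in any change analysis
    sw = table._bilinear(tl.separation, mua, table.sum_weights[..., None])[0]
    return np.array([-np.log(sw), cm[0], cm[1]])


def _shot_noise_draws(rng, table: SensitivityTable, tl, budget: float, nt: int):
    """(3, nt) Gaussian draws from the shot-noise covariance model."""
    mua = baseline_absorption(tl.wavelength)
    m1, mu2, mu3, mu4 = table.interp_central_moments(tl.separation, mua)
    cov = shot_noise_covariance_from_central_moments(mu2, mu3, mu4, budget).matrix
    # eigen-decomposition is more robust than Cholesky for the near-singular
    # M2 block at high photon budgets
    evals, evecs = np.linalg.eigh(cov)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    return root @ rng.standard_normal((3, nt))


@dataclass
class SyntheticSession:
    """Resting + augmented series with complete generation ground truth.

    ``added`` is the exact forward-modeled HRF contribution:
    ``augmented.values == resting.values + added`` bit-consistently.
    ``trains`` maps channel index -> StimulusTrain for augmented channels.
    """

    resting: MomentTimeSeries
    augmented: MomentTimeSeries
    hrf: CanonicalHRF
    trains: dict[int, StimulusTrain]
    added: np.ndarray
    scalp_thickness: float
    generator_params: dict
    failures: list = field(default_factory=list)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            self.resting.to_hdf5(f.create_group("resting"))
            self.augmented.to_hdf5(f.create_group("augmented"))
            f.create_dataset("added", data=self.added)
            g = f.create_group("hrf")
            g.create_dataset("time_base", data=self.hrf.time_base)
            g.create_dataset("hbo", data=self.hrf.hbo)
            g.create_dataset("hbr", data=self.hrf.hbr)
            g.attrs["scale"] = self.hrf.scale
            tg = f.create_group("trains")
            for ci, train in self.trains.items():
                sub = tg.create_group(str(ci))
                sub.create_dataset("onsets", data=train.onsets)
                sub.attrs["mean_isi"] = train.mean_isi
                sub.attrs["sd_isi"] = train.sd_isi
                sub.attrs["seed"] = train.seed
            f.attrs["scalp_thickness"] = self.scalp_thickness
            f.attrs["generator_params"] = json.dumps(self.generator_params)
            f.attrs["failures"] = json.dumps(self.failures)

    @classmethod
    def load(cls, path) -> "SyntheticSession":
        with h5py.File(path, "r") as f:
            g = f["hrf"]
            hrf = CanonicalHRF(
                time_base=g["time_base"][()],
                hbo=g["hbo"][()],
                hbr=g["hbr"][()],
                scale=float(g.attrs["scale"]),
            )
            trains = {}
            for key, sub in f["trains"].items():
                trains[int(key)] = StimulusTrain(
                    onsets=sub["onsets"][()],
                    mean_isi=float(sub.attrs["mean_isi"]),
                    sd_isi=float(sub.attrs["sd_isi"]),
                    seed=int(sub.attrs["seed"]),
                )
            return cls(
                resting=MomentTimeSeries.from_hdf5(f["resting"]),
                augmented=MomentTimeSeries.from_hdf5(f["augmented"]),
                hrf=hrf,
                trains=trains,
                added=f["added"][()],
                scalp_thickness=float(f.attrs["scalp_thickness"]),
                generator_params=json.loads(f.attrs["generator_params"]),
                failures=json.loads(f.attrs["failures"]),
            )


def hrf_convolved_concentration(
    hrf: CanonicalHRF, train: StimulusTrain, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(HbO, HbR) time courses: the HRF superposed at every onset.

    Evaluated by interpolating the HRF curve at t - onset, so overlapping
    responses sum linearly and no discretization of the onsets occurs.
    """
    hbo = np.zeros_like(times)
    hbr = np.zeros_like(times)
    for onset in train.onsets:
        h_o, h_r = hrf.sample(times - onset)
        hbo += h_o
        hbr += h_r
    return hbo, hbr


def augment(
    resting: MomentTimeSeries,
    hrf: CanonicalHRF,
    train: StimulusTrain | dict[int, StimulusTrain],
    table: SensitivityTable,
    scalp_thickness: float = 13.0,
    max_separation: float = 34.0,
    augment_ss: bool = True,
    mean_subtract: bool = True,
    generator_params: dict | None = None,
) -> SyntheticSession:
    """Inject the HRF into the brain layer of eligible channels.

    Per channel and wavelength the added moment change is
    ``dMn(t) = Sn_brain(lambda, rho) * dmua_brain(lambda, t)`` with
    ``dmua_brain`` the Beer-Lambert projection of the HRF convolved with the
    channel's onset train.  Channels with separation >= ``max_separation``
    are never augmented; SS channels are augmented by default (set
    ``augment_ss=False`` to keep them response-free).  ``train`` may be a
    single train (shared by all channels) or a per-channel mapping.
    Channels whose separation the table cannot serve are skipped and listed
    in ``failures``.
    """
    values = np.asarray(resting.values, float).copy()
    if mean_subtract:
        values = values - values.mean(axis=3, keepdims=True)
    base = MomentTimeSeries(
        values=values,
        separations=resting.separations,
        wavelengths=resting.wavelengths,
        sample_rate=resting.sample_rate,
        detector_ids=resting.detector_ids,
    )
    times = base.times
    kappa = chromophores.molar_absorption_matrix(base.wavelengths)  # (Nw, 2)
    added = np.zeros_like(values)
    trains: dict[int, StimulusTrain] = {}
    failures: list = []
    for ci, rho in enumerate(base.separations):
        if rho >= max_separation:
            continue
        if not augment_ss and rho < 10.0:
            continue
        tr = train[ci] if isinstance(train, dict) else train
        if tr is None:
            continue
        try:
            tls = [
                interp_two_layer(
                    table,
                    float(rho),
                    baseline_absorption(lam),
                    scalp_thickness,
                    wavelength=float(lam),
                )
                for lam in base.wavelengths
            ]
        except ValueError as exc:
            failures.append([int(ci), str(exc)])
            continue
        hbo, hbr = hrf_convolved_concentration(hrf, tr, times)
        trains[ci] = tr
        for wi in range(len(base.wavelengths)):
            dmua = kappa[wi, 0] * hbo + kappa[wi, 1] * hbr  # mm^-1 (t)
            for n in range(3):
                added[ci, wi, n] = tls[wi].brain[n] * dmua
    aug = MomentTimeSeries(
        values=values + added,
        separations=base.separations,
        wavelengths=base.wavelengths,
        sample_rate=base.sample_rate,
        detector_ids=base.detector_ids,
    )
    # canonicalize to JSON-representable types so save/load round-trips exactly
    params = json.loads(json.dumps(dict(generator_params or {})))
    params.setdefault("scale", hrf.scale)
    params.setdefault("scalp_thickness", scalp_thickness)
    params.setdefault("augment_ss", augment_ss)
    params.setdefault("max_separation", max_separation)
    return SyntheticSession(
        resting=base,
        augmented=aug,
        hrf=hrf,
        trains=trains,
        added=added,
        scalp_thickness=float(scalp_thickness),
        generator_params=params,
        failures=failures,
    )


def simulate_session(
    table: SensitivityTable,
    geometry: ProbeGeometry | None = None,
    duration: float = 300.0,
    sample_rate: float = 7.0,
    scale: float = 1.0,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    scalp_thickness: float = 13.0,
    augment_ss: bool = True,
) -> SyntheticSession:
    """End-to-end session: resting physiology + per-channel HRF injection.

    Every augmented channel gets its own stimulus train (seeded from
    ``seed``), mirroring independently randomized runs.
    """
    geometry = geometry or ProbeGeometry()
    resting = simulate_resting(
        geometry,
        table,
        duration,
        sample_rate=sample_rate,
        noise_config=noise_config,
        seed=seed,
        scalp_thickness=scalp_thickness,
    )
    hrf = make_hrf(scale, sample_rate=max(sample_rate, 7.0))
    ss = np.random.SeedSequence(entropy=int(seed) + 0x5EED)
    train_seeds = ss.generate_state(resting.n_channels)
    trains = {
        ci: make_stimulus_train(duration, seed=int(train_seeds[ci]))
        for ci in range(resting.n_channels)
    }
    cfg = noise_config if noise_config is not None else NoiseConfig()
    params = {
        "seed": int(seed),
        "duration": duration,
        "sample_rate": sample_rate,
        "scale": scale,
        "scalp_thickness": scalp_thickness,
        "geometry": asdict(geometry),
        "noise_config": asdict(cfg),
        "augment_ss": augment_ss,
    }
    return augment(
        resting,
        hrf,
        trains,
        table,
        scalp_thickness=scalp_thickness,
        augment_ss=augment_ss,
        generator_params=params,
    )
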