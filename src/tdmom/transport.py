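"""Layered-medium photon Monte Carlo and moment sensitivity tables.

The tissue is modeled as a stack of plane-parallel layers (default twenty:
nineteen 1 mm layers over a semi-infinite bottom layer) sharing a single
scattering coefficient, anisotropy and refractive index.  A time-resolved
Monte Carlo simulation records, for every photon detected at the surface,
its time of flight and its partial pathlength in every layer.  Absorption is
applied afterwards through survival weights, so a single simulation serves
every absorption query — which is also what makes first-derivative moment
sensitivities exact on the simulated sample:

    S0j = <l_j>_w                  (mm per mm^-1)
    S1j = -Cov_w(t, l_j)           (s  mm per mm^-1)
    S2j = -Cov_w((t - M1)^2, l_j)  (s^2 mm per mm^-1)

with weighted expectations over detected photons.  These follow from
differentiating the moment definitions with respect to the layer absorption
(d w_i / d mu_a[j] = -l_ij w_i).

The detector exploits the lateral symmetry of the medium: photons escaping
the top surface in the annulus ``separation +/- 1 mm`` are accepted, which
is the ring average of a 1 mm radius disk detector and serves every
source–detector separation from a single run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from . import chromophores
from ._mc import C_MM_PER_S, propagate
from .moments import MomentVector

__all__ = [
    "TissueModel",
    "PhotonRecordSet",
    "SensitivityTable",
    "TwoLayerSensitivity",
    "TableConfig",
    "run_mc",
    "moments_from_records",
    "records_central_moments",
    "sensitivities_from_records",
    "build_lookup_table",
    "interp_two_layer",
    "baseline_absorption",
]


@dataclass(frozen=True, eq=False)
class TissueModel:
    """Optical model of the layered head: scalp/skull/brain as 1 mm slabs.

    ``absorption`` is the nominal per-layer absorption (mm^-1) used when an
    operation is not given an explicit absorption vector.
    """

    n_layers: int = 20
    layer_thickness: float = 1.0  # mm, layers 1..n-1; last layer semi-infinite
    scattering: float = 10.0  # mm^-1
    anisotropy: float = 0.9
    refractive_index: float = 1.4
    absorption: np.ndarray = None  # mm^-1 per layer
    depth: float = 100.0  # mm, termination depth of the volume
    lateral_extent: float = 50.0  # mm, lateral termination radius
    t_max: float = 5e-9  # s, DTOF support

    def __post_init__(self):
        if self.scattering <= 0 or self.refractive_index <= 0 or self.layer_thickness <= 0:
            raise ValueError("optical properties must be positive")
        if not 0.0 <= self.anisotropy < 1.0:
            raise ValueError("anisotropy must be in [0, 1)")
        mua = self.absorption
        if mua is None:
            mua = np.full(self.n_layers, 0.01)
        mua = np.asarray(mua, float)
        if mua.shape != (self.n_layers,):
            raise ValueError(f"absorption must have shape ({self.n_layers},)")
        if np.any(mua < 0):
            raise ValueError("absorption must be non-negative")
        object.__setattr__(self, "absorption", mua)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TissueModel):
            return NotImplemented
        return self.to_json() == other.to_json()

    def __hash__(self) -> int:
        return hash(self.to_json())

    @property
    def max_path(self) -> float:
        """Pathlength (mm) corresponding to the DTOF support ``t_max``."""
        return self.t_max * C_MM_PER_S / self.refractive_index

    def to_json(self) -> str:
        d = {
            "n_layers": self.n_layers,
            "layer_thickness": self.layer_thickness,
            "scattering": self.scattering,
            "anisotropy": self.anisotropy,
            "refractive_index": self.refractive_index,
            "absorption": list(self.absorption),
            "depth": self.depth,
            "lateral_extent": self.lateral_extent,
            "t_max": self.t_max,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TissueModel":
        d = json.loads(text)
        d["absorption"] = np.asarray(d["absorption"])
        return cls(**d)


@dataclass
class PhotonRecordSet:
    """Detected-photon records from one simulation.

    ``partial_pathlengths`` is (Nd, n_layers) in mm; ``times`` in seconds;
    ``radii`` are the surface exit radii in mm.  ``weights`` are the survival
    weights at the simulation's nominal absorption — all ones, because
    absorption is applied at query time via :func:`absorption_weights`.
    """

    times: np.ndarray
    radii: np.ndarray
    partial_pathlengths: np.ndarray
    n_launched: int
    seed: int
    model: TissueModel
    separation: float | None = None

    @property
    def n_detected(self) -> int:
        return self.times.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return np.ones(self.n_detected)

    def absorption_weights(self, absorption) -> np.ndarray:
        """Survival weights exp(-sum_j mu_a[j] l_j) for an absorption vector."""
        mua = np.asarray(absorption, float)
        if mua.shape != (self.model.n_layers,):
            raise ValueError(
                f"absorption vector must have shape ({self.model.n_layers},), "
                f"got {mua.shape}"
            )
        return np.exp(-self.partial_pathlengths.astype(float) @ mua)

    def select_ring(self, separation: float, halfwidth: float = 1.0) -> "PhotonRecordSet":
        """Sub-select photons whose exit radius lies within +/- halfwidth."""
        mask = np.abs(self.radii - separation) <= halfwidth
        return replace(
            self,
            times=self.times[mask],
            radii=self.radii[mask],
            partial_pathlengths=self.partial_pathlengths[mask],
            separation=separation,
        )


def _run_kernel(
    model: TissueModel, rmin: float, rmax: float, n_photons: int, seed: int
) -> PhotonRecordSet:
    n_photons = int(n_photons)
    out_path = np.empty(n_photons)
    out_r = np.empty(n_photons)
    # float64 scratch for the kernel (a float32 buffer slows it down a lot);
    # the kept rows are downcast to float32 for storage below
    out_L = np.empty((n_photons, model.n_layers))
    n_kept = propagate(
        n_photons,
        int(seed),
        model.scattering,
        model.anisotropy,
        model.refractive_index,
        model.n_layers,
        model.layer_thickness,
        model.depth,
        model.lateral_extent,
        float(rmin),
        float(rmax),
        model.max_path,
        out_path,
        out_r,
        out_L,
    )
    times = out_path[:n_kept] * model.refractive_index / C_MM_PER_S
    return PhotonRecordSet(
        times=times,
        radii=out_r[:n_kept].copy(),
        partial_pathlengths=out_L[:n_kept].astype(np.float32),
        n_launched=n_photons,
        seed=int(seed),
        model=model,
    )


def run_mc(
    model: TissueModel,
    separation: float,
    n_photons: int = 100_000,
    seed: int = 0,
    detector_halfwidth: float = 1.0,
) -> PhotonRecordSet:
    """Simulate photons and keep those detected at ``separation`` +/- 1 mm.

    Reproducible bit-for-bit under a fixed seed.  Raises if no photon is
    detected (suggesting more photons or a different geometry).
    """
    if not 0 < separation < model.lateral_extent:
        raise ValueError("separation must lie inside the simulated volume")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rec = _run_kernel(
        model,
        max(separation - detector_halfwidth, 0.0),
        separation + detector_halfwidth,
        n_photons,
        seed,
    )
    rec.separation = float(separation)
    if rec.n_detected == 0:
        raise RuntimeError(
            f"no photons detected at separation {separation} mm with "
            f"{n_photons:.0g} launched; increase n_photons or the detector size"
        )
    return rec


def _weighted_time_stats(records: PhotonRecordSet, weights: np.ndarray):
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all survival weights vanished; absorption too high")
    p = weights / wsum
    t = records.times
    m1 = float(p @ t)
    d = t - m1
    mu = [float(p @ d**k) for k in (2, 3, 4)]
    return wsum, m1, mu[0], mu[1], mu[2]


def moments_from_records(records: PhotonRecordSet, absorption=None) -> MomentVector:
    """Moments of the absorption-reweighted detected DTOF.

    ``M0 = -log(sum of survival weights)``; the (arbitrary) launch
    normalization only shifts M0 by a constant, which cancels in any change
    analysis.
    """
    if records.n_detected == 0:
        raise ValueError("empty record set")
    if absorption is None:
        absorption = records.model.absorption
    w = records.absorption_weights(absorption)
    wsum, m1, mu2, _, _ = _weighted_time_stats(records, w)
    return MomentVector(M0=-np.log(wsum), M1=m1, M2=mu2)


def records_central_moments(records: PhotonRecordSet, absorption=None):
    """(sum_weights, M1, mu2, mu3, mu4) of the reweighted DTOF.

    The third and fourth central moments feed the shot-noise covariance
    model; the weight sum gives the relative detected intensity.
    """
    if absorption is None:
        absorption = records.model.absorption
    w = records.absorption_weights(absorption)
    return _weighted_time_stats(records, w)


def sensitivities_from_records(records: PhotonRecordSet, absorption=None) -> np.ndarray:
    """Per-layer moment sensitivities S[n, j] = d M_n / d mu_a[j].

    Shape (3, n_layers); units mm, s*mm, s^2*mm.  Layers no detected photon
    visited get exact zeros.
    """
    if records.n_detected == 0:
        raise ValueError("empty record set")
    if absorption is None:
        absorption = records.model.absorption
    w = records.absorption_weights(absorption)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all survival weights vanished; absorption too high")
    p = w / wsum
    L = records.partial_pathlengths.astype(float)  # (Nd, nl)
    t = records.times
    s0 = p @ L  # <l_j>_w
    m1 = float(p @ t)
    dt = t - m1
    s1 = -((p * dt) @ L)  # -Cov(t, l_j) since E[dt]=0
    q = dt**2
    m2 = float(p @ q)
    s2 = -((p * (q - m2)) @ L)
    return np.vstack([s0, s1, s2])


def baseline_absorption(
    wavelength_nm: float,
    water_fraction: float = 0.8,
    c_hbo_um: float = 30.0,
    c_hbr_um: float = 20.0,
) -> float:
    """Baseline tissue absorption (mm^-1) from water + hemoglobin content.

    Defaults describe tissue that is 80% water with 30 uM HbO and 20 uM HbR
    (60% oxygen saturation).
    """
    if c_hbo_um < 0 or c_hbr_um < 0 or water_fraction < 0:
        raise ValueError("composition fractions must be non-negative")
    eps_hbo, eps_hbr = chromophores.extinction_coefficients(wavelength_nm)
    mua_cm = water_fraction * chromophores.water_absorption(wavelength_nm)
    mua_cm += chromophores.LN10 * (
        float(eps_hbo) * c_hbo_um * 1e-6 + float(eps_hbr) * c_hbr_um * 1e-6
    )
    return mua_cm * 0.1  # cm^-1 -> mm^-1


@dataclass
class TableConfig:
    """Grids and budget for a sensitivity lookup table.

    The default grids are the full benchmark grids (separations 6–34 mm in
    2 mm steps; uniform baseline absorptions 0.009–0.030 mm^-1 in
    0.001 mm^-1 steps); the default photon budget is the desk-scale one —
    a single shared simulation whose annular detector serves every
    separation.
    """

    separations: np.ndarray = field(
        default_factory=lambda: np.arange(6.0, 34.0 + 1e-9, 2.0)
    )
    absorptions: np.ndarray = field(
        default_factory=lambda: np.arange(0.009, 0.030 + 1e-9, 0.001)
    )
    n_photons: int = 400_000
    seed: int = 12345
    ring_halfwidth: float = 1.0
    min_detected: int = 50

    def __post_init__(self):
        self.separations = np.asarray(self.separations, float)
        self.absorptions = np.asarray(self.absorptions, float)
        if np.any(np.diff(self.separations) <= 0) or np.any(np.diff(self.absorptions) <= 0):
            raise ValueError("grids must be strictly increasing")


@dataclass
class SensitivityTable:
    """Per-layer moment sensitivities on a (separation, absorption) grid.

    ``S`` has shape (n_rho, n_mua, 3, n_layers); ``central_moments`` holds
    (M1, mu2, mu3, mu4) of the detected DTOF per cell, used by the
    shot-noise covariance model; ``valid`` flags cells with enough detected
    photons for interpolation.
    """

    separations: np.ndarray
    absorptions: np.ndarray
    S: np.ndarray
    central_moments: np.ndarray  # (n_rho, n_mua, 4)
    sum_weights: np.ndarray  # (n_rho, n_mua) relative detected intensity
    n_detected: np.ndarray  # (n_rho,) photons in each ring
    valid: np.ndarray  # (n_rho, n_mua) bool
    model: TissueModel
    provenance: dict

    @property
    def n_layers(self) -> int:
        return self.S.shape[3]

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("separations", data=self.separations)
            f.create_dataset("absorptions", data=self.absorptions)
            f.create_dataset("S", data=self.S)
            f.create_dataset("central_moments", data=self.central_moments)
            f.create_dataset("sum_weights", data=self.sum_weights)
            f.create_dataset("n_detected", data=self.n_detected)
            f.create_dataset("valid", data=self.valid.astype(np.uint8))
            f.attrs["model"] = self.model.to_json()
            f.attrs["provenance"] = json.dumps(self.provenance)

    @classmethod
    def load(cls, path) -> "SensitivityTable":
        with h5py.File(path, "r") as f:
            return cls(
                separations=f["separations"][()],
                absorptions=f["absorptions"][()],
                S=f["S"][()],
                central_moments=f["central_moments"][()],
                sum_weights=f["sum_weights"][()],
                n_detected=f["n_detected"][()],
                valid=f["valid"][()].astype(bool),
                model=TissueModel.from_json(f.attrs["model"]),
                provenance=json.loads(f.attrs["provenance"]),
            )

    # -- interpolation ---------------------------------------------------
    def _bilinear(self, separation: float, absorption: float, values: np.ndarray):
        """Bilinear interpolation of ``values[(rho, mua), ...]`` at a query."""
        rho_g, mua_g = self.separations, self.absorptions
        if not (rho_g[0] <= separation <= rho_g[-1]):
            raise ValueError(
                f"separation {separation} mm outside table hull "
                f"[{rho_g[0]}, {rho_g[-1]}] mm; refusing to extrapolate"
            )
        if not (mua_g[0] <= absorption <= mua_g[-1]):
            raise ValueError(
                f"absorption {absorption} mm^-1 outside table hull "
                f"[{mua_g[0]}, {mua_g[-1]}] mm^-1; refusing to extrapolate"
            )
        i = min(int(np.searchsorted(rho_g, separation, "right")) - 1, len(rho_g) - 2)
        j = min(int(np.searchsorted(mua_g, absorption, "right")) - 1, len(mua_g) - 2)
        i = max(i, 0)
        j = max(j, 0)
        fx = (separation - rho_g[i]) / (rho_g[i + 1] - rho_g[i])
        fy = (absorption - mua_g[j]) / (mua_g[j + 1] - mua_g[j])
        corners = [(i, j), (i + 1, j), (i, j + 1), (i + 1, j + 1)]
        if not all(self.valid[a, b] for a, b in corners):
            raise ValueError(
                f"table cell near (rho={separation}, mua={absorption}) has "
                "under-sampled corners; rebuild with more photons"
            )
        w = [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
        out = np.zeros(values.shape[2:])
        for wk, (a, b) in zip(w, corners):
            out = out + wk * values[a, b]
        return out

    def interp_layer_sensitivities(self, separation: float, absorption: float) -> np.ndarray:
        """Interpolated per-layer sensitivities, shape (3, n_layers)."""
        return self._bilinear(separation, absorption, self.S)

    def interp_central_moments(self, separation: float, absorption: float) -> np.ndarray:
        """Interpolated DTOF central moments (M1, mu2, mu3, mu4)."""
        return self._bilinear(separation, absorption, self.central_moments)


@dataclass(frozen=True)
class TwoLayerSensitivity:
    """Moment sensitivities collapsed to a scalp/brain two-layer model.

    ``scalp``/``brain`` are (S0, S1, S2) arrays; their sum equals the sum
    over all layers of the underlying table.
    """

    scalp: np.ndarray
    brain: np.ndarray
    scalp_thickness: float  # mm
    separation: float  # mm
    wavelength: float | None = None  # nm

    @property
    def total(self) -> np.ndarray:
        return self.scalp + self.brain

    def design_matrix(self) -> np.ndarray:
        """3x2 block [S_n_scalp, S_n_brain] for the two-layer inversion."""
        return np.column_stack([self.scalp, self.brain])


def build_lookup_table(model: TissueModel, config: TableConfig | None = None) -> SensitivityTable:
    """Build the (separation x absorption) sensitivity lookup table.

    One Monte Carlo run with an annular detector spanning all requested
    separations; every absorption grid value is evaluated by reweighting the
    same photon records with a uniform absorption vector.  Cells whose ring
    captured fewer than ``config.min_detected`` photons are flagged invalid
    and excluded from interpolation.
    """
    if config is None:
        config = TableConfig()
    rho = config.separations
    mua_grid = config.absorptions
    rec = _run_kernel(
        model,
        max(rho[0] - config.ring_halfwidth, 0.0),
        rho[-1] + config.ring_halfwidth,
        config.n_photons,
        config.seed,
    )
    nr, na, nl = len(rho), len(mua_grid), model.n_layers
    S = np.zeros((nr, na, 3, nl))
    cm = np.zeros((nr, na, 4))
    sw = np.zeros((nr, na))
    nd = np.zeros(nr, int)
    valid = np.zeros((nr, na), bool)
    for i, r in enumerate(rho):
        sub = rec.select_ring(r, config.ring_halfwidth)
        nd[i] = sub.n_detected
        if sub.n_detected < config.min_detected:
            continue
        for j, mu in enumerate(mua_grid):
            mua_vec = np.full(nl, mu)
            wsum, m1, mu2, mu3, mu4 = records_central_moments(sub, mua_vec)
            S[i, j] = sensitivities_from_records(sub, mua_vec)
            cm[i, j] = (m1, mu2, mu3, mu4)
            sw[i, j] = wsum
            valid[i, j] = True
    provenance = {
        "seed": config.seed,
        "n_photons": config.n_photons,
        "ring_halfwidth": config.ring_halfwidth,
        "min_detected": config.min_detected,
        "separations": list(map(float, rho)),
        "absorptions": list(map(float, mua_grid)),
    }
    return SensitivityTable(
        separations=rho,
        absorptions=mua_grid,
        S=S,
        central_moments=cm,
        sum_weights=sw,
        n_detected=nd,
        valid=valid,
        model=model,
        provenance=provenance,
    )


def interp_two_layer(
    table: SensitivityTable,
    separation: float,
    absorption: float,
    scalp_thickness: float = 13.0,
    wavelength: float | None = None,
) -> TwoLayerSensitivity:
    """Collapse the per-layer table to scalp/brain sensitivities at a query.

    The scalp block sums layers 1..t_scalp (t_scalp in integer mm), the
    brain block sums the remaining layers.  Queries outside the table hull
    raise instead of clamping.
    """
    t = scalp_thickness / table.model.layer_thickness
    if abs(t - round(t)) > 1e-9:
        raise ValueError("scalp_thickness must be an integer number of layers")
    t = int(round(t))
    if not 1 <= t <= table.n_layers - 1:
        raise ValueError(f"scalp_thickness must be in [1, {table.n_layers - 1}] layers")
    S = table.interp_layer_sensitivities(separation, absorption)
    return TwoLayerSensitivity(
        scalp=S[:, :t].sum(axis=1),
        brain=S[:, t:].sum(axis=1),
        scalp_thickness=float(scalp_thickness),
        separation=float(separation),
        wavelength=wavelength,
    )
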