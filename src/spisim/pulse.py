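"""Temporal pulse profiles and fluence on the sample.

The nominal irradiation conditions are a 4.96 keV, 5×10¹¹-photon pulse of
9 fs FWHM duration focused to 250 nm × 160 nm FWHM.  Real SASE pulses are
spiky; since measured profiles are not available, a partial-coherence
emulation is provided: the smooth Gaussian envelope is multiplied by the
squared magnitude of a correlated complex random field whose coherence
time sets the spike width.  The molecule (≤ hundreds of Å) is far smaller
than the focus, so the fluence is uniform over the sample and only the
on-axis value matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: nominal irradiation conditions
NOMINAL_PHOTON_ENERGY_KEV = 4.96
NOMINAL_PHOTONS_PER_PULSE = 5e11
NOMINAL_FWHM_FS = 9.0
NOMINAL_FOCUS_FWHM_NM = (250.0, 160.0)

_FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class PulseProfile:
    """Photon flux vs time on a uniform grid.

    ``flux`` is in photons/fs; ``sum(flux)·Δt`` equals ``total_photons``.
    """

    t: np.ndarray                       # fs, uniform grid
    flux: np.ndarray                    # photons / fs
    photon_energy_keV: float
    total_photons: float
    focus_fwhm_nm: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "flux", np.asarray(self.flux, dtype=float))
        if self.flux.min() < 0:
            raise ValueError("negative flux")
        integral = self.flux.sum() * self.dt
        if not math.isclose(integral, self.total_photons, rel_tol=1e-9):
            raise ValueError("flux does not integrate to total_photons")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def effective_focus_area_A2(self) -> float:
        """On-axis effective area 2π σx σy of the 2-D Gaussian focus (Å²)."""
        sx = self.focus_fwhm_nm[0] * 10.0 * _FWHM_TO_SIGMA
        sy = self.focus_fwhm_nm[1] * 10.0 * _FWHM_TO_SIGMA
        return 2.0 * math.pi * sx * sy

    def flux_at(self, t) -> np.ndarray:
        """Linear interpolation of the flux (photons/fs), zero outside."""
        return np.interp(t, self.t, self.flux, left=0.0, right=0.0)


def _grid(envelope_fwhm_fs: float, nt: int) -> np.ndarray:
    half = 3.0 * envelope_fwhm_fs
    return np.linspace(-half, half, nt)


def gaussian_profile(
    fwhm_fs: float = NOMINAL_FWHM_FS,
    total_photons: float = NOMINAL_PHOTONS_PER_PULSE,
    nt: int = 512,
    photon_energy_keV: float = NOMINAL_PHOTON_ENERGY_KEV,
    focus_fwhm_nm: tuple[float, float] = NOMINAL_FOCUS_FWHM_NM,
) -> PulseProfile:
    """Smooth Gaussian envelope peaked at t = 0."""
    if fwhm_fs <= 0:
        raise ValueError("fwhm must be positive")
    if nt < 16:
        raise ValueError("nt must be at least 16")
    t = _grid(fwhm_fs, nt)
    sigma = fwhm_fs * _FWHM_TO_SIGMA
    flux = np.exp(-0.5 * (t / sigma) ** 2)
    flux *= total_photons / (flux.sum() * (t[1] - t[0]))
    return PulseProfile(t, flux, photon_energy_keV, total_photons, focus_fwhm_nm)


def sase_profile(
    seed: int,
    envelope_fwhm_fs: float = NOMINAL_FWHM_FS,
    spike_fwhm_fs: float = 0.25,
    total_photons: float = NOMINAL_PHOTONS_PER_PULSE,
    nt: int = 512,
    photon_energy_keV: float = NOMINAL_PHOTON_ENERGY_KEV,
    focus_fwhm_nm: tuple[float, float] = NOMINAL_FOCUS_FWHM_NM,
) -> PulseProfile:
    """SASE-like spiky profile (partial-coherence emulation), seeded.

    A complex white-noise field is low-pass filtered to the coherence
    (spike) time; its squared magnitude multiplies the Gaussian envelope
    and the result is renormalized to the total photon count.  The
    ensemble average over seeds approaches the smooth envelope.
    """
    if not spike_fwhm_fs < envelope_fwhm_fs:
        raise ValueError("spike width must be below the envelope width")
    rng = np.random.default_rng(seed)
    t = _grid(envelope_fwhm_fs, nt)
    dt = t[1] - t[0]
    field = rng.standard_normal(nt) + 1j * rng.standard_normal(nt)
    # intensity autocorrelation width ≈ spike FWHM
    sig_filt = spike_fwhm_fs * _FWHM_TO_SIGMA / math.sqrt(2.0) / dt
    field = gaussian_filter1d(field.real, sig_filt) + 1j * gaussian_filter1d(field.imag, sig_filt)
    envelope = np.exp(-0.5 * (t / (envelope_fwhm_fs * _FWHM_TO_SIGMA)) ** 2)
    flux = envelope * np.abs(field) ** 2
    flux *= total_photons / (flux.sum() * dt)
    return PulseProfile(t, flux, photon_energy_keV, total_photons, focus_fwhm_nm)


def peak_fluence_rate(profile: PulseProfile, t) -> np.ndarray:
    """On-axis fluence rate (photons/Å²/fs) at time(s) t."""
    return profile.flux_at(t) / profile.effective_focus_area_A2


def time_zero(profiles: list[PulseProfile]) -> float:
    """Time of the maximum of the average temporal envelope.

    All profiles must share one time grid; ties break toward earlier time.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    t = profiles[0].t
    for p in profiles[1:]:
        if len(p.t) != len(t) or not np.allclose(p.t, t):
            raise ValueError("profiles are not on a common time grid")
    mean_flux = np.mean([p.flux for p in profiles], axis=0)
    return float(t[int(np.argmax(mean_flux))])


def interval_edges(profile: PulseProfile, n_intervals: int = 10,
                   spacing: str = "photon") -> np.ndarray:
    """Edges of n contiguous intervals covering the pulse support.

    ``spacing="photon"`` places edges at equal photon-content quantiles of
    the cumulative flux (the default used for snapshot placement);
    ``spacing="time"`` uses equal-duration intervals.
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    if spacing == "time":
        return np.linspace(profile.t[0], profile.t[-1], n_intervals + 1)
    if spacing != "photon":
        raise ValueError(f"unknown spacing {spacing!r}")
    cum = np.cumsum(profile.flux) * profile.dt
    if cum[-1] == 0.0:   # empty pulse: photon quantiles degenerate
        return np.linspace(profile.t[0], profile.t[-1], n_intervals + 1)
    cum = np.concatenate([[0.0], cum])
    tq = np.concatenate([[profile.t[0] - 0.5 * profile.dt],
                         profile.t + 0.5 * profile.dt])
    targets = np.linspace(0.0, cum[-1], n_intervals + 1)
    edges = np.interp(targets, cum, tq)
    edges[0], edges[-1] = tq[0], tq[-1]
    return edges


def interval_weights(profile: PulseProfile, n_intervals: int = 10,
                     spacing: str = "photon") -> np.ndarray:
    """Photon content of each interval; sums to ``total_photons`` exactly."""
    edges = interval_edges(profile, n_intervals, spacing)
    cum = np.cumsum(profile.flux) * profile.dt
    cum = np.concatenate([[0.0], cum])
    tq = np.concatenate([[profile.t[0] - 0.5 * profile.dt],
                         profile.t + 0.5 * profile.dt])
    cum_at = np.interp(edges, tq, cum)
    w = np.diff(cum_at)
    if w.sum() == 0.0:
        return np.zeros(n_intervals)
    # pin the exact sum against interpolation round-off
    w *= profile.total_photons / w.sum()
    return w


def snapshot_times(profile: PulseProfile, n_snapshots: int = 10,
                   spacing: str = "photon") -> np.ndarray:
    """Representative time of each interval: its median-photon time."""
    edges = interval_edges(profile, n_snapshots, spacing)
    cum = np.cumsum(profile.flux) * profile.dt
    cum = np.concatenate([[0.0], cum])
    tq = np.concatenate([[profile.t[0] - 0.5 * profile.dt],
                         profile.t + 0.5 * profile.dt])
    if cum[-1] == 0.0:
        return 0.5 * (edges[:-1] + edges[1:])
    cum_at = np.interp(edges, tq, cum)
    mid = 0.5 * (cum_at[:-1] + cum_at[1:])
    return np.interp(mid, cum, tq)


def write_profile_txt(profile: PulseProfile, path) -> None:
    """Two-column (time fs, flux photons/fs) plain-text serialization."""
    header = (f"photon_energy_keV {profile.photon_energy_keV}\n"
              f"total_photons {profile.total_photons}\n"
              f"focus_fwhm_nm {profile.focus_fwhm_nm[0]} {profile.focus_fwhm_nm[1]}\n"
              "t_fs flux_per_fs")
    np.savetxt(path, np.column_stack([profile.t, profile.flux]), header=header)


def read_profile_txt(path) -> PulseProfile:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if parts and parts[0] in ("photon_energy_keV", "total_photons", "focus_fwhm_nm"):
                meta[parts[0]] = [float(x) for x in parts[1:]]
    data = np.loadtxt(path)
    return PulseProfile(data[:, 0], data[:, 1],
                        meta["photon_energy_keV"][0], meta["total_photons"][0],
                        tuple(meta["focus_fwhm_nm"]))
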