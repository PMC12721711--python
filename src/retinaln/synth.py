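"""Ground-truth-known synthetic data generators.

Every analysis stage in the package has a parameter-recovery test against
data produced here: LN responses with known filter and nonlinearity,
inhomogeneous-Poisson spike trains, glutamate release from a single-pool
depressing ribbon synapse, postsynaptic currents and glutamate-sensor
fluorescence derived from that release, and ribbon morphometry tables with a
known volume-to-vesicle-count slope.

The depressing synapse is deliberately minimal: one readily-releasable pool
of size ``P0`` whose occupancy ``p`` obeys

    dp/dt = (P0 - p) / tau_r  -  k * max(drive - theta, 0) * p

with release rate ``R(t) = k * max(drive - theta, 0) * p(t)``.  Pool size,
release-rate constant, release threshold and replenishment time constant are
the four knobs that reproduce transience, paired-flash depression and
size-dependent sustainedness; reserve-pool cascades are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.special import ndtr

from .errors import DegenerateInputError, IntegrationError, ParameterError
from .kinetics import filter_kinetics
from .ln import LinearFilter, generator_signal
from .stimulus import StimulusTrace

__all__ = [
    "Identity",
    "Rectifier",
    "CumulativeGaussian",
    "GroundTruthLN",
    "SpikeTrain",
    "DepressingSynapse",
    "RibbonRecord",
    "RibbonDataset",
    "difference_of_gammas",
    "make_ground_truth_filter",
    "simulate_ln_response",
    "simulate_spikes",
    "simulate_depressing_release",
    "simulate_epsc",
    "simulate_fluorescence",
    "make_ribbon_dataset",
    "calibrate_count_noise_sd",
]

#: default Euler step for synapse integration (s)
DEFAULT_SYNAPSE_DT = 1e-4

#: glutamate-sensor imaging frame rate (Hz) emulated by default
DEFAULT_FRAME_RATE_HZ = 58.25


# ---------------------------------------------------------------------------
# parametric static nonlinearities (monotone nondecreasing by construction)
# ---------------------------------------------------------------------------

class Identity:
    """Pass-through output function."""

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return np.asarray(g, dtype=float)


@dataclass
class Rectifier:
    """Piecewise-linear rectifier: ``baseline + gain * max(g - threshold, 0)``."""

    threshold: float = 0.0
    gain: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ParameterError("rectifier gain must be >= 0 (monotone output)")

    def __call__(self, g: np.ndarray) -> np.ndarray:
        return self.baseline + self.gain * np.maximum(np.asarray(g, float) - self.threshold, 0.0)


@dataclass
class CumulativeGaussian:
    """Sigmoid output function: ``baseline + amplitude * Phi((g - midpoint)/slope_sd)``."""

    midpoint: float = 0.0
    slope_sd: float = 1.0
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_sd <= 0 or self.amplitude < 0:
            raise ParameterError("slope_sd must be > 0 and amplitude >= 0")

    def __call__(self, g: np.ndarray) -> np.ndarray:
        z = (np.asarray(g, float) - self.midpoint) / self.slope_sd
        return self.baseline + self.amplitude * ndtr(z)


@dataclass
class GroundTruthLN:
    """Generative LN cell: known filter plus a named monotone nonlinearity."""

    filter: LinearFilter
    nonlinearity: object = field(default_factory=Identity)
    output_units: str = "a.u."


# ---------------------------------------------------------------------------
# parametric biphasic kernels
# ---------------------------------------------------------------------------

def _unit_peak_gamma(t: np.ndarray, tau: float, order: int) -> np.ndarray:
    """``(t/tau)^n exp(n (1 - t/tau))``: peak value 1 at ``t = tau``."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = x**order * np.exp(order * (1.0 - x))
    return out


def difference_of_gammas(
    t: np.ndarray,
    peak_amp: float,
    trough_amp: float,
    tau_rise_s: float,
    tau_damp_s: float,
    order: int = 6,
    trough_delay_s: float = 0.0,
) -> np.ndarray:
    """Continuous difference-of-gammas kernel, evaluable on any grid.

    ``peak_amp * G(t; tau_rise) - trough_amp * G(t - delay; tau_damp)`` with
    unit-peak gamma lobes, so the two amplitudes directly set the lobe scales
    (up to lobe overlap).  This is the analytic reference the sampled kernels
    and the fine-grid kinetics oracles share.
    """
    t = np.asarray(t, dtype=float)
    out = peak_amp * _unit_peak_gamma(t, tau_rise_s, order)
    if trough_amp != 0:
        out = out - trough_amp * _unit_peak_gamma(t - trough_delay_s, tau_damp_s, order)
    return out


def make_ground_truth_filter(
    peak_amp: float,
    trough_amp: float,
    tau_rise_s: float,
    tau_damp_s: float,
    dt_s: float = 1e-3,
    T_filt_s: float = 0.5,
    order: int = 6,
    trough_delay_s: float = 0.0,
) -> LinearFilter:
    """Biphasic ON-type kernel with analytically controllable lobes.

    The first lobe is positive (ON convention).  Ground-truth kinetics of the
    *continuous* kernel (lobe amplitudes, biphasic index, zero-cross time),
    evaluated on a 10-us grid, are stored in the metadata so estimators can be
    scored against them.
    """
    if peak_amp < 0 or trough_amp < 0:
        raise ParameterError("lobe amplitudes must be >= 0")
    if tau_rise_s <= 0 or tau_damp_s <= 0:
        raise ParameterError("time constants must be positive")
    if trough_amp > 0 and tau_damp_s + trough_delay_s < tau_rise_s:
        raise ParameterError("secondary lobe must follow the initial lobe")
    n = int(round(T_filt_s / dt_s))
    if n < 2:
        raise ParameterError("T_filt shorter than two samples")

    params = dict(
        peak_amp=peak_amp, trough_amp=trough_amp, tau_rise_s=tau_rise_s,
        tau_damp_s=tau_damp_s, order=order, trough_delay_s=trough_delay_s,
    )
    # ground truth on a fine grid of the continuous kernel
    fine_dt = 1e-5
    t_fine = np.arange(int(round(T_filt_s / fine_dt))) * fine_dt
    fine = difference_of_gammas(t_fine, **params)
    truth = filter_kinetics(LinearFilter(fine, fine_dt))
    if trough_amp > 0 and truth.zero_cross_time_s is None:
        raise ParameterError(
            "T_filt_s too short: the kernel never crosses zero inside the window"
        )
    taps = difference_of_gammas(np.arange(n) * dt_s, **params)
    return LinearFilter(
        taps, dt_s,
        {
            "kind": "difference_of_gammas",
            "params": params,
            "true_biphasic_index": truth.biphasic_index if trough_amp > 0 else 0.0,
            "true_zero_cross_s": truth.zero_cross_time_s,
            "true_lobe_B_amp": truth.lobe_B_amp,
            "true_lobe_A_amp": truth.lobe_A_amp if trough_amp > 0 else 0.0,
        },
    )


# ---------------------------------------------------------------------------
# LN responses and spike trains
# ---------------------------------------------------------------------------

def simulate_ln_response(
    model: GroundTruthLN,
    stim: StimulusTrace,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Forward LN response: nonlinearity(filter * contrast) + Gaussian noise.

    The first ``len(filter) - 1`` samples carry incomplete stimulus history
    (burn-in) and should be excluded from fits.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    g = generator_signal(model.filter, stim)
    resp = np.asarray(model.nonlinearity(g), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.size)
    return resp


@dataclass
class SpikeTrain:
    """Sorted spike times (s) on [0, duration)."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and (
            np.any(np.diff(self.spike_times) <= 0)
            or self.spike_times[0] < 0
            or self.spike_times[-1] >= self.duration
        ):
            raise ParameterError("spike times must be strictly increasing in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


def simulate_spikes(
    drive: np.ndarray,
    dt_s: float,
    rate_map=None,
    refractory_s: float = 0.0,
    seed: int | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spiking by thinning, with absolute refractory.

    ``rate_map`` maps the drive to an instantaneous rate in Hz (monotone,
    >= 0); default is rectification, ``max(drive, 0)``.  With zero refractory
    the expected count is the integral of the rate.
    """
    if refractory_s < 0:
        raise ParameterError("refractory must be >= 0")
    drive = np.asarray(drive, dtype=float)
    rates = np.maximum(drive, 0.0) if rate_map is None else np.asarray(rate_map(drive), float)
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ParameterError("rate_map must produce finite rates >= 0")
    duration = drive.size * dt_s
    lam_max = float(rates.max())
    if lam_max == 0:
        return SpikeTrain(np.empty(0), duration)
    rng = np.random.default_rng(seed)
    spikes: list[float] = []
    t = rng.exponential(1.0 / lam_max)
    last = -np.inf
    while t < duration:
        i = min(int(t / dt_s), rates.size - 1)
        if t - last >= refractory_s and rng.uniform() < rates[i] / lam_max:
            spikes.append(t)
            last = t
        t += rng.exponential(1.0 / lam_max)
    return SpikeTrain(np.asarray(spikes), duration)


# ---------------------------------------------------------------------------
# depressing ribbon synapse
# ---------------------------------------------------------------------------

@dataclass
class DepressingSynapse:
    """Single readily-releasable pool with threshold-rectified drive.

    pool_size
        P0, vesicles; the stand-in for the ribbon-associated vesicle count.
    release_rate_k
        1/s per unit suprathreshold drive.
    threshold
        drive units below which no release occurs ("release threshold").
    tau_replenish_s
        exponential refill time constant of the pool, s.
    """

    pool_size: float
    release_rate_k: float
    threshold: float = 0.0
    tau_replenish_s: float = 0.5

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ParameterError("pool_size must be > 0")
        if self.release_rate_k < 0:
            raise ParameterError("release_rate_k must be >= 0")
        if self.tau_replenish_s <= 0:
            raise ParameterError("tau_replenish_s must be > 0")

    def steady_state_release(self, drive: float) -> float:
        """Closed-form sustained release rate for constant suprathreshold
        drive: ``k d P0 / (1 + k d tau_r)`` with ``d = drive - threshold``."""
        d = max(drive - self.threshold, 0.0)
        kd = self.release_rate_k * d
        return kd * self.pool_size / (1.0 + kd * self.tau_replenish_s)


def simulate_depressing_release(
    drive: np.ndarray,
    dt_s: float,
    syn: DepressingSynapse,
    p_init: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler integration of the single-pool model.

    Returns ``(release_rate, occupancy)``, both sampled on the drive grid;
    ``release_rate[i]`` uses the occupancy at the start of step ``i``.  The
    explicit-Euler step is guarded: if the per-step loss fraction
    ``dt * (1/tau_r + k * max(drive - theta, 0))`` reaches 1 anywhere the
    integration would be unstable and an error asks for a smaller dt, rather
    than silently clamping.  Occupancy then stays in [0, P0] exactly.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ParameterError("drive must be finite")
    a = syn.release_rate_k * np.maximum(drive - syn.threshold, 0.0)
    loss = dt_s * (1.0 / syn.tau_replenish_s + a)
    if loss.max() >= 1.0:
        raise IntegrationError(
            f"unstable Euler step (max per-step loss {loss.max():.3g}); "
            f"use dt < {dt_s / loss.max():.3g} s"
        )
    p0 = syn.pool_size if p_init is None else float(p_init)
    if not 0 <= p0 <= syn.pool_size:
        raise ParameterError("p_init must be in [0, pool_size]")
    release = np.empty(drive.size)
    occupancy = np.empty(drive.size)
    refill = dt_s * syn.pool_size / syn.tau_replenish_s
    decay = 1.0 - loss  # per-step survival factor, > 0 by the guard
    p = p0
    a_list = a.tolist()  # plain floats: the sequential loop dominates runtime
    d_list = decay.tolist()
    for i in range(drive.size):
        occupancy[i] = p
        release[i] = a_list[i] * p
        p = p * d_list[i] + refill
    return release, occupancy


def simulate_epsc(
    release_rate: np.ndarray,
    dt_s: float,
    quantal_amp_pA: float = 5.0,
    quantal_kernel_tau_s: float = 0.002,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Postsynaptic current from a release-rate trace (pA, inward negative).

    The release rate is convolved with a unit-area exponential quantal
    kernel and scaled by the quantal amplitude, so sustained release at R
    vesicles/s produces a sustained current of ``-R * quantal_amp_pA`` pA.
    Baseline is 0 (holding current subtracted).
    """
    if quantal_amp_pA <= 0:
        raise ParameterError("quantal_amp_pA must be > 0")
    if quantal_kernel_tau_s <= 0:
        raise ParameterError("quantal_kernel_tau_s must be > 0")
    r = np.asarray(release_rate, dtype=float)
    n_k = max(int(round(8 * quantal_kernel_tau_s / dt_s)), 2)
    kern = np.exp(-np.arange(n_k) * dt_s / quantal_kernel_tau_s)
    kern /= kern.sum() * dt_s  # unit area
    current = -quantal_amp_pA * _signal.fftconvolve(r, kern, mode="full")[: r.size] * dt_s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    return current


def simulate_fluorescence(
    release_rate: np.ndarray,
    dt_s: float,
    sensor_tau_s: float = 0.06,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Glutamate-sensor fluorescence sampled at the imaging frame rate.

    Release is convolved with an exponential sensor kernel of area
    ``sensor_tau_s`` (so sustained release at R maps to a mean fluorescence
    of ``R * sensor_tau_s``), averaged within each frame, and frame noise is
    added.  Default frame rate 58.25 Hz.
    """
    if frame_rate_hz <= 0 or sensor_tau_s <= 0:
        raise ParameterError("frame_rate_hz and sensor_tau_s must be > 0")
    r = np.asarray(release_rate, dtype=float)
    n_k = max(int(round(8 * sensor_tau_s / dt_s)), 2)
    kern = np.exp(-np.arange(n_k) * dt_s / sensor_tau_s)
    conv = _signal.fftconvolve(r, kern, mode="full")[: r.size] * dt_s
    frame_dt = 1.0 / frame_rate_hz
    n_frames = int(r.size * dt_s / frame_dt)
    if n_frames < 1:
        raise ParameterError("release trace shorter than one imaging frame")
    edges = (np.arange(n_frames + 1) * frame_dt / dt_s).astype(int)
    frames = np.array([conv[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.size)
    return frames


# ---------------------------------------------------------------------------
# ribbon morphometry tables
# ---------------------------------------------------------------------------

BIPOLAR_TYPES = ("5i", "5o", "5t", "XBC", "6", "7")

#: per-type mean ribbon volume (um^3).  Type 6 ribbons are set 2.5x larger
#: than type 5i, the middle of the ~2-3x range seen across ON bipolar types.
DEFAULT_TYPE_VOLUME_MEANS = {
    "5i": 0.010,
    "5o": 0.010,
    "5t": 0.008,
    "XBC": 0.012,
    "6": 0.025,
    "7": 0.009,
}

#: vesicles per um^3 of ribbon volume (generator ground truth); chosen so the
#: default-direction regression (volume on count) lands at the calibrated
#: beta/r-squared regime (see docs/methods.md).
DEFAULT_SLOPE_VESICLES_PER_UM3 = 0.66 / 6.98e-06


@dataclass
class RibbonRecord:
    """One synaptic ribbon: volume, associated-vesicle count, provenance."""

    ribbon_volume: float  # um^3, > 0
    vesicle_count: int  # >= 0
    bipolar_type: str
    target: str = "unassigned"  # postsynaptic partner: ON-T | ON-S | unassigned

    def __post_init__(self) -> None:
        if self.ribbon_volume <= 0:
            raise ParameterError("ribbon volume must be > 0")
        if self.vesicle_count < 0:
            raise ParameterError("vesicle count must be >= 0")


@dataclass
class RibbonDataset:
    """Ribbon records plus the generator ground truth used to build them."""

    records: list[RibbonRecord]
    true_slope: float
    count_noise_sd: float

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def calibrate_count_noise_sd(
    volumes: np.ndarray, slope: float, target_r2: float
) -> float:
    """Variance-matching oracle for the count-noise level.

    For counts ``C = slope * V + e`` the regression explains
    ``r2 = Var(slope V) / (Var(slope V) + sigma^2)``; invert for sigma.
    """
    if not 0 < target_r2 < 1:
        raise ParameterError("target_r2 must be in (0, 1)")
    signal_var = float(np.var(slope * np.asarray(volumes, float)))
    return float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))


def make_ribbon_dataset(
    n_per_type: int = 25,
    type_volume_means: dict[str, float] | None = None,
    volume_cv: float = 0.4,
    slope_vesicles_per_volume: float = DEFAULT_SLOPE_VESICLES_PER_UM3,
    count_noise_sd: float | None = None,
    target_r2: float = 0.66,
    seed: int | None = None,
) -> RibbonDataset:
    """Synthetic ribbon morphometry table.

    Volumes are lognormal per bipolar type (coefficient of variation
    ``volume_cv``); vesicle counts are ``round(slope * volume + noise)``
    floored at zero.  When ``count_noise_sd`` is None it is set by the
    variance-matching oracle so the pooled volume-count regression lands at
    ``target_r2``.  Types 5i/5o/5t/XBC ribbons contact ON-transient cells,
    type 7 contacts ON-sustained cells, and type 6 splits 30/70 between the
    two targets, mirroring the connectivity fractions of the circuits being
    emulated.
    """
    if slope_vesicles_per_volume <= 0:
        raise ParameterError("slope must be > 0")
    if volume_cv <= 0:
        raise ParameterError("volume_cv must be > 0")
    means = dict(DEFAULT_TYPE_VOLUME_MEANS if type_volume_means is None else type_volume_means)
    if any(v <= 0 for v in means.values()):
        raise ParameterError("type volume means must be > 0")
    rng = np.random.default_rng(seed)

    sigma2 = np.log1p(volume_cv**2)
    sigma = np.sqrt(sigma2)
    types: list[str] = []
    volumes: list[float] = []
    for btype, mean_v in means.items():
        mu = np.log(mean_v) - sigma2 / 2.0
        volumes.extend(rng.lognormal(mu, sigma, size=n_per_type))
        types.extend([btype] * n_per_type)
    volumes_arr = np.asarray(volumes)

    if count_noise_sd is None:
        count_noise_sd = calibrate_count_noise_sd(
            volumes_arr, slope_vesicles_per_volume, target_r2
        )
    counts = np.maximum(
        np.round(
            slope_vesicles_per_volume * volumes_arr
            + rng.normal(0.0, count_noise_sd, size=volumes_arr.size)
        ),
        0,
    ).astype(int)

    records = []
    for btype, vol, cnt in zip(types, volumes_arr, counts):
        if btype in ("5i", "5o", "5t", "XBC"):
            target = "ON-T"
        elif btype == "7":
            target = "ON-S"
        else:  # type 6 contacts both RGC types
            target = "ON-T" if rng.uniform() < 0.3 else "ON-S"
        records.append(RibbonRecord(float(vol), int(cnt), btype, target))
    return RibbonDataset(records, slope_vesicles_per_volume, float(count_noise_sd))
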