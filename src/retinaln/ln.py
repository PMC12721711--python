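"""Linear-nonlinear (LN) model estimation by reverse correlation.

The encoding model is a cascade of a causal linear temporal filter and a
static (memoryless) nonlinearity.  The filter is estimated either as a
spike-triggered average (STA) or, for continuous responses, by
cross-correlating the stimulus contrast with the response and dividing by the
stimulus power spectrum.  The nonlinearity is read off by comparing the
filter's output ("generator signal") with the measured response point by
point and binning along the prediction axis.

Conventions
-----------
* Filters live on a causal lag axis: ``taps[k]`` weights stimulus contrast
  ``k * dt`` seconds *before* the response sample.  Publication-style plots
  put the most recent stimulus on the right; :meth:`LinearFilter.plot_axis`
  returns the reversed (negated-lag) axis for display without affecting any
  computation.
* Tap units are response-units per unit contrast per second, so the generator
  signal is ``dt * sum_k taps[k] * contrast[n - k]`` — a discrete
  approximation of the continuous convolution that is invariant to the choice
  of dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import ConditioningError, DegenerateInputError, ParameterError
from .stimulus import StimulusTrace

__all__ = [
    "LinearFilter",
    "StaticNonlinearity",
    "LNModel",
    "compute_sta",
    "estimate_linear_filter",
    "generator_signal",
    "fit_nonlinearity",
    "predict_response",
    "model_performance",
    "fit_ln_model",
]


@dataclass
class LinearFilter:
    """Causal temporal kernel on a lag axis.

    ``taps[k]`` applies to stimulus contrast at lag ``k * dt`` before the
    response sample; units are response-units per unit contrast per second.
    """

    taps: np.ndarray
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if self.taps.ndim != 1 or self.taps.size < 2:
            raise ParameterError("filter needs >= 2 taps on a 1-D lag axis")
        if self.dt <= 0:
            raise ParameterError("filter dt must be positive")
        if not np.all(np.isfinite(self.taps)):
            raise ParameterError("filter taps must be finite")

    @property
    def lags(self) -> np.ndarray:
        """Causal lag axis in seconds (lag 0 = time of the response sample)."""
        return np.arange(self.taps.size) * self.dt

    @property
    def duration(self) -> float:
        return self.taps.size * self.dt

    def plot_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(time, taps) with the lag axis negated, matching the common
        reversed-time presentation of STAs.  Display only."""
        return -self.lags, self.taps


@dataclass
class StaticNonlinearity:
    """Binned input-output curve along the generator-signal axis."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if self.bin_centers.size < 2:
            raise ParameterError("nonlinearity needs >= 2 bins")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ParameterError("bin centers must be strictly increasing")

    def __call__(self, g: np.ndarray) -> np.ndarray:
        """Evaluate by linear interpolation between bin centers, constant
        beyond the end bins."""
        return np.interp(g, self.bin_centers, self.bin_means)


@dataclass
class LNModel:
    """Fitted LN cascade: linear filter, static nonlinearity, and the
    response baseline that was subtracted before fitting."""

    filter: LinearFilter
    nonlinearity: StaticNonlinearity
    response_baseline: float = 0.0


def _spike_times(spikes) -> np.ndarray:
    times = np.asarray(getattr(spikes, "spike_times", spikes), dtype=float)
    if times.ndim != 1:
        raise ParameterError("spike times must be 1-D")
    return times


def compute_sta(
    stim: StimulusTrace,
    spikes,
    window_s: float = 0.5,
    method: str = "fft",
) -> LinearFilter:
    """Spike-triggered average of the stimulus contrast.

    ``STA[k]`` is the mean over spikes of the (mean-subtracted) contrast at
    lag ``k * dt`` before each spike.  Spikes earlier than ``window_s`` after
    stimulus onset cannot contribute a full window and are excluded; their
    count is recorded in the result metadata.

    ``method`` selects the FFT-accelerated cross-correlation (default) or the
    direct spike-segment averaging loop; both compute the identical quantity
    and agree to floating-point precision.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    dt = stim.dt
    n_lags = int(round(window_s / dt))
    if n_lags < 2:
        raise ParameterError("window shorter than two samples")
    c = stim.contrast
    c = c - c.mean()
    times = _spike_times(spikes)
    idx = np.floor(times / dt + 1e-9).astype(int)
    usable = idx[(idx >= n_lags - 1) & (idx < c.size)]
    n_excluded = times.size - usable.size
    if usable.size == 0:
        raise DegenerateInputError("no spikes with a full stimulus window")

    if method == "direct":
        acc = np.zeros(n_lags)
        for i in usable:
            acc += c[i - n_lags + 1 : i + 1][::-1]
        sta = acc / usable.size
    elif method == "fft":
        counts = np.bincount(usable, minlength=c.size).astype(float)
        # sta[k] = (1/n) sum_i c[s_i - k]: cross-correlate counts with c
        full = _signal.fftconvolve(counts, c[::-1], mode="full")
        # full[m] = sum_i counts[i] c[N-1-(m-i)]; lag k ==> m = i + N-1 - (i-k)
        sta = full[c.size - 1 : c.size - 1 + n_lags] / usable.size
    else:
        raise ParameterError(f"unknown method {method!r}")
    return LinearFilter(
        sta, dt,
        {"n_spikes": int(usable.size), "n_excluded": int(n_excluded),
         "kind": "sta"},
    )


def _stimulus_band(stim: StimulusTrace, psd: np.ndarray, freqs: np.ndarray) -> float:
    bw = stim.metadata.get("bandwidth_hz")
    if bw is not None:
        return float(bw)
    # infer: highest frequency retaining appreciable power
    above = psd > 1e-6 * psd.max()
    return float(freqs[above].max()) if above.any() else 0.0


def estimate_linear_filter(
    stim: StimulusTrace,
    response: np.ndarray,
    filter_len_s: float = 0.5,
    bandwidth_hz: float | None = None,
    eps_frac: float = 1e-6,
    psd_smooth_hz: float = 0.0,
) -> LinearFilter:
    """Linear filter by regularized frequency-domain deconvolution.

    Computes ``F(w) = conj(S(w)) R(w) / (P(w) + eps)`` where ``S`` is the
    spectrum of the stimulus contrast, ``R`` that of the mean-subtracted
    response and ``P`` the stimulus power spectrum, zeroing frequencies above
    the stimulus bandwidth before inverting (the division is ill-posed where
    the stimulus carries no power).  ``eps = eps_frac * max P``.

    ``P`` is the raw periodogram by default (exact per-bin inversion; the
    ``eps`` floor bounds noise amplification at low-power bins).  A positive
    ``psd_smooth_hz`` instead divides by the periodogram averaged over that
    frequency window — slightly biased but with lower variance under heavy
    response noise.
    """
    response = np.asarray(response, dtype=float)
    if response.size != stim.n_samples:
        raise ParameterError("stimulus and response must have equal length")
    if stim.duration < 10 * filter_len_s:
        raise ParameterError("need >= 10 filter lengths of data")
    n_lags = int(round(filter_len_s / stim.dt))
    if n_lags < 2:
        raise ParameterError("filter_len shorter than two samples")

    c = stim.contrast
    c = c - c.mean()
    r = response - response.mean()
    S = np.fft.rfft(c)
    R = np.fft.rfft(r)
    psd = np.abs(S) ** 2
    freqs = np.fft.rfftfreq(c.size, d=stim.dt)
    bw = bandwidth_hz if bandwidth_hz is not None else _stimulus_band(stim, psd, freqs)
    in_band = freqs <= bw
    if not in_band.any() or psd[in_band].max() <= 1e-30 * c.size:
        raise ConditioningError("stimulus has no usable in-band power")
    if psd_smooth_hz > 0:
        df = freqs[1] - freqs[0]
        width = int(round(psd_smooth_hz / df))
        if width >= 3:
            kern = np.ones(width)
            mask = in_band.astype(float)
            # average over in-band neighbours only: no edge bias at the
            # brick-wall cutoff where out-of-band power is exactly zero
            num = np.convolve(psd * mask, kern, mode="same")
            cnt = np.convolve(mask, kern, mode="same")
            denom = np.where(cnt > 0, num / np.maximum(cnt, 1), psd)
        else:
            denom = psd
    else:
        denom = psd
    F = np.conj(S) * R / (denom + eps_frac * denom.max())
    F[~in_band] = 0.0
    taps = np.fft.irfft(F, n=c.size)[:n_lags] / stim.dt
    return LinearFilter(taps, stim.dt, {"kind": "deconvolution", "bandwidth_hz": bw})


def generator_signal(filt: LinearFilter, stim: StimulusTrace) -> np.ndarray:
    """Causal convolution of the filter with the stimulus contrast.

    Returns a trace of the same length as the stimulus; the first
    ``len(filter) - 1`` samples are burn-in (incomplete stimulus history).
    """
    if not np.isclose(filt.dt, stim.dt, rtol=1e-9, atol=0):
        raise ParameterError(
            f"dt mismatch: filter {filt.dt:g} s vs stimulus {stim.dt:g} s"
        )
    c = stim.contrast
    return _signal.fftconvolve(c, filt.taps, mode="full")[: c.size] * filt.dt


def burn_in_samples(filt: LinearFilter) -> int:
    """Number of leading samples without full stimulus history."""
    return filt.taps.size - 1


def fit_nonlinearity(
    generator: np.ndarray,
    response: np.ndarray,
    n_bins: int = 20,
    min_count: int = 50,
) -> StaticNonlinearity:
    """Static nonlinearity by equal-count binning along the generator axis.

    Generator samples are split into ``n_bins`` quantile bins; each bin
    contributes (mean generator value, mean response).  Bins that end up with
    fewer than ``min_count`` samples (possible with heavily tied generator
    values) are merged with their neighbor.  Burn-in must already be removed.
    """
    g = np.asarray(generator, dtype=float)
    r = np.asarray(response, dtype=float)
    if g.size != r.size:
        raise ParameterError("generator and response must have equal length")
    if n_bins < 2:
        raise ParameterError("need at least two bins")
    if np.ptp(g) == 0:
        raise ParameterError("generator signal is constant; nonlinearity undefined")

    edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # tied quantiles collapse bins
    if edges.size < 3:
        raise ParameterError("generator distribution too degenerate to bin")
    which = np.clip(np.searchsorted(edges, g, side="right") - 1, 0, edges.size - 2)

    counts = np.bincount(which, minlength=edges.size - 1)
    sums_g = np.bincount(which, weights=g, minlength=edges.size - 1)
    sums_r = np.bincount(which, weights=r, minlength=edges.size - 1)

    # merge under-filled bins into the nearest neighbor, left to right
    bins: list[list[float]] = []
    for cnt, sg, sr in zip(counts, sums_g, sums_r):
        if cnt == 0:
            continue
        if bins and (bins[-1][0] < min_count or cnt < min_count):
            bins[-1][0] += cnt
            bins[-1][1] += sg
            bins[-1][2] += sr
        else:
            bins.append([cnt, sg, sr])
    if len(bins) >= 2 and bins[-1][0] < min_count:
        last = bins.pop()
        bins[-1] = [bins[-1][0] + last[0], bins[-1][1] + last[1], bins[-1][2] + last[2]]
    if len(bins) < 2:
        raise ParameterError("too few samples per bin; lower n_bins or min_count")

    arr = np.array(bins)
    centers = arr[:, 1] / arr[:, 0]
    means = arr[:, 2] / arr[:, 0]
    return StaticNonlinearity(centers, means, arr[:, 0].astype(int))


def predict_response(model: LNModel, stim: StimulusTrace) -> np.ndarray:
    """LN prediction: nonlinearity applied to the generator signal, with the
    fitted baseline re-added.  Same length as the stimulus (leading
    ``len(filter) - 1`` samples are burn-in)."""
    g = generator_signal(model.filter, stim)
    return model.nonlinearity(g) + model.response_baseline


def model_performance(prediction: np.ndarray, measured: np.ndarray) -> float:
    """Pearson correlation between a model prediction and the (trial-mean)
    measured response, burn-in already removed."""
    p = np.asarray(prediction, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.size != m.size:
        raise ParameterError("prediction and measurement must have equal length")
    if p.std() == 0 or m.std() == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    return float(np.corrcoef(p, m)[0, 1])


def fit_ln_model(
    stim: StimulusTrace,
    response: np.ndarray,
    filter_len_s: float = 0.5,
    n_bins: int = 20,
    min_count: int = 50,
    bandwidth_hz: float | None = None,
) -> LNModel:
    """Convenience end-to-end fit: filter by deconvolution, then the binned
    nonlinearity on the burn-in-free segment."""
    response = np.asarray(response, dtype=float)
    baseline = float(response.mean())
    filt = estimate_linear_filter(
        stim, response, filter_len_s, bandwidth_hz=bandwidth_hz
    )
    g = generator_signal(filt, stim)
    skip = burn_in_samples(filt)
    nl = fit_nonlinearity(
        g[skip:], response[skip:] - baseline, n_bins=n_bins, min_count=min_count
    )
    return LNModel(filt, nl, baseline)
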