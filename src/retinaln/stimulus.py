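"""Full-field light stimuli on a regular time grid.

Three stimulus classes drive every analysis in the package: band-limited
Gaussian noise (for reverse correlation), contrast steps (for step-response
kinetics), and paired flashes (for short-term depression).  Intensity is in
arbitrary photoisomerization-rate units and is never negative; the contrast
variable used everywhere downstream is Weber contrast relative to the mean
level, ``(I - I_mean) / I_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "StimulusTrace",
    "make_gaussian_noise",
    "make_step",
    "make_paired_flash",
]

#: default sample interval (s) for analysis-grade stimuli; acquisition in the
#: emulated experiments ran at 10 kHz but stimulus content is <= 60 Hz, so
#: 1 kHz resolves it with large margin.
DEFAULT_DT = 1e-3


@dataclass
class StimulusTrace:
    """Light-intensity time series.

    Attributes
    ----------
    values : ndarray
        Intensity samples, arbitrary photoisomerization-rate units, >= 0.
    dt : float
        Sample interval in seconds.
    mean_level : float
        Nominal mean intensity; the reference for Weber contrast.
    metadata : dict
        Free-form provenance (seed, bandwidth, clipped fraction, ...).
    """

    values: np.ndarray
    dt: float
    mean_level: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("stimulus needs >= 2 samples on a 1-D grid")
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.mean_level <= 0:
            raise ParameterError(f"mean_level must be positive, got {self.mean_level}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ParameterError("intensity samples must be finite and >= 0")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def contrast(self) -> np.ndarray:
        """Weber contrast, (I - I_mean) / I_mean."""
        return (self.values - self.mean_level) / self.mean_level


def make_gaussian_noise(
    mean_level: float,
    contrast_sd: float = 0.5,
    bandwidth_hz: float = 60.0,
    duration_s: float = 60.0,
    dt_s: float = DEFAULT_DT,
    seed: int | None = None,
) -> StimulusTrace:
    """Band-limited Gaussian noise around a photopic mean level.

    White Gaussian samples are drawn at ``dt_s``, brick-wall low-passed in the
    frequency domain at ``bandwidth_hz`` (zero phase), rescaled so the
    pre-clipping contrast SD equals ``contrast_sd``, shifted to ``mean_level``
    and clipped at zero intensity.  The clipped fraction is recorded in
    ``metadata['clipped_fraction']`` and the trace is *not* re-normalized after
    clipping (a physical light source simply cannot go negative).

    The defaults mirror the study conditions: SD = 50% of the mean and a
    0-60 Hz band.
    """
    if mean_level <= 0:
        raise ParameterError("mean_level must be positive")
    if not 0 <= contrast_sd <= 1:
        raise ParameterError(f"contrast_sd must be in [0, 1], got {contrast_sd}")
    nyquist = 0.5 / dt_s
    if bandwidth_hz <= 0 or bandwidth_hz > nyquist:
        raise ParameterError(
            f"bandwidth_hz must be in (0, {nyquist:g}] for dt={dt_s:g}"
        )
    n = int(round(duration_s / dt_s))
    if n < 2:
        raise ParameterError("duration too short for the requested dt")

    if contrast_sd == 0:
        values = np.full(n, float(mean_level))
        return StimulusTrace(values, dt_s, mean_level, {"seed": seed, "bandwidth_hz": bandwidth_hz, "contrast_sd": 0.0, "clipped_fraction": 0.0})

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    spec[freqs > bandwidth_hz] = 0.0
    band = np.fft.irfft(spec, n=n)
    band *= contrast_sd * mean_level / band.std()
    values = mean_level + band
    clipped = float(np.mean(values < 0))
    np.clip(values, 0.0, None, out=values)
    return StimulusTrace(
        values,
        dt_s,
        mean_level,
        {
            "seed": seed,
            "bandwidth_hz": bandwidth_hz,
            "contrast_sd": contrast_sd,
            "clipped_fraction": clipped,
        },
    )


def make_step(
    mean_level: float,
    contrast: float = 0.5,
    step_start_s: float = 0.5,
    step_dur_s: float = 0.5,
    total_dur_s: float = 2.0,
    dt_s: float = DEFAULT_DT,
) -> StimulusTrace:
    """Contrast step from the mean level (default: the 0.5-s, 50% step).

    Intensity is ``mean_level * (1 + contrast)`` for exactly
    ``round(step_dur_s / dt_s)`` samples starting at ``step_start_s`` and
    ``mean_level`` elsewhere.  ``contrast = -1`` darkens to zero, never below.
    """
    if contrast < -1:
        raise ParameterError("contrast below -1 would imply negative intensity")
    n = int(round(total_dur_s / dt_s))
    i0 = int(round(step_start_s / dt_s))
    n_step = int(round(step_dur_s / dt_s))
    if i0 < 0 or n_step <= 0 or i0 + n_step > n:
        raise ParameterError("step interval must lie inside the trace")
    values = np.full(n, float(mean_level))
    values[i0 : i0 + n_step] = mean_level * (1.0 + contrast)
    return StimulusTrace(
        values, dt_s, mean_level,
        {"contrast": contrast, "step_start_s": i0 * dt_s, "step_dur_s": n_step * dt_s},
    )


def make_paired_flash(
    mean_level: float,
    flash_contrast: float = 4.0,
    flash_dur_s: float = 0.010,
    intervals_s: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4),
    dt_s: float = DEFAULT_DT,
    first_flash_start_s: float = 0.5,
    total_dur_s: float | None = None,
) -> tuple[list[StimulusTrace], StimulusTrace]:
    """Paired-flash family: one trace per inter-flash interval plus the
    single-flash template.

    Each paired trace carries two identical rectangular flashes whose onsets
    are separated by the interval; the template has only the first flash and is
    the subtraction reference used to isolate the second-flash response.
    Defaults follow the study protocol: 400% contrast, 10-ms flashes at
    onset-to-onset intervals of 50, 100, 200 and 400 ms.
    """
    if flash_contrast <= 0:
        raise ParameterError("flash_contrast must be positive")
    intervals = [float(iv) for iv in intervals_s]
    if not intervals:
        raise ParameterError("need at least one interval")
    for iv in intervals:
        if iv < flash_dur_s:
            raise ParameterError(
                f"interval {iv:g} s < flash duration {flash_dur_s:g} s: flashes overlap"
            )
    if total_dur_s is None:
        # leave a full second after the latest second flash for the response
        total_dur_s = first_flash_start_s + max(intervals) + flash_dur_s + 1.0
    n = int(round(total_dur_s / dt_s))
    i0 = int(round(first_flash_start_s / dt_s))
    n_flash = int(round(flash_dur_s / dt_s))
    if n_flash <= 0:
        raise ParameterError("flash_dur_s shorter than one sample")

    def _with_flash_at(values: np.ndarray, idx: int) -> None:
        if idx < 0 or idx + n_flash > n:
            raise ParameterError("flash falls outside the trace")
        values[idx : idx + n_flash] = mean_level * (1.0 + flash_contrast)

    base_meta = {
        "flash_contrast": flash_contrast,
        "flash_dur_s": n_flash * dt_s,
        "first_flash_start_s": i0 * dt_s,
    }
    single = np.full(n, float(mean_level))
    _with_flash_at(single, i0)
    template = StimulusTrace(single, dt_s, mean_level, dict(base_meta))

    paired = []
    for iv in intervals:
        values = single.copy()
        _with_flash_at(values, i0 + int(round(iv / dt_s)))
        meta = dict(base_meta)
        meta["interval_s"] = int(round(iv / dt_s)) * dt_s
        paired.append(StimulusTrace(values, dt_s, mean_level, meta))
    return paired, template
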