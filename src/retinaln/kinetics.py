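"""Formula-defined response-kinetics statistics.

Four families of metrics quantify transient-versus-sustained behaviour:

* filter/STA waveform metrics — zero-cross time between the first and second
  lobes, and the biphasic index ``|A| / |B|`` where ``|B|`` is the absolute
  peak of the initial lobe and ``|A|`` that of the secondary lobe;
* step-response metrics — time to peak and the mean steady-state response in
  a late window divided by the initial peak (x100);
* the paired-flash ratio — peak response to the second of two flashes divided
  by the peak response to the first, per inter-flash interval.

All metrics are invariant to overall gain, and the waveform metrics also to
sign flips; a filter reported here on the causal lag axis at +0.080 s
corresponds to -0.080 s on the reversed display axis used for STAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .ln import LinearFilter

__all__ = [
    "KineticsSummary",
    "PairedFlashResult",
    "zero_cross_time",
    "biphasic_index",
    "filter_kinetics",
    "step_kinetics",
    "paired_flash_ratio",
]

#: extrema smaller than this fraction of max |filter| are treated as ripple,
#: not lobes; guards lobe detection on estimated (noisy) filters
DEFAULT_NOISE_FLOOR_FRAC = 0.1


@dataclass
class KineticsSummary:
    """Union of kinetics metrics; fields not applicable to the input are None.

    ``steady_state_pct`` can exceed 100 only when the response keeps growing
    past its windowed peak; that case is flagged.
    """

    zero_cross_time_s: float | None = None
    biphasic_index: float | None = None
    lobe_B_amp: float | None = None  # absolute peak of the initial lobe
    lobe_A_amp: float | None = None  # absolute peak of the secondary lobe
    time_to_peak_s: float | None = None
    steady_state_pct: float | None = None
    peak_amp: float | None = None
    baseline: float | None = None
    growth_flagged: bool = False


@dataclass
class PairedFlashResult:
    """Second-flash / first-flash peak ratios, one per inter-flash interval."""

    intervals_s: list[float]
    ratios: list[float]
    first_peak_amp: float


def _local_extrema(taps: np.ndarray) -> list[int]:
    """Indices of strict local extrema (plateau-tolerant, interior only)."""
    d = np.diff(taps)
    rising = d > 0
    falling = d < 0
    idx = []
    last_dir = 0
    for i in range(d.size):
        if rising[i]:
            direction = 1
        elif falling[i]:
            direction = -1
        else:
            continue
        if last_dir != 0 and direction != last_dir:
            idx.append(i)  # first sample after the turning slope run
        last_dir = direction
    return idx


def _initial_lobe(taps: np.ndarray, noise_floor_frac: float) -> int:
    peak = np.max(np.abs(taps))
    if peak == 0 or not np.all(np.isfinite(taps)):
        raise DegenerateInputError("filter is all zero or non-finite")
    floor = noise_floor_frac * peak
    for i in _local_extrema(taps):
        if abs(taps[i]) >= floor:
            return i
    # monotone waveform: extremum sits at an endpoint
    return int(np.argmax(np.abs(taps)))


def _zero_cross_index(taps: np.ndarray, i_ext: int) -> tuple[int, float] | None:
    """First sign change after the initial-lobe extremum.

    Returns (index of first opposite/zero sample, sub-sample crossing position
    in samples), or None when the waveform never crosses back."""
    s = np.sign(taps[i_ext])
    for j in range(i_ext + 1, taps.size):
        if taps[j] == 0:
            return j, float(j)
        if np.sign(taps[j]) != s:
            frac = taps[j - 1] / (taps[j - 1] - taps[j])
            return j, (j - 1) + float(frac)
    return None


def zero_cross_time(
    filt: LinearFilter, noise_floor_frac: float = DEFAULT_NOISE_FLOOR_FRAC
) -> float | None:
    """Time (s, causal lag axis) at which the waveform crosses zero between
    its first and second lobes; sub-sample by linear interpolation.  None for
    monophasic waveforms."""
    i_ext = _initial_lobe(filt.taps, noise_floor_frac)
    hit = _zero_cross_index(filt.taps, i_ext)
    if hit is None:
        return None
    return hit[1] * filt.dt


def biphasic_index(
    filt: LinearFilter, noise_floor_frac: float = DEFAULT_NOISE_FLOOR_FRAC
) -> float:
    """``|A| / |B|``: secondary-lobe over initial-lobe absolute peak.

    ``A`` is the largest-magnitude opposite-sign excursion after the zero
    cross (for triphasic waveforms this picks the dominant secondary lobe).
    Returns 0 when the waveform never develops a secondary lobe.
    """
    taps = filt.taps
    i_ext = _initial_lobe(taps, noise_floor_frac)
    b = abs(taps[i_ext])
    hit = _zero_cross_index(taps, i_ext)
    if hit is None:
        return 0.0
    j0 = hit[0]
    s = np.sign(taps[i_ext])
    tail = taps[j0:]
    opposite = tail[np.sign(tail) == -s]
    if opposite.size == 0:
        return 0.0
    return float(np.max(np.abs(opposite)) / b)


def filter_kinetics(
    filt: LinearFilter, noise_floor_frac: float = DEFAULT_NOISE_FLOOR_FRAC
) -> KineticsSummary:
    """Waveform metrics of a filter/STA in one pass."""
    taps = filt.taps
    i_ext = _initial_lobe(taps, noise_floor_frac)
    b = abs(taps[i_ext])
    zc = zero_cross_time(filt, noise_floor_frac)
    bi = biphasic_index(filt, noise_floor_frac)
    return KineticsSummary(
        zero_cross_time_s=zc,
        biphasic_index=bi,
        lobe_B_amp=float(b),
        lobe_A_amp=float(bi * b),
    )


def step_kinetics(
    response: np.ndarray,
    dt: float,
    step_onset_s: float,
    step_dur_s: float,
    steady_window_s: float = 0.1,
    baseline_window_s: float = 0.25,
) -> KineticsSummary:
    """Time-to-peak and steady-state percentage of peak for a step response.

    The baseline (mean over ``baseline_window_s`` immediately before onset)
    is subtracted; the peak is the largest-magnitude excursion within the
    step, and its sign defines the positive direction, so a downward
    (inward-current) response yields the same metrics as its mirror image.
    Time to peak is measured to the end of the peak sample, so an ideal
    square-pulse response reports one sample interval.  The default windows
    follow the electrophysiology convention (last 100 ms of the step); pass
    ``steady_window_s=1.0`` for the 2-s fluorescence convention.
    """
    y = np.asarray(response, dtype=float)
    i0 = int(round(step_onset_s / dt))
    n_step = int(round(step_dur_s / dt))
    nb = int(round(baseline_window_s / dt))
    ns = int(round(steady_window_s / dt))
    if nb < 1 or i0 - nb < 0:
        raise ParameterError("baseline window must precede step onset inside the trace")
    if n_step < 1 or i0 + n_step > y.size:
        raise ParameterError("step interval must lie inside the trace")
    if ns < 1 or ns > n_step:
        raise ParameterError("steady window must fit inside the step")

    baseline = float(y[i0 - nb : i0].mean())
    seg = y[i0 : i0 + n_step] - baseline
    ipk = int(np.argmax(np.abs(seg)))
    peak = float(seg[ipk])
    if peak == 0:
        raise DegenerateInputError("flat response: step kinetics undefined")
    steady = float(seg[-ns:].mean())
    pct = 100.0 * steady / peak
    return KineticsSummary(
        time_to_peak_s=(ipk + 1) * dt,
        steady_state_pct=pct,
        peak_amp=peak,
        baseline=baseline,
        growth_flagged=pct > 100.0,
    )


def paired_flash_ratio(
    paired_responses: dict[float, np.ndarray],
    single_flash_response: np.ndarray,
    dt: float,
    first_flash_onset_s: float,
    window_s: float = 0.2,
    subtract_template: bool = True,
) -> PairedFlashResult:
    """Peak-of-second-flash over peak-of-first-flash response ratios.

    The first-flash peak is measured from the single-flash template.  At short
    intervals the two responses overlap, so by default the template (aligned
    at the first-flash onset) is subtracted from each paired trace before the
    second-flash peak is read out — exact under linear superposition.  Set
    ``subtract_template=False`` for the raw peak after the second onset.
    Responses must share the time base and be baseline-subtracted.
    """
    tmpl = np.asarray(single_flash_response, dtype=float)
    i0 = int(round(first_flash_onset_s / dt))
    nw = int(round(window_s / dt))
    if nw < 1 or i0 < 0 or i0 + nw > tmpl.size:
        raise ParameterError("analysis window around the first flash exceeds the trace")
    seg1 = tmpl[i0 : i0 + nw]
    k1 = int(np.argmax(np.abs(seg1)))
    peak1 = float(seg1[k1])
    if peak1 == 0:
        raise DegenerateInputError("no first-flash response: ratio undefined")

    intervals: list[float] = []
    ratios: list[float] = []
    for iv in paired_responses:
        trace = np.asarray(paired_responses[iv], dtype=float)
        if trace.size != tmpl.size:
            raise ParameterError("paired trace and template must share the time base")
        i2 = i0 + int(round(iv / dt))
        if i2 + nw > trace.size:
            raise ParameterError(
                f"second-flash window at interval {iv:g} s exceeds the trace"
            )
        probe = trace - tmpl if subtract_template else trace
        seg2 = probe[i2 : i2 + nw]
        peak2 = float(seg2[np.argmax(np.abs(seg2))])
        intervals.append(float(iv))
        ratios.append(abs(peak2) / abs(peak1))
    return PairedFlashResult(intervals, ratios, first_peak_amp=peak1)
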