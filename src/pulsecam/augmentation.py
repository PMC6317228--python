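"""Radial augmentation index (AI).

    AI = late-systolic peak height / early-systolic peak height x 100 (%)

AI is the standard tonometric surrogate of arterial stiffness: the late
(tidal) peak is raised by the reflected pressure wave, so a stiffer arterial
tree augments it relative to the early (percussion) peak.

Conventions
-----------
* Peak heights are measured on the waveform's value scale (reference level
  zero).  For min-max normalized pulses -- the pipeline currency -- the
  diastolic foot sits at zero, so heights are then foot-referenced pulse
  pressures and AI is invariant to affine rescaling of the raw record.
* The peak search is restricted to the systolic window (phase below
  ``late_search_max_phase``, default 0.5) so the dicrotic wave is never
  mistaken for the late-systolic peak.
* Peak locations and heights are refined by a three-point parabolic fit, so
  AI varies smoothly with the underlying waveform (important both for
  grid-density independence and for gradient-based fitting on top of it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import PeakDetectionError
from .waveform import SampledWaveform, _moving_average


class Peak(NamedTuple):
    phase: float
    height: float


@dataclass(frozen=True)
class PeakConfig:
    """Systolic peak detection parameters.

    distinct_trough_frac:
        Two maxima count as distinct peaks only if the trough between them
        dips at least this fraction of the waveform amplitude below the
        lower of the two.  Below that, the inflection (shoulder) fallback is
        used.
    late_search_max_phase:
        Upper phase bound of the systolic window searched for both peaks.
    early_min_frac:
        A local maximum preceding the window's tallest peak is accepted as
        the early peak only if it reaches this fraction of that peak's
        height (guards against small noise bumps on the upstroke when the
        late peak dominates, i.e. AI > 100).
    min_upstroke_frac:
        A preceding maximum must additionally rise above the minimum before
        it by this fraction of the pulse amplitude: a percussion peak climbs
        from the diastolic foot, a noise bump on a descending limb does not.
    smooth_frac:
        Width of the pre-detection moving average as a fraction of the
        period (so measurements agree across grid densities); 0 disables.
        The default (1.5% of the period, 3 samples on the standard 200-point
        grid) suppresses single-sample noise maxima while biasing peak
        heights negligibly.
    """

    late_search_max_phase: float = 0.4
    distinct_trough_frac: float = 0.01
    early_min_frac: float = 0.5
    min_upstroke_frac: float = 0.25
    smooth_frac: float = 0.015


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (left-strict, right-weak)."""
    v = values
    mask = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])
    return np.flatnonzero(mask) + 1


def _refine(values: np.ndarray, idx: int, n: int) -> Peak:
    """Parabolic refinement of a peak through its three surrounding samples."""
    if idx <= 0 or idx >= values.size - 1:
        return Peak(phase=idx / n, height=float(values[idx]))
    y0, y1, y2 = values[idx - 1], values[idx], values[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # flat or non-concave: keep the grid sample
        return Peak(phase=idx / n, height=float(values[idx]))
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    height = y1 - 0.25 * (y0 - y2) * shift
    return Peak(phase=(idx + shift) / n, height=float(height))


@dataclass(frozen=True)
class AIResult:
    """Systolic peaks and the radial augmentation index of one pulse."""

    early_peak_phase: float
    early_peak_height: float
    late_peak_phase: float
    late_peak_height: float
    ai_percent: float
    #: AI > 100 (late peak taller than early) is physiologically possible in
    #: stiff arteries; it is flagged here rather than rejected.
    augmented_over_100: bool

    def to_dict(self) -> dict:
        return {
            "early_peak_phase": self.early_peak_phase,
            "early_peak_height": self.early_peak_height,
            "late_peak_phase": self.late_peak_phase,
            "late_peak_height": self.late_peak_height,
            "ai_percent": self.ai_percent,
            "augmented_over_100": self.augmented_over_100,
        }


def detect_systolic_peaks(
    pulse: SampledWaveform, config: PeakConfig | None = None
) -> tuple[Peak, Peak]:
    """Locate the early- and late-systolic peaks of one pulse.

    The pulse is assumed foot-anchored (phase 0 at the diastolic foot).
    Within the systolic window, the early peak is the dominant maximum (or a
    qualifying maximum preceding it), and the late peak is the tallest
    distinct maximum after it.  If no distinct second maximum exists, the
    late-systolic shoulder is located from the first derivative: the
    flattening point where the derivative, after the post-systolic descent,
    turns back toward zero (local minimum-to-maximum transition).

    Raises
    ------
    PeakDetectionError
        If the pulse is monotone/single-peaked with no detectable shoulder.
    """
    config = config or PeakConfig()
    window = max(1, int(round(config.smooth_frac * pulse.n)))
    v = _moving_average(pulse.values, window)
    n = pulse.n
    amp = pulse.amplitude
    if amp <= 0:
        raise PeakDetectionError("constant pulse has no systolic peaks")
    limit = int(np.ceil(config.late_search_max_phase * n))
    window = v[: limit + 1]
    maxima = _local_maxima(window)
    if maxima.size == 0:
        raise PeakDetectionError("no local maximum in the systolic window")

    def distinct(i: int, j: int) -> bool:
        trough = v[i : j + 1].min()
        return trough <= min(v[i], v[j]) - config.distinct_trough_frac * amp

    top = maxima[np.argmax(v[maxima])]
    # a qualifying maximum before the tallest one means the pulse is
    # late-augmented (AI > 100): the earlier maximum is the percussion peak
    early_idx = top
    for i in maxima[maxima < top]:
        rise = v[i] - v[: i + 1].min()
        if (
            v[i] >= config.early_min_frac * v[top]
            and rise >= config.min_upstroke_frac * amp
            and distinct(i, top)
        ):
            early_idx = i
            break
    if early_idx != top:
        late_idx = top
    else:
        after = maxima[maxima > early_idx]
        after = after[[distinct(early_idx, j) for j in after]] if after.size else after
        if after.size:
            # the late-systolic peak is the most prominent distinct maximum
            # after the early peak: prominence (height above the deepest
            # trough separating it from the early peak) is robust against
            # small noise bumps riding on the descending limb
            prominence = [v[j] - v[early_idx : j + 1].min() for j in after]
            late_idx = after[int(np.argmax(prominence))]
        else:
            return _shoulder_fallback(v, n, early_idx, limit)
    return _refine(v, int(early_idx), n), _refine(v, int(late_idx), n)


def _shoulder_fallback(
    v: np.ndarray, n: int, early_idx: int, limit: int
) -> tuple[Peak, Peak]:
    """Locate a late-systolic shoulder as an inflection feature.

    On the falling limb after the early peak, a shoulder shows up as the
    first derivative descending to a local minimum and then rising to a
    local maximum (the flattening).  The shoulder is placed at that
    derivative maximum; a monotone decay has no such interior feature.
    """
    d = np.gradient(v)
    seg = d[early_idx : limit + 1]
    if seg.size < 5:
        raise PeakDetectionError("no late-systolic feature")
    interior = _local_maxima(seg)
    # require a preceding descent (local min of the derivative) and a
    # non-trivial derivative rise, so smooth single-peak decays are rejected
    d_amp = np.max(np.abs(seg)) or 1.0
    for j in interior:
        pre_min = seg[:j].min() if j > 0 else seg[0]
        if seg[j] - pre_min > 0.02 * d_amp and pre_min < seg[j]:
            idx = early_idx + int(j)
            return _refine(v, int(early_idx), n), Peak(phase=idx / n, height=float(v[idx]))
    raise PeakDetectionError("no late-systolic feature")


def radial_ai(
    pulse: SampledWaveform, config: PeakConfig | None = None
) -> AIResult:
    """Compute the radial augmentation index of one pulse.

    ``ai_percent = 100 * late_peak_height / early_peak_height`` with heights
    measured from the zero of the pulse's value scale (the diastolic foot,
    for normalized pulses).
    """
    early, late = detect_systolic_peaks(pulse, config)
    if early.height <= 0:
        raise PeakDetectionError(
            f"early systolic peak height must be positive, got {early.height:g}"
        )
    ai = 100.0 * late.height / early.height
    return AIResult(
        early_peak_phase=early.phase,
        early_peak_height=early.height,
        late_peak_phase=late.phase,
        late_peak_height=late.height,
        ai_percent=ai,
        augmented_over_100=ai > 100.0,
    )
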