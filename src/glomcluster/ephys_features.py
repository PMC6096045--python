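"""Spike and passive-membrane feature extraction from current-clamp sweeps.

Nine physiological parameters feed the clustering: the three ICA
afterhyperpolarisation (AHP) scores, AP half-width, membrane time constant,
input resistance, AP speed ratio, CV of the inter-spike-interval
distribution, and AP amplitude.

Spike conventions
-----------------
* Detection: the smoothed dV/dt crosses a threshold (default 20 mV/ms) and
  a local voltage maximum follows within 2 ms; a 2 ms refractory period is
  enforced between accepted peaks.
* The AP threshold is the first point before the peak where dV/dt reaches
  the same criterion; the amplitude is peak − threshold voltage, and the
  half-width is measured between the two half-maximum crossings with linear
  sub-sample interpolation.  The rise/decay velocities are dV/dt at those
  two crossings; their quotient is the speed ratio.
* The average spike shape is a 25 ms window (5 ms pre-, 20 ms post-peak)
  aligned at the AP maximum and normalised by subtracting the voltage 1 ms
  before the peak.

The three AHP factors come from fixed-point ICA (FastICA) on the post-peak
segments of all cells' average shapes.  ICA is identifiable only up to sign
and permutation, so each factor is re-oriented so its dominant deflection
is negative and factors are ordered by the time of their most negative
extremum (early < intermediate < late).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit
from sklearn.decomposition import FastICA

from .io_formats import Sweep, SweepSet

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeEvent",
    "AverageSpikeShape",
    "ICAModel",
    "EphysFeatures",
    "NoSpikesError",
    "detect_spikes",
    "characterize_spike",
    "input_resistance",
    "membrane_time_constant",
    "cv_isi",
    "average_spike_shape",
    "fit_ahp_ica",
    "score_ahp",
    "compute_ephys_features",
]

#: dV/dt criterion for spike detection and threshold definition (mV/ms)
DVDT_THRESHOLD = 20.0
#: initial stretch of the post-peak segment excluded from the ICA fit; the
#: spike repolarisation lives there and would otherwise dominate the factors
AHP_FIT_SKIP_S = 2e-3
#: refractory / local-max search window (s)
REFRACTORY_S = 2e-3
#: average-shape window split around the peak (s)
PRE_PEAK_S, POST_PEAK_S = 5e-3, 20e-3


class NoSpikesError(ValueError):
    """Raised when an operation needs spikes and the cell fired none."""


@dataclass(frozen=True)
class SpikeEvent:
    peak_time: float       # s
    threshold_v: float     # mV
    amplitude: float       # mV
    half_width: float      # ms
    rise_velocity: float   # mV/ms
    decay_velocity: float  # mV/ms (negative)
    t_halfmax_pre: float   # s
    t_halfmax_post: float  # s

    @property
    def speed_ratio(self) -> float:
        return self.rise_velocity / abs(self.decay_velocity)


@dataclass
class AverageSpikeShape:
    waveform: np.ndarray    # mV, 25 ms window
    alignment_index: int    # sample of the peak
    sampling_rate: float    # Hz
    baseline_ref: float     # raw mV value 1 ms pre-peak (subtracted)

    def ahp_segment(self) -> np.ndarray:
        """Post-peak segment (peak to window end) used for the ICA factors."""
        return self.waveform[self.alignment_index:]


@dataclass
class ICAModel:
    """Three AHP factor time-courses plus the orientation/order convention."""

    factors: np.ndarray         # (3, T); dominant deflection negative
    sampling_rate: float
    scores: np.ndarray | None = None   # (n_cells, 3) mixing coefficients
    convention: str = "negative-deflection, ordered by extremum time"

    def to_json(self) -> dict:
        return {
            "factors": self.factors.tolist(),
            "sampling_rate": self.sampling_rate,
            "convention": self.convention,
        }

    @classmethod
    def from_json(cls, doc: dict) -> "ICAModel":
        return cls(
            factors=np.asarray(doc["factors"], dtype=float),
            sampling_rate=float(doc["sampling_rate"]),
            convention=doc.get("convention", ""),
        )


@dataclass(frozen=True)
class EphysFeatures:
    early_ahp: float
    late_ahp: float
    intermediate_ahp: float
    half_width: float        # ms
    time_constant: float     # ms
    input_resistance: float  # GΩ
    speed_ratio: float
    cv_isi: float
    amplitude: float         # mV

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# spike detection and characterisation
# ---------------------------------------------------------------------------

def _dvdt(voltage: np.ndarray, rate: float, smooth: int = 5) -> np.ndarray:
    """First derivative in mV/ms after light boxcar smoothing."""
    v = voltage
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        v = np.convolve(v, kernel, mode="same")
    return np.gradient(v) * rate / 1000.0


def detect_spikes(sweep: Sweep, rate: float, dvdt_threshold: float = DVDT_THRESHOLD,
                  restrict_to_step: bool = True) -> np.ndarray:
    """Indices of AP peaks in a sweep.

    A candidate is an upward dV/dt crossing of ``dvdt_threshold`` followed by
    a local voltage maximum within 2 ms; peaks closer than 2 ms to the
    previous accepted peak are discarded.
    """
    v = sweep.voltage
    d = _dvdt(v, rate)
    crossing = np.flatnonzero((d[1:] >= dvdt_threshold) & (d[:-1] < dvdt_threshold)) + 1
    if restrict_to_step:
        lo = int(sweep.step_onset * rate)
        hi = int(sweep.step_offset * rate) + int(REFRACTORY_S * rate)
        crossing = crossing[(crossing >= lo) & (crossing <= hi)]
    win = max(1, int(REFRACTORY_S * rate))
    peaks: list[int] = []
    for c in crossing:
        stop = min(len(v), c + win + 1)
        peak = c + int(np.argmax(v[c:stop]))
        # require a genuine local maximum, not a rising edge at the window end
        if peak + 1 < len(v) and v[peak + 1] > v[peak]:
            continue
        if peaks and (peak - peaks[-1]) < win:
            continue
        peaks.append(peak)
    return np.asarray(peaks, dtype=int)


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def characterize_spike(sweep: Sweep, peak: int, rate: float,
                       dvdt_threshold: float = DVDT_THRESHOLD) -> SpikeEvent | None:
    """Threshold, amplitude, half-width and half-max velocities of one AP.

    Returns None (with a warning) when no threshold crossing is found before
    the peak or the half-maximum crossings cannot be located.
    """
    v = sweep.voltage
    d = _dvdt(v, rate)
    dt = 1.0 / rate
    # threshold: first point of the rising-phase run where dV/dt >= criterion.
    # Locate the run by scanning backwards from the peak (the derivative is
    # ~0 at the peak itself), then walk to its start.
    lookback = max(1, int(5e-3 * rate))
    run_end = None
    for i in range(peak, max(0, peak - lookback), -1):
        if d[i] >= dvdt_threshold:
            run_end = i
            break
    if run_end is None:
        logger.warning("no threshold found before peak at sample %d; spike discarded", peak)
        return None
    idx = run_end
    while idx > 0 and d[idx - 1] >= dvdt_threshold:
        idx -= 1
    if idx == 0:
        logger.warning("threshold run reaches trace start at peak %d; spike discarded", peak)
        return None
    thr_idx = idx
    threshold_v = float(v[thr_idx])
    amplitude = float(v[peak] - threshold_v)
    if amplitude <= 0:
        return None
    half_level = threshold_v + amplitude / 2.0

    # pre-peak half-max crossing
    pre = None
    for i in range(peak, thr_idx, -1):
        if v[i - 1] <= half_level <= v[i]:
            pre = (i - 1, i)
            break
    # post-peak half-max crossing
    post = None
    stop = min(len(v) - 1, peak + int(POST_PEAK_S * rate))
    for i in range(peak, stop):
        if v[i] >= half_level >= v[i + 1]:
            post = (i, i + 1)
            break
    if pre is None or post is None:
        logger.warning("half-maximum crossings not found for peak %d; spike discarded", peak)
        return None

    t_pre = _interp_crossing(pre[0] * dt, pre[1] * dt, v[pre[0]], v[pre[1]], half_level)
    t_post = _interp_crossing(post[0] * dt, post[1] * dt, v[post[0]], v[post[1]], half_level)
    # derivative at the crossings, linearly interpolated between samples
    frac_pre = (t_pre / dt) - pre[0]
    frac_post = (t_post / dt) - post[0]
    rise = float(d[pre[0]] + frac_pre * (d[pre[1]] - d[pre[0]]))
    decay = float(d[post[0]] + frac_post * (d[post[1]] - d[post[0]]))
    if rise <= 0 or decay >= 0:
        return None
    return SpikeEvent(
        peak_time=peak * dt,
        threshold_v=threshold_v,
        amplitude=amplitude,
        half_width=(t_post - t_pre) * 1000.0,
        rise_velocity=rise,
        decay_velocity=decay,
        t_halfmax_pre=t_pre,
        t_halfmax_post=t_post,
    )


# ---------------------------------------------------------------------------
# passive properties
# ---------------------------------------------------------------------------

def _subthreshold_sweeps(sweeps: SweepSet) -> list[Sweep]:
    out = []
    for s in sweeps.sweeps:
        if s.step_amplitude == 0:
            continue
        if len(detect_spikes(s, sweeps.sampling_rate)) == 0:
            out.append(s)
    return out


def _baseline_and_steady(sweep: Sweep, rate: float) -> tuple[float, float]:
    on = int(sweep.step_onset * rate)
    off = int(sweep.step_offset * rate)
    baseline = float(np.mean(sweep.voltage[:on])) if on > 0 else float(sweep.voltage[0])
    tail = off - max(1, int(0.2 * (off - on)))
    steady = float(np.mean(sweep.voltage[tail:off]))
    return baseline, steady


def input_resistance(sweeps: SweepSet) -> float:
    """Steady-state ΔV/ΔI slope over all subthreshold step sweeps (GΩ).

    Steady state is the mean of the last 20% of the step window; the slope
    is the least-squares fit through the origin, which in mV/pA is GΩ.
    """
    sub = _subthreshold_sweeps(sweeps)
    if not sub:
        raise ValueError("no subthreshold (spike-free) step sweep available")
    dv = np.array([_baseline_and_steady(s, sweeps.sampling_rate)[1]
                   - _baseline_and_steady(s, sweeps.sampling_rate)[0] for s in sub])
    di = np.array([s.step_amplitude for s in sub])
    return float(np.sum(dv * di) / np.sum(di * di))


def membrane_time_constant(sweeps: SweepSet, fit_window_s: float = 0.25) -> float:
    """Membrane time constant τ (ms) from the passive step response.

    Fits V(t) = V∞ + ΔV·e^(−t/τ) after step onset of the largest
    subthreshold hyperpolarising sweep; falls back to the direct (1 − 1/e)
    crossing time if the fit does not converge.  The 250 ms default window
    keeps slow membranes (τ up to ~90 ms) identifiable with a free
    asymptote; pass 0.1 for a strict first-100-ms fit.
    """
    sub = [s for s in _subthreshold_sweeps(sweeps) if s.step_amplitude < 0]
    if not sub:
        raise ValueError("no subthreshold hyperpolarising sweep available")
    sweep = min(sub, key=lambda s: s.step_amplitude)
    rate = sweeps.sampling_rate
    on = int(sweep.step_onset * rate)
    stop = min(len(sweep.voltage), on + int(fit_window_s * rate))
    t = (np.arange(on, stop) - on) / rate
    v = sweep.voltage[on:stop]

    def model(tt, v_inf, dv, tau):
        return v_inf + dv * np.exp(-tt / tau)

    baseline, steady = _baseline_and_steady(sweep, rate)
    try:
        popt, _ = curve_fit(
            model, t, v,
            p0=(steady, baseline - steady, 0.02),
            bounds=((-np.inf, -np.inf, 1e-5), (np.inf, np.inf, 1.0)),
            maxfev=10000,
        )
        return float(popt[2] * 1000.0)
    except RuntimeError:
        # direct 1/e crossing of the deflection
        target = baseline + (steady - baseline) * (1.0 - 1.0 / np.e)
        below = np.flatnonzero(v <= target) if steady < baseline else np.flatnonzero(v >= target)
        if len(below) == 0:
            raise ValueError("time-constant fit failed and no 1/e crossing found")
        return float(below[0] / rate * 1000.0)


# ---------------------------------------------------------------------------
# firing statistics and spike shapes
# ---------------------------------------------------------------------------

def cv_isi(spike_trains: list[np.ndarray]) -> float:
    """CV of the pooled inter-spike-interval distribution (sample SD / mean).

    ISIs are computed within each suprathreshold sweep and pooled; fewer
    than two ISIs overall yield 0 (regular or single-spike firing).
    """
    isis = np.concatenate([np.diff(np.asarray(st, dtype=float)) for st in spike_trains]
                          or [np.array([])])
    if len(isis) < 2:
        return 0.0
    mean = float(np.mean(isis))
    return float(np.std(isis, ddof=1) / mean) if mean > 0 else 0.0


def average_spike_shape(sweeps: SweepSet) -> AverageSpikeShape:
    """Peak-aligned 25 ms average spike waveform, zeroed 1 ms pre-peak.

    Only isolated spikes enter the average: a spike is skipped when another
    detected spike falls inside its window (the preceding 5 ms or the
    following 20 ms), so that burst neighbours do not contaminate the AHP
    segment.  In bursting cells this keeps the burst-terminating spikes,
    which carry a clean afterhyperpolarisation.  If no spike is isolated,
    every spike is used.
    """
    rate = sweeps.sampling_rate
    n_pre = int(round(PRE_PEAK_S * rate))
    n_post = int(round(POST_PEAK_S * rate))
    snippets, crowded = [], []
    for s in sweeps.sweeps:
        peaks = detect_spikes(s, rate)
        for j, peak in enumerate(peaks):
            if peak - n_pre < 0 or peak + n_post >= len(s.voltage):
                continue
            window = s.voltage[peak - n_pre: peak + n_post + 1]
            isolated = ((j == 0 or peak - peaks[j - 1] > n_pre)
                        and (j == len(peaks) - 1 or peaks[j + 1] - peak > n_post))
            (snippets if isolated else crowded).append(window)
    if not snippets:
        snippets = crowded
    if not snippets:
        raise NoSpikesError("no spikes detected; cannot build an average spike shape")
    avg = np.mean(snippets, axis=0)
    ref_idx = n_pre - int(round(1e-3 * rate))
    baseline_ref = float(avg[ref_idx])
    return AverageSpikeShape(
        waveform=avg - baseline_ref,
        alignment_index=n_pre,
        sampling_rate=rate,
        baseline_ref=baseline_ref,
    )


# ---------------------------------------------------------------------------
# ICA of AHP waveforms
# ---------------------------------------------------------------------------

def fit_ahp_ica(shapes: np.ndarray, sampling_rate: float, n_components: int = 3,
                seed: int = 0) -> ICAModel:
    """Fixed-point ICA of the post-peak AHP segments of all cells.

    ``shapes`` is (n_cells, T) of peak-to-+20 ms segments.  The first 2 ms
    (the spike repolarisation) are excluded from the fit; components are
    re-oriented so each factor's dominant deflection is negative and ordered
    by the time of the most negative extremum; scores are the per-cell
    mixing coefficients under that convention.
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need at least 4 shapes with a common window")
    X = X[:, int(round(AHP_FIT_SKIP_S * sampling_rate)):]
    centered = X - X.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(centered) < n_components:
        raise ValueError(
            f"shape matrix has fewer than {n_components} effective dimensions; "
            "use fewer components"
        )
    # treat time as the sample axis: sources are factor time-courses and the
    # mixing matrix holds one coefficient triplet per cell
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=2000, tol=1e-6)
    sources = ica.fit_transform(X.T)            # (T, 3)
    mixing = ica.mixing_.copy()                 # (n_cells, 3)
    factors = sources.T.copy()                  # (3, T)
    for i in range(n_components):
        if factors[i].max() > -factors[i].min():
            factors[i] *= -1.0
            mixing[:, i] *= -1.0
    order = np.argsort([int(np.argmin(f)) for f in factors])
    factors = factors[order]
    mixing = mixing[:, order]
    return ICAModel(factors=factors, sampling_rate=sampling_rate,
                    scores=mixing)


def score_ahp(model: ICAModel, shape: np.ndarray) -> np.ndarray:
    """Project one AHP segment onto the model factors (least squares).

    The segment is cropped to the factors' support (the fit skips the
    repolarisation stretch), so a full peak-to-+20 ms segment can be passed.
    """
    x = np.asarray(shape, dtype=float)
    T = model.factors.shape[1]
    if len(x) > T:
        x = x[len(x) - T:]
    x = x - x.mean()
    coef, *_ = np.linalg.lstsq(model.factors.T, x, rcond=None)
    return coef


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def compute_ephys_features(sweeps: SweepSet, ica_model: ICAModel) -> EphysFeatures:
    """All nine physiological parameters for one cell.

    Spike-shape statistics are averaged over every detected spike; the AHP
    scores come from projecting the cell's average shape onto the shared ICA
    factors.  Raises :class:`NoSpikesError` for spike-free cells.
    """
    rate = sweeps.sampling_rate
    events: list[SpikeEvent] = []
    trains: list[np.ndarray] = []
    for s in sweeps.sweeps:
        peaks = detect_spikes(s, rate)
        if len(peaks) > 0:
            trains.append(peaks / rate)
        for p in peaks:
            ev = characterize_spike(s, p, rate)
            if ev is not None:
                events.append(ev)
    if not events:
        raise NoSpikesError(f"cell {sweeps.cell_id or '?'}: no spikes detected")
    shape = average_spike_shape(sweeps)
    scores = score_ahp(ica_model, shape.ahp_segment())
    return EphysFeatures(
        early_ahp=float(scores[0]),
        late_ahp=float(scores[2]),
        intermediate_ahp=float(scores[1]),
        half_width=float(np.mean([e.half_width for e in events])),
        time_constant=membrane_time_constant(sweeps),
        input_resistance=input_resistance(sweeps),
        speed_ratio=float(np.mean([e.speed_ratio for e in events])),
        cv_isi=cv_isi(trains),
        amplitude=float(np.mean([e.amplitude for e in events])),
    )
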