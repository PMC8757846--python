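"""PCG preprocessing, simplified cycle segmentation, and the six features.

The processing chain mirrors a classic auscultation pipeline:

1. **Preprocess** — zero-phase 10–900 Hz Butterworth band-pass followed by
   db4 wavelet denoising (5 levels, soft universal threshold estimated
   from the finest detail level).
2. **Segment** — Shannon-energy envelope of a 20–110 Hz band-limited copy
   (where S1/S2 live and broadband murmurs do not), peak picking with a
   200 ms refractory distance, alternating S1/S2 assignment using the
   physiological rule that systole is shorter than diastole, and interval
   extents at the 10% envelope crossing around each peak.  An *oracle*
   mode consumes ground-truth annotations instead, so features and the
   classifier can be tested independently of segmentation quality.
3. **Features** — per record, averaged over cycles:

   =====  =======================================================
   F1     systolic / diastolic interval ratio
   F2     S1 / S2 interval ratio
   F3     systolic peak energy / total cycle energy
   F4     diastolic peak energy / total cycle energy
   F5     mean 10 Hz-binned spectral magnitude (10–900 Hz), systole
   F6     same, diastole
   =====  =======================================================

   "Peak energy" is the energy in a 50 ms window centred on the in-interval
   envelope maximum; spectra use a Hann window, zero padding to <= 1 Hz
   resolution and per-cycle amplitude normalisation, so every feature is
   invariant to global amplitude scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.fft import next_fast_len, rfft, rfftfreq

from .synth import PCGRecord

__all__ = [
    "PipelineConfig",
    "SegmentationError",
    "CycleIntervals",
    "SegmentationResult",
    "FeatureVector",
    "FEATURE_NAMES",
    "preprocess",
    "shannon_envelope",
    "segment",
    "segment_from_annotations",
    "feature_f1",
    "feature_f2",
    "feature_f3",
    "feature_f4",
    "feature_f5",
    "feature_f6",
    "binned_magnitude_spectrum",
    "extract_features",
    "features_from_record",
]

FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6")


class SegmentationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable constant of the processing chain, with defaults."""

    band: tuple[float, float] = (10.0, 900.0)
    filter_order: int = 4
    wavelet: str = "db4"
    wavelet_levels: int = 5
    env_band: tuple[float, float] = (20.0, 110.0)
    env_win_s: float = 0.015
    env_hop_s: float = 0.005
    peak_min_dist_s: float = 0.2
    peak_rel_height: float = 0.2
    extent_rel: float = 0.1
    peak_energy_win_s: float = 0.05
    spec_band: tuple[float, float] = (10.0, 900.0)
    spec_bin_hz: float = 10.0

    def __post_init__(self):
        if self.env_win_s <= self.env_hop_s or self.env_hop_s <= 0:
            raise ValueError("requires env_win_s > env_hop_s > 0")
        if not (0 < self.peak_rel_height < 1 and 0 < self.extent_rel < 1):
            raise ValueError("relative thresholds must be in (0,1)")


@dataclass
class CycleIntervals:
    """One cardiac cycle as four half-open [start, end) intervals (seconds)."""

    s1: tuple[float, float]
    systole: tuple[float, float]
    s2: tuple[float, float]
    diastole: tuple[float, float]

    def __post_init__(self):
        seq = [*self.s1, *self.systole, *self.s2, *self.diastole]
        if any(b < a for a, b in zip(seq[:-1], seq[1:])):
            raise ValueError(f"cycle intervals out of order: {self}")
        if self.s1[1] != self.systole[0] or self.systole[1] != self.s2[0] or self.s2[1] != self.diastole[0]:
            raise ValueError("cycle intervals must be contiguous")

    @property
    def start(self) -> float:
        return self.s1[0]

    @property
    def end(self) -> float:
        return self.diastole[1]


@dataclass
class SegmentationResult:
    cycles: list  # of CycleIntervals
    source: str  # "estimated" | "oracle"
    warnings: list = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(samples, fs: float, config: PipelineConfig | None = None) -> np.ndarray:
    """Band-pass + wavelet-denoise a raw PCG trace (length preserved)."""
    cfg = config or PipelineConfig()
    x = np.asarray(samples, dtype=float)
    if fs < 1800:
        raise ValueError("fs must be >= 1800 Hz for a 10-900 Hz band")
    if len(x) < fs:
        raise ValueError("signal shorter than 1 s")
    hi = min(cfg.band[1], 0.45 * fs)
    sos = sps.butter(cfg.filter_order, (cfg.band[0], hi), btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)

    coeffs = pywt.wavedec(y, cfg.wavelet, level=cfg.wavelet_levels)
    # noise scale from the finest detail level (VisuShrink)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(len(y), 2)))
    if thr > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, cfg.wavelet)
    return out[: len(y)]


def shannon_envelope(samples, fs: float, win_s: float = 0.015, hop_s: float = 0.005):
    """Windowed Shannon energy envelope.

    Per hop: mean of ``-s^2 * ln(s^2)`` over the window, on globally
    amplitude-normalised samples (``0*ln 0 := 0``), then a 3-point moving
    average.  Returns ``(times, envelope)`` with times at window centres.
    The normalisation makes the envelope invariant to global scaling; the
    normaliser is 1.2x the absolute peak so the loudest transient stays
    below the turnover of the Shannon weighting (-a^2 ln a^2 peaks at
    ``a = 1/sqrt(e)``), keeping a single apex per burst.
    """
    if not (win_s > hop_s > 0):
        raise ValueError("requires win_s > hop_s > 0")
    x = np.asarray(samples, dtype=float)
    m = 1.2 * np.max(np.abs(x))
    s = x / m if m > 0 else x
    s2 = s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(s2 > 0, -s2 * np.log(s2), 0.0)
    win = max(2, int(round(win_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    n_frames = 1 + max(0, (len(e) - win)) // hop
    csum = np.concatenate([[0.0], np.cumsum(e)])
    starts = np.arange(n_frames) * hop
    env = (csum[starts + win] - csum[starts]) / win
    env = np.convolve(env, np.ones(3) / 3.0, mode="same")
    times = (starts + win / 2.0) / fs
    return times, env


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _extent(env, pk, lo_bound, hi_bound, rel):
    """Indices of the rel-threshold crossing around peak ``pk``."""
    thr = rel * env[pk]
    i = pk
    while i > lo_bound and env[i] >= thr:
        i -= 1
    j = pk
    while j < hi_bound and env[j] >= thr:
        j += 1
    return i, j


def segment(samples, fs: float, config: PipelineConfig | None = None) -> SegmentationResult:
    """Estimate S1/systole/S2/diastole intervals from the waveform alone.

    Peak-picks the Shannon envelope of a band-limited (default 20-110 Hz)
    copy of the signal; alternating peaks are assigned S1/S2 roles by
    comparing the two alternating gap families (systole is the shorter
    one).  Degenerate cycles (systole >= diastole, or non-positive
    intervals) are dropped with a warning.
    """
    cfg = config or PipelineConfig()
    x = np.asarray(samples, dtype=float)
    sos = sps.butter(4, cfg.env_band, btype="bandpass", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)
    times, env = shannon_envelope(xb, fs, cfg.env_win_s, cfg.env_hop_s)
    hop = times[1] - times[0] if len(times) > 1 else cfg.env_hop_s
    dist = max(1, int(round(cfg.peak_min_dist_s / hop)))
    peaks, _ = sps.find_peaks(env, distance=dist, height=cfg.peak_rel_height * np.max(env))
    if len(peaks) < 2:
        raise SegmentationError(f"only {len(peaks)} envelope peak(s) detected")

    gaps = np.diff(times[peaks])
    even = gaps[0::2]
    odd = gaps[1::2]
    # systolic gaps are the shorter alternating family; if the even-index
    # family is shorter, peak 0 is an S1
    first_is_s1 = np.mean(even) <= np.mean(odd) if len(odd) else True
    s1_peaks = peaks[0::2] if first_is_s1 else peaks[1::2]
    s2_peaks = peaks[1::2] if first_is_s1 else peaks[2::2]

    # per-peak extents, bounded by midpoints to neighbouring peaks
    bounds_lo = {}
    bounds_hi = {}
    for k, pk in enumerate(peaks):
        bounds_lo[pk] = 0 if k == 0 else (peaks[k - 1] + pk) // 2 + 1
        bounds_hi[pk] = len(env) - 1 if k == len(peaks) - 1 else (pk + peaks[k + 1]) // 2 - 1

    def interval(pk):
        i, j = _extent(env, pk, bounds_lo[pk], bounds_hi[pk], cfg.extent_rel)
        return float(times[i]), float(times[j])

    cycles = []
    warns = []
    n_pairs = min(len(s1_peaks), len(s2_peaks))
    dia_lengths = []
    for k in range(n_pairs):
        p1, p2 = s1_peaks[k], s2_peaks[k]
        if p2 <= p1:
            continue
        s1_on, s1_off = interval(p1)
        s2_on, s2_off = interval(p2)
        if k + 1 < len(s1_peaks):
            next_on, _ = interval(s1_peaks[k + 1])
            dia_lengths.append(max(next_on - s2_off, 0.0))
        elif dia_lengths:
            # the record ends before the next S1: close the final diastole
            # at the running mean diastolic length instead of the file end
            next_on = min(s2_off + float(np.mean(dia_lengths)), float(times[-1]))
        else:
            next_on = float(times[-1])
        s1_off = min(s1_off, s2_on)
        dia_end = max(next_on, s2_off)
        try:
            cyc = CycleIntervals(
                s1=(s1_on, s1_off),
                systole=(s1_off, s2_on),
                s2=(s2_on, s2_off),
                diastole=(s2_off, dia_end),
            )
        except ValueError as exc:
            warns.append(f"cycle {k}: {exc}")
            continue
        sys_len = cyc.systole[1] - cyc.systole[0]
        dia_len = cyc.diastole[1] - cyc.diastole[0]
        if sys_len <= 0 or dia_len <= 0 or sys_len >= dia_len:
            warns.append(f"cycle {k}: degenerate (systole {sys_len:.3f}s >= diastole {dia_len:.3f}s)")
            continue
        cycles.append(cyc)
    if warns:
        warnings.warn("; ".join(warns), stacklevel=2)
    if not cycles:
        raise SegmentationError("no valid cycles after degeneracy filtering")
    return SegmentationResult(cycles=cycles, source="estimated", warnings=warns)


def segment_from_annotations(annotations, duration: float) -> SegmentationResult:
    """Oracle segmentation from ground-truth (s1_on, s1_off, s2_on, s2_off).

    The final cycle's diastole is closed at the mean diastolic length of
    the preceding cycles (the next S1 onset is not annotated); a lone
    cycle falls back to the record end.
    """
    cycles = []
    anns = list(annotations)
    prev_dia = [
        anns[k + 1][0] - anns[k][3] for k in range(len(anns) - 1)
    ]
    for k, (s1_on, s1_off, s2_on, s2_off) in enumerate(anns):
        if k + 1 < len(anns):
            dia_end = anns[k + 1][0]
        elif prev_dia:
            dia_end = min(s2_off + float(np.mean(prev_dia)), duration)
        else:
            dia_end = duration
        cycles.append(
            CycleIntervals(
                s1=(s1_on, s1_off),
                systole=(s1_off, s2_on),
                s2=(s2_on, s2_off),
                diastole=(s2_off, dia_end),
            )
        )
    if not cycles:
        raise SegmentationError("empty annotation list")
    return SegmentationResult(cycles=cycles, source="oracle")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    F1: float
    F2: float
    F3: float
    F4: float
    F5: float
    F6: float
    details: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.F1, self.F2, self.F3, self.F4, self.F5, self.F6])


def _ratio_mean(pairs, what: str) -> float:
    vals = [a / b for a, b in pairs if b > 0]
    if not vals:
        raise ValueError(f"no cycles with nonzero {what}")
    return float(np.mean(vals))


def feature_f1(seg: SegmentationResult) -> float:
    """Mean systolic/diastolic interval ratio over cycles."""
    return _ratio_mean(
        [
            (c.systole[1] - c.systole[0], c.diastole[1] - c.diastole[0])
            for c in seg.cycles
        ],
        "diastole length",
    )


def feature_f2(seg: SegmentationResult) -> float:
    """Mean S1/S2 interval-length ratio over cycles."""
    return _ratio_mean(
        [(c.s1[1] - c.s1[0], c.s2[1] - c.s2[0]) for c in seg.cycles], "S2 length"
    )


def _peak_energy_fraction(samples, fs, seg, which: str, cfg: PipelineConfig) -> float:
    """Shared implementation of F3 (systole) / F4 (diastole)."""
    x = np.asarray(samples, dtype=float)
    times, env = shannon_envelope(x, fs, cfg.env_win_s, cfg.env_hop_s)
    half = cfg.peak_energy_win_s / 2.0
    fracs = []
    for c in seg.cycles:
        lo, hi = getattr(c, which)
        total = np.sum(x[int(c.start * fs): int(c.end * fs)] ** 2)
        if total <= 0:
            continue
        mask = (times >= lo) & (times < hi)
        if not np.any(mask):
            fracs.append(0.0)
            continue
        idx = np.flatnonzero(mask)
        t_star = times[idx[np.argmax(env[idx])]]
        w_lo = max(lo, t_star - half)
        w_hi = min(hi, t_star + half)
        e = np.sum(x[int(w_lo * fs): int(w_hi * fs)] ** 2)
        fracs.append(float(e / total))
    if not fracs:
        raise ValueError("no cycles with nonzero energy")
    return float(np.mean(fracs))


def feature_f3(samples, fs, seg, config: PipelineConfig | None = None) -> float:
    """Mean fraction of cycle energy in a 50 ms window at the systolic envelope peak."""
    return _peak_energy_fraction(samples, fs, seg, "systole", config or PipelineConfig())


def feature_f4(samples, fs, seg, config: PipelineConfig | None = None) -> float:
    """Diastolic counterpart of F3."""
    return _peak_energy_fraction(samples, fs, seg, "diastole", config or PipelineConfig())


def binned_magnitude_spectrum(segment_samples, fs, cfg: PipelineConfig | None = None):
    """Per-10 Hz-bin mean magnitude spectrum of one (cycle-phase) segment.

    The segment is amplitude-normalised, Hann-windowed and zero-padded to
    <= 1 Hz resolution; returns ``(bin_edges, bin_means)`` over the 10-900
    Hz analysis band.  An all-zero segment yields all-zero bins.
    """
    cfg = cfg or PipelineConfig()
    seg_x = np.asarray(segment_samples, dtype=float)
    if len(seg_x) < 2:
        raise ValueError("segment shorter than 2 samples")
    lo_f, hi_f = cfg.spec_band
    edges = np.arange(lo_f, hi_f + 1e-9, cfg.spec_bin_hz)
    m = np.max(np.abs(seg_x))
    if m == 0:
        return edges, np.zeros(len(edges) - 1)
    seg_n = seg_x / m
    w = np.hanning(len(seg_n))
    nfft = next_fast_len(max(len(seg_n), int(np.ceil(fs / 1.0))))  # <= 1 Hz resolution
    spec = np.abs(rfft(seg_n * w, n=nfft))
    freqs = rfftfreq(nfft, d=1.0 / fs)
    bin_means = np.array(
        [
            np.mean(spec[(freqs >= a) & (freqs < b)]) if np.any((freqs >= a) & (freqs < b)) else 0.0
            for a, b in zip(edges[:-1], edges[1:])
        ]
    )
    return edges, bin_means


def _binned_spectral_mean(samples, fs, seg, which: str, cfg: PipelineConfig) -> float:
    """Mean over 10 Hz bins of the Hann-windowed magnitude spectrum."""
    x = np.asarray(samples, dtype=float)
    vals = []
    for c in seg.cycles:
        lo, hi = getattr(c, which)
        seg_x = x[int(lo * fs): int(hi * fs)]
        if len(seg_x) < 2:
            continue
        _, bin_means = binned_magnitude_spectrum(seg_x, fs, cfg)
        vals.append(float(np.mean(bin_means)))
    if not vals:
        raise ValueError(f"no usable {which} segments")
    return float(np.mean(vals))


def feature_f5(samples, fs, seg, config: PipelineConfig | None = None) -> float:
    """Systolic spectral mean over 10 Hz bins spanning 10-900 Hz."""
    return _binned_spectral_mean(samples, fs, seg, "systole", config or PipelineConfig())


def feature_f6(samples, fs, seg, config: PipelineConfig | None = None) -> float:
    """Diastolic spectral mean over 10 Hz bins spanning 10-900 Hz."""
    return _binned_spectral_mean(samples, fs, seg, "diastole", config or PipelineConfig())


def extract_features(samples, fs, seg, config: PipelineConfig | None = None) -> FeatureVector:
    """Assemble the six-feature descriptor for one record."""
    cfg = config or PipelineConfig()
    fv = FeatureVector(
        F1=feature_f1(seg),
        F2=feature_f2(seg),
        F3=feature_f3(samples, fs, seg, cfg),
        F4=feature_f4(samples, fs, seg, cfg),
        F5=feature_f5(samples, fs, seg, cfg),
        F6=feature_f6(samples, fs, seg, cfg),
        details={"n_cycles": seg.n_cycles, "source": seg.source},
    )
    return fv


def features_from_record(
    record: PCGRecord,
    segmentation: str = "estimated",
    config: PipelineConfig | None = None,
) -> FeatureVector:
    """Preprocess + segment + extract features for one record.

    ``segmentation`` is ``"estimated"`` (envelope segmenter) or
    ``"oracle"`` (ground-truth annotations).
    """
    cfg = config or PipelineConfig()
    clean = preprocess(record.samples, record.fs, cfg)
    if segmentation == "oracle":
        seg = segment_from_annotations(record.annotations, record.duration)
    elif segmentation == "estimated":
        seg = segment(clean, record.fs, cfg)
    else:
        raise ValueError(f"unknown segmentation mode {segmentation!r}")
    return extract_features(clean, record.fs, seg, cfg)
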