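"""Synthetic phonocardiogram generator with ground-truth annotations.

Emulates single-channel heart-sound recordings: each cardiac cycle carries
an S1 and an S2 valve transient (Gaussian-modulated sinusoids), optional
low-frequency S3/S4 sounds in early/late diastole, and optionally one of
three murmurs — aortic stenosis (crescendo–decrescendo mid-systolic noise),
mitral regurgitation (holosystolic noise) or mitral stenosis (diastolic
rumble).  Murmur noise is band-limited to 100–400 Hz; white measurement
noise is added at a configurable SNR, and the result is peak-normalised.

Ground truth is emitted alongside the waveform: per-cycle
``(s1_on, s1_off, s2_on, s2_off)`` times.  The annotated S1/S2 edges sit at
two Gaussian sigmas from the burst centre — the point where the burst's
Shannon envelope has decayed to roughly 10% of its peak — so the annotated
interval is the envelope-visible extent of the sound.

Everything is driven by a single seed; the same config reproduces the same
record bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "CLASS_NAMES",
    "MURMUR_CLASSES",
    "SynthConfig",
    "PCGRecord",
    "gen_transient",
    "gen_components",
    "gen_record",
    "gen_dataset",
]

CLASS_NAMES = (
    "S1S2_normal",
    "S3S4",
    "aortic_stenosis",
    "mitral_stenosis",
    "mitral_regurgitation",
)
MURMUR_CLASSES = ("none", "aortic_stenosis", "mitral_stenosis", "mitral_regurgitation")

# Murmur loudness (noise RMS at the envelope peak, relative to the unit S1
# amplitude) by type: aortic stenosis is characteristically loud and harsh,
# regurgitant and stenotic mitral murmurs softer.
_MURMUR_AMP_DEFAULT = {
    "aortic_stenosis": 0.50,
    "mitral_regurgitation": 0.35,
    "mitral_stenosis": 0.40,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic PCG record.

    Durations are in seconds, frequencies in Hz.  ``systole_s`` /
    ``diastole_s`` default to ``0.30 * T`` and the cycle remainder
    (``T = 60/heart_rate_bpm``), mimicking the physiological shortening of
    diastole with heart rate.  ``s1_dur`` etc. are *annotated* interval
    lengths; the underlying tone burst's Gaussian sigma is ``dur/4``.
    """

    fs: float = 2000.0
    heart_rate_bpm: float = 70.0
    systole_s: float | None = None
    diastole_s: float | None = None
    s1_freq: float = 60.0
    s2_freq: float = 90.0
    s1_dur: float = 0.10
    s2_dur: float = 0.08
    s1_amp: float = 1.0
    s2_amp: float = 0.8
    include_s3: bool = False
    include_s4: bool = False
    s3s4_freq: float = 40.0
    s3s4_dur: float = 0.06
    s3s4_amp: float = 0.30
    murmur: str = "none"
    murmur_amp: float | None = None
    murmur_band: tuple[float, float] = (100.0, 400.0)
    snr_db: float = 20.0
    jitter_frac: float = 0.02
    n_cycles: int = 8
    seed: int = 0
    lead_s: float = 0.1

    def __post_init__(self):
        if self.murmur not in MURMUR_CLASSES:
            raise ValueError(f"unknown murmur type {self.murmur!r}")
        if self.murmur != "none" and (self.include_s3 or self.include_s4):
            raise ValueError("murmur and S3/S4 flags are mutually exclusive")
        if self.fs < 2000:
            raise ValueError("fs must be >= 2000 Hz (10-900 Hz feature band)")
        if not (0 <= self.jitter_frac < 0.2):
            raise ValueError("jitter_frac out of range")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def resolved(self) -> "SynthConfig":
        """Fill derived systole/diastole durations and validate the cycle budget."""
        T = self.period
        sys_s = self.systole_s if self.systole_s is not None else 0.30 * T
        dia_s = (
            self.diastole_s
            if self.diastole_s is not None
            else T - self.s1_dur - self.s2_dur - sys_s
        )
        if dia_s <= 0 or sys_s <= 0:
            raise ValueError("cycle durations are inconsistent with heart rate")
        total = self.s1_dur + sys_s + self.s2_dur + dia_s
        if abs(total - T) > 0.01 * T:
            raise ValueError(
                f"s1+systole+s2+diastole = {total:.4f}s deviates from the "
                f"cycle period {T:.4f}s by more than 1%"
            )
        return replace(self, systole_s=sys_s, diastole_s=dia_s)

    @property
    def label(self) -> str:
        if self.murmur != "none":
            return self.murmur
        if self.include_s3 or self.include_s4:
            return "S3S4"
        return "S1S2_normal"

    @property
    def murmur_amplitude(self) -> float:
        if self.murmur == "none":
            return 0.0
        if self.murmur_amp is not None:
            return self.murmur_amp
        return _MURMUR_AMP_DEFAULT[self.murmur]


@dataclass
class PCGRecord:
    """A synthetic (or loaded) PCG waveform with its ground truth."""

    samples: np.ndarray
    fs: float
    annotations: list  # [(s1_on, s1_off, s2_on, s2_off), ...] seconds
    label: str
    config: SynthConfig | None = None
    components: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        dur = len(self.samples) / self.fs
        prev_end = -1.0
        for a in self.annotations:
            s1_on, s1_off, s2_on, s2_off = a
            if not (prev_end < s1_on < s1_off < s2_on < s2_off <= dur):
                raise ValueError(f"annotation ordering violated: {a}")
            prev_end = s2_off

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def gen_transient(
    center: float, freq: float, dur: float, amp: float, fs: float, total_s: float
) -> np.ndarray:
    """Gaussian-modulated sinusoid modelling a single valve sound.

    ``amp * sin(2*pi*freq*(t-center)) * exp(-(t-center)^2 / (2*sigma^2))``
    with ``sigma = dur/6``, rendered over a ``total_s``-long sample grid.
    """
    if dur <= 0:
        raise ValueError("dur must be positive")
    if freq >= fs / 2:
        raise ValueError("transient frequency violates Nyquist")
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    sigma = dur / 6.0
    env = np.exp(-((t - center) ** 2) / (2.0 * sigma**2))
    return amp * np.sin(2.0 * np.pi * freq * (t - center)) * env


def _cos_ramp_window(t: np.ndarray, start: float, end: float, ramp: float) -> np.ndarray:
    """Flat window on [start, end] with raised-cosine ramps of length ``ramp``."""
    w = np.zeros_like(t)
    core = (t >= start + ramp) & (t <= end - ramp)
    w[core] = 1.0
    up = (t >= start) & (t < start + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    dn = (t > end - ramp) & (t <= end)
    w[dn] = 0.5 * (1 - np.cos(np.pi * (end - t[dn]) / ramp))
    return w


def _diamond_window(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Triangular (crescendo-decrescendo) window peaking mid-interval."""
    w = np.zeros_like(t)
    mid = 0.5 * (start + end)
    half = 0.5 * (end - start)
    inside = (t >= start) & (t <= end)
    w[inside] = 1.0 - np.abs(t[inside] - mid) / half
    return w


def gen_components(cfg: SynthConfig) -> dict:
    """Render a record's constituent parts separately.

    Returns a dict with keys ``transients`` (S1/S2/S3/S4 sum), ``murmur``,
    ``noise`` (white, scaled to the requested SNR against
    transients+murmur), ``annotations``, ``cycle_starts`` and ``duration``.
    Exposed so tests can audit SNR and murmur placement exactly.
    """
    cfg = cfg.resolved()
    rng = np.random.default_rng(cfg.seed)
    T = cfg.period

    # per-cycle period jitter, absorbed by diastole
    jit = cfg.jitter_frac * rng.uniform(-1.0, 1.0, size=cfg.n_cycles)
    periods = T * (1.0 + jit)
    starts = cfg.lead_s + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    duration = cfg.lead_s + float(np.sum(periods)) + cfg.lead_s
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    transients = np.zeros(n)
    annotations = []
    cycles = []  # (s1_on, s1_off, s2_on, s2_off, dia_end)
    for i, t0 in enumerate(starts):
        s1_on = t0
        s1_off = s1_on + cfg.s1_dur
        s2_on = s1_off + cfg.systole_s
        s2_off = s2_on + cfg.s2_dur
        dia_end = t0 + periods[i]
        annotations.append((s1_on, s1_off, s2_on, s2_off))
        cycles.append((s1_on, s1_off, s2_on, s2_off, dia_end))
        s1_c = 0.5 * (s1_on + s1_off)
        s2_c = 0.5 * (s2_on + s2_off)
        # annotated edge at 2 sigma  =>  gen_transient dur = 1.5 * annotated dur
        transients += gen_transient(s1_c, cfg.s1_freq, 1.5 * cfg.s1_dur, cfg.s1_amp, cfg.fs, duration)
        transients += gen_transient(s2_c, cfg.s2_freq, 1.5 * cfg.s2_dur, cfg.s2_amp, cfg.fs, duration)
        if cfg.include_s3:
            c3 = s2_off + 0.12
            transients += gen_transient(c3, cfg.s3s4_freq, 1.5 * cfg.s3s4_dur, cfg.s3s4_amp, cfg.fs, duration)
        if cfg.include_s4:
            c4 = dia_end - 0.09
            transients += gen_transient(c4, cfg.s3s4_freq, 1.5 * cfg.s3s4_dur, cfg.s3s4_amp, cfg.fs, duration)

    murmur = np.zeros(n)
    if cfg.murmur != "none":
        raw = rng.standard_normal(n)
        sos = sps.butter(4, cfg.murmur_band, btype="bandpass", fs=cfg.fs, output="sos")
        band = sps.sosfiltfilt(sos, raw)
        band /= np.std(band) + 1e-30  # unit RMS before windowing
        window = np.zeros(n)
        for (s1_on, s1_off, s2_on, s2_off, dia_end) in cycles:
            if cfg.murmur == "aortic_stenosis":
                # mid-systolic diamond over the central 70% of systole
                span = s2_on - s1_off
                window += _diamond_window(t, s1_off + 0.15 * span, s2_on - 0.15 * span)
            elif cfg.murmur == "mitral_regurgitation":
                window += _cos_ramp_window(t, s1_off, s2_on, ramp=0.01)
            else:  # mitral stenosis: rumble over the middle of diastole
                span = dia_end - s2_off
                window += _cos_ramp_window(
                    t, s2_off + 0.15 * span, dia_end - 0.25 * span, ramp=0.03
                )
        murmur = cfg.murmur_amplitude * band * np.clip(window, 0.0, 1.0)

    clean = transients + murmur
    p_clean = float(np.mean(clean**2))
    noise_std = np.sqrt(p_clean / 10.0 ** (cfg.snr_db / 10.0))
    noise = noise_std * rng.standard_normal(n)

    return {
        "transients": transients,
        "murmur": murmur,
        "noise": noise,
        "annotations": annotations,
        "cycle_starts": starts,
        "duration": duration,
        "config": cfg,
    }


def gen_record(cfg: SynthConfig, keep_components: bool = False) -> PCGRecord:
    """Generate one annotated PCG record (peak-normalised to 0.95)."""
    parts = gen_components(cfg)
    raw = parts["transients"] + parts["murmur"] + parts["noise"]
    peak = np.max(np.abs(raw))
    scale = 0.95 / peak if peak > 0 else 1.0
    samples = raw * scale
    comps = {}
    if keep_components:
        comps = {
            "clean": (parts["transients"] + parts["murmur"]) * scale,
            "noise": parts["noise"] * scale,
            "murmur": parts["murmur"] * scale,
            "transients": parts["transients"] * scale,
        }
    return PCGRecord(
        samples=samples,
        fs=cfg.fs,
        annotations=parts["annotations"],
        label=parts["config"].label,
        config=parts["config"],
        components=comps,
    )


def _class_config(base: SynthConfig, label: str) -> SynthConfig:
    if label == "S1S2_normal":
        return replace(base, murmur="none", include_s3=False, include_s4=False)
    if label == "S3S4":
        return replace(base, murmur="none", include_s3=True, include_s4=True)
    return replace(base, murmur=label, include_s3=False, include_s4=False)


def gen_dataset(
    base_cfg: SynthConfig,
    n_per_class: int,
    seed: int,
    classes: tuple = CLASS_NAMES,
    hr_range: tuple[float, float] = (55.0, 95.0),
    snr_range: tuple[float, float] = (15.0, 30.0),
) -> list[PCGRecord]:
    """Balanced synthetic dataset over the five heart-sound classes.

    Heart rate and SNR are resampled per record from physiological ranges;
    per-record seeds derive deterministically from the master ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    records = []
    for label in classes:
        for _ in range(n_per_class):
            hr = master.uniform(*hr_range)
            snr = master.uniform(*snr_range)
            child = int(master.integers(0, 2**31 - 1))
            cfg = replace(
                _class_config(base_cfg, label),
                heart_rate_bpm=hr,
                snr_db=snr,
                seed=child,
                systole_s=None,
                diastole_s=None,
            )
            records.append(gen_record(cfg))
    return records
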