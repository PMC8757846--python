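"""File formats: PCM16 mono WAV, annotation tables, feature tables, configs.

All on-disk formats are plain text or standard WAV so runs are easy to
inspect and diff.  Annotation dialect (tab-separated, one row per cycle):

    cycle_index  s1_on  s1_off  s2_on  s2_off  label

Feature tables are CSV with header ``F1..F6,label``.
"""

from __future__ import annotations

import dataclasses
import json
import wave
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import FEATURE_NAMES
from .synth import PCGRecord, SynthConfig

__all__ = [
    "read_wav",
    "write_wav",
    "write_annotations",
    "read_annotations",
    "write_record",
    "read_record",
    "write_feature_table",
    "read_feature_table",
    "load_run_config",
]


def write_wav(path, samples, fs: float) -> None:
    """Write mono 16-bit PCM; samples are clipped to [-1, 1]."""
    s = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    pcm = np.round(s * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(int(round(fs)))
        wf.writeframes(pcm.tobytes())


def read_wav(path):
    """Read mono 16-bit PCM WAV; returns (samples in [-1, 1], fs)."""
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1:
            raise ValueError(f"{path}: expected mono WAV, got {wf.getnchannels()} channels")
        if wf.getsampwidth() != 2:
            raise ValueError(f"{path}: expected 16-bit PCM, got {8 * wf.getsampwidth()}-bit")
        fs = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(float) / 32767.0
    return samples, float(fs)


def write_annotations(path, annotations, label: str) -> None:
    with open(path, "w") as fh:
        fh.write("cycle_index\ts1_on\ts1_off\ts2_on\ts2_off\tlabel\n")
        for i, (a, b, c, d) in enumerate(annotations):
            fh.write(f"{i}\t{a:.6f}\t{b:.6f}\t{c:.6f}\t{d:.6f}\t{label}\n")


def read_annotations(path):
    """Returns (annotations list, label)."""
    anns, label = [], None
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:5] != ["cycle_index", "s1_on", "s1_off", "s2_on", "s2_off"]:
            raise ValueError(f"{path}: unrecognised annotation header")
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 6:
                continue
            anns.append(tuple(float(v) for v in parts[1:5]))
            label = parts[5]
    return anns, label


def write_record(record: PCGRecord, wav_path, ann_path=None, config_path=None) -> None:
    """WAV + annotation table + (optional) config echo for one record."""
    write_wav(wav_path, record.samples, record.fs)
    if ann_path is not None:
        write_annotations(ann_path, record.annotations, record.label)
    if config_path is not None and record.config is not None:
        with open(config_path, "w") as fh:
            json.dump(dataclasses.asdict(record.config), fh, indent=1)


def read_record(wav_path, ann_path=None) -> PCGRecord:
    samples, fs = read_wav(wav_path)
    anns, label = ([], "unknown")
    if ann_path is not None and Path(ann_path).exists():
        anns, label = read_annotations(ann_path)
    return PCGRecord(samples=samples, fs=fs, annotations=anns, label=label or "unknown")


def write_feature_table(path, feature_rows, labels) -> None:
    df = pd.DataFrame(np.atleast_2d(feature_rows), columns=list(FEATURE_NAMES))
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in (*FEATURE_NAMES, "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return df


def load_run_config(path, cls=SynthConfig):
    """Load a dataclass config from JSON/YAML, rejecting unknown keys."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("murmur_band", "band", "env_band", "spec_band"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return cls(**doc)
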