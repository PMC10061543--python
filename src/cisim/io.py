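"""Small I/O helpers: WAV audio and JSON/CSV artifacts."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile


def load_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono WAV file as float in [-1, 1]; returns (audio, fs)."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(fs)


def save_wav(path, audio: np.ndarray, fs: float) -> None:
    """Write float audio as 16-bit PCM."""
    clipped = np.clip(audio, -1.0, 1.0)
    wavfile.write(path, int(fs), (clipped * 32767).astype(np.int16))


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))


def load_json(path):
    return json.loads(Path(path).read_text())
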