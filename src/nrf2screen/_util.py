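"""Shared helpers: seeded RNG streams, atomic file writes, checksums."""

from __future__ import annotations

import hashlib
import os
import tempfile
from pathlib import Path

import numpy as np

# Named sub-streams so every generator draws from its own deterministic
# stream derived from a single user-facing integer seed.
_STREAM_KEYS = {
    "cohort": 1,
    "screen": 2,
    "tma": 3,
    "qpcr": 4,
    "sensitization": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named sub-stream of ``seed``."""
    key = _STREAM_KEYS.get(stream)
    if key is None:
        raise KeyError(f"unknown RNG stream {stream!r}")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def atomic_write_text(path: str | Path, text: str) -> Path:
    """Write text to ``path`` via a temp file + rename so readers never see
    a partially written file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_dataframe(df, path: str | Path, sep: str = ",") -> Path:
    return atomic_write_text(path, df.to_csv(index=False, sep=sep))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
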