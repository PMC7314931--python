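"""Shared plumbing: seeding, hashing, atomic file writes."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np

logger = logging.getLogger("dfcnet")

_SEED_MOD = 2**31


def child_seed(master_seed: int, stream: int | str) -> int:
    """Derive an independent child seed from one master seed and a stream label.

    Counter-based: every module draws its randomness from
    ``child_seed(master, <its counter or name>)`` so stages can be re-run
    in isolation and still reproduce the full-pipeline draws.
    """
    if isinstance(stream, str):
        stream = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(master_seed) % _SEED_MOD, int(stream) % _SEED_MOD])
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def config_hash(mapping: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    payload = json.dumps(mapping, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename so readers never see
    a partially written file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
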