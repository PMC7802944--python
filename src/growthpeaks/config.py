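"""Flat key:value config files and atomic file output.

Configs are deliberately flat (``key: value`` or ``key=value``, one per line,
``#`` comments) so a run's resolved parameters stay auditable.  Values parse
to float when possible and stay strings otherwise.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

from .errors import FormatError

__all__ = ["read_config", "write_config", "atomic_write_text", "atomic_write_json"]


def read_config(path) -> dict:
    """Parse a flat key:value file."""
    config: dict = {}
    text = Path(path).read_text()
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise FormatError(f"{path}:{lineno}: expected 'key: value', got {raw_line!r}")
        key = key.strip()
        value = value.strip()
        if not key:
            raise FormatError(f"{path}:{lineno}: empty key")
        try:
            config[key] = float(value)
        except ValueError:
            config[key] = value
    return config


def atomic_write_text(path, text: str) -> None:
    """Write-then-rename so readers never see a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_config(config: dict, path) -> None:
    lines = [f"{key}: {value}" for key, value in config.items()]
    atomic_write_text(path, "\n".join(lines) + "\n")
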