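"""Flat run configuration: YAML file merged with command-line overrides.

Every subcommand resolves its parameters through :func:`load_config`:
values from ``--config file.yaml`` are overridden by explicit flags, the
fully-resolved mapping is echoed to the log for provenance, and unknown
keys are rejected by name.  A single global seed fans out to per-stage
seeds through a fixed counter scheme (stage index appended to the seed),
so each pipeline stage is reproducible in isolation.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)

#: Fixed per-stage offsets for fanning one global seed out to stages.
STAGE_OFFSETS = {
    "simulate": 1,
    "decoys": 2,
    "train": 3,
    "predict": 4,
    "benchmark": 5,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed: (global_seed * 8 + stage offset) mod 2^31."""
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(global_seed) * 8 + STAGE_OFFSETS[stage]) % (2**31)


def load_config(
    allowed: Mapping[str, type],
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Merge a flat YAML config with flag overrides.

    ``allowed`` maps permitted keys to their expected types.  File values
    are overridden by non-None entries of ``overrides``.  Unknown keys and
    type mismatches raise with the key named.  The resolved configuration
    is logged; loading that echo again yields the same mapping.
    """
    resolved: dict[str, Any] = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat key-value document")
        for key, value in loaded.items():
            if key not in allowed:
                raise ValueError(f"unknown config key {key!r} in {path}")
            resolved[key] = value
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in allowed:
            raise ValueError(f"unknown config key {key!r}")
        resolved[key] = value
    for key, value in resolved.items():
        expected = allowed[key]
        if expected is float and isinstance(value, int):
            value = float(value)
            resolved[key] = value
        if not isinstance(value, expected):
            raise ValueError(
                f"config key {key!r}: expected {expected.__name__}, "
                f"got {type(value).__name__} ({value!r})"
            )
    logger.info("resolved config: %s", resolved)
    return resolved


def atomic_write_text(text: str, path: str | Path) -> None:
    """Write via a temporary file and rename, so readers never see a partial file."""
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
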