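"""Run configuration: a flat ``key = value`` text dialect.

One option per line, ``#`` comments, booleans as true/false, and a
``row,col;row,col`` list syntax for pixel coordinates.  CLI flags override
file values.  Round-trips are lossless.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, fields
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of the edge/segment/inpaint drivers in one place."""

    c: float = 1.0
    delta_fraction: float = 0.5
    admissible_fraction: float = 0.5
    n_keypoints: int = 3
    alpha: float | None = None
    potential_smoothing: float = 0.0
    fill_mode: str = "dirichlet"
    restart: bool = False
    restarts: int = 0
    exclusion_radius: int = 3
    keypoints: list | None = None     # [(row, col), ...] manual seeds
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.delta_fraction <= 1):
            raise ValueError("delta_fraction must be in (0, 1]")
        if not (0 < self.admissible_fraction <= 1):
            raise ValueError("admissible_fraction must be in (0, 1]")
        if self.n_keypoints < 1:
            raise ValueError("n_keypoints must be at least 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.fill_mode not in ("dirichlet", "neumann"):
            raise ValueError("fill_mode must be dirichlet or neumann")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be nonnegative")


def _format(value):
    if value is None:
        return "none"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, list):
        return ";".join(f"{r},{c}" for r, c in value)
    return repr(value) if isinstance(value, float) else str(value)


def _parse(name, text, target_type):
    text = text.strip()
    if text == "none":
        return None
    if name == "keypoints":
        return [tuple(int(x) for x in pair.split(","))
                for pair in text.split(";") if pair]
    if target_type is bool:
        return text == "true"
    if target_type is int:
        return int(text)
    if target_type is float:
        return float(text)
    return text


_TYPES = {"c": float, "delta_fraction": float, "admissible_fraction": float,
          "n_keypoints": int, "alpha": float, "potential_smoothing": float,
          "fill_mode": str, "restart": bool, "restarts": int,
          "exclusion_radius": int, "keypoints": list, "seed": int}


def save_config(cfg: RunConfig, path):
    lines = [f"{f.name} = {_format(getattr(cfg, f.name))}"
             for f in fields(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> RunConfig:
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, text = (s.strip() for s in line.split("=", 1))
        if key not in _TYPES:
            raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
        values[key] = _parse(key, text, _TYPES[key])
    return RunConfig(**values)


def log_run(cfg: RunConfig):
    """Record config, seed and library versions for reproducibility."""
    import numpy
    import scipy
    import skimage
    logger.info("run config: %s", cfg)
    logger.info("python %s numpy %s scipy %s scikit-image %s",
                sys.version.split()[0], numpy.__version__,
                scipy.__version__, skimage.__version__)
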