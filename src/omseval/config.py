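"""Run configuration mirroring the reference engine's parameter block."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


@dataclass
class RunConfig:
    threshold: int = 7
    strategy: int = 1
    min_length: int = 7
    max_length: int = 30
    missed_cleavages: int = 0
    max_masses_count: int = 60  # fragments per spectrum; must be >= 2 * max_length
    minimum_score: int = 60  # carried for fidelity with the reference engine; inert here
    precision: float = 0.001  # Da, mass discretization step
    decoy_base: bool = True
    single_match: bool = True  # one best PSM per bait; the only supported mode
    fdr_alpha: float = 0.01
    decoy_tag: str = "DECOY_"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in (1, 2):
            raise ValueError("strategy must be 1 or 2")
        if not self.single_match:
            raise ValueError("single_match=false is not supported")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.max_masses_count < 2 * self.max_length:
            raise ValueError(
                "max_masses_count must be >= 2 * max_length "
                "(every peptide produces 2n fragments)"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a simple ``key = value`` config file; flags override it."""
        known = {f.name: f.type for f in fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


_BOOL_KEYS = {"decoy_base", "single_match"}
_FLOAT_KEYS = {"precision", "fdr_alpha"}
_STR_KEYS = {"decoy_tag"}


def _coerce(key: str, raw: str):
    if key in _STR_KEYS:
        return raw
    if key in _BOOL_KEYS:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key!r}: expected a boolean, got {raw!r}")
    if key in _FLOAT_KEYS:
        return float(raw)
    return int(raw)
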