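"""Run configuration (TOML).

A :class:`RunConfig` captures everything needed to reproduce a run: input
paths, per-module parameter overrides, the master seed, the output directory
and verbosity.  Unknown keys are rejected rather than silently ignored, and
the TOML serialization round-trips losslessly for the supported value types
(str, int, float, bool, flat lists thereof).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError

_KNOWN_KEYS = {"inputs", "params", "seed", "outdir", "verbosity"}


@dataclass
class RunConfig:
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."
    verbosity: int = 1

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise FormatError(f"seed must be an integer, got {self.seed!r}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            data = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as exc:
            raise FormatError(f"cannot parse {path} as TOML: {exc}") from exc
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise FormatError(
                f"{path}: unknown configuration key(s) {sorted(unknown)}; "
                f"known keys: {sorted(_KNOWN_KEYS)}"
            )
        return cls(**data)

    def to_toml(self, path) -> None:
        Path(path).write_text(self.dumps())

    def dumps(self) -> str:
        lines = [
            f"seed = {self.seed}",
            f'outdir = "{self.outdir}"',
            f"verbosity = {self.verbosity}",
            "",
            "[inputs]",
        ]
        lines += [f"{k} = {_fmt(v)}" for k, v in self.inputs.items()]
        lines += ["", "[params]"]
        lines += [f"{k} = {_fmt(v)}" for k, v in self.params.items()]
        return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    raise FormatError(f"unsupported config value type: {type(v).__name__}")
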