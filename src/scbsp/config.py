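"""Run configuration: every knob needed to reproduce a run, serializable to
a flat ``key = value`` file (TOML-compatible scalars)."""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .io import ValidationError

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    r1: float = 1.0
    r2: float = 3.0
    alpha: float = 0.05
    null_kind: str = "lognormal"  # lognormal | permutation
    n_perm: int = 1000
    neighbor_mode: str = "exact"  # exact | approximate
    recall_target: float = 0.99
    seed: int | None = None
    adjust: str = "none"  # none | bh
    weight_on_scaled: bool = False
    variance_denominator: str = "population"  # population | sample
    trim_top: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.r1 >= self.r2:
            raise ValidationError(
                f"r1 must be below r2 (got r1={self.r1}, r2={self.r2})"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.null_kind not in ("lognormal", "permutation"):
            raise ValidationError(f"unknown null kind {self.null_kind!r}")
        if self.neighbor_mode not in ("exact", "approximate"):
            raise ValidationError(f"unknown neighbor mode {self.neighbor_mode!r}")
        if self.adjust not in ("none", "bh"):
            raise ValidationError(f"unknown adjustment {self.adjust!r}")
        if self.variance_denominator not in ("population", "sample"):
            raise ValidationError(
                f"unknown variance denominator {self.variance_denominator!r}"
            )

    def to_file(self, path: str | Path) -> None:
        lines = []
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if value is None:
                continue
            if isinstance(value, bool):
                rendered = "true" if value else "false"
            elif isinstance(value, str):
                rendered = f'"{value}"'
            else:
                rendered = repr(value)
            lines.append(f"{field.name} = {rendered}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        valid = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise ValidationError(f"{path}:{lineno}: unknown option {key!r}")
            kwargs[key] = _parse_scalar(value)
        return cls(**kwargs)


def _parse_scalar(text: str):
    if text.startswith('"') and text.endswith('"'):
        return text[1:-1]
    if text in ("true", "false"):
        return text == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
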