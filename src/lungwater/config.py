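"""Run configuration: defaults, key=value file round-trip, flag overrides."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

from .errors import ValidationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide settings.

    diff_direction is fixed to reference_minus_test by design; it is recorded
    here for provenance, not as a switch.
    """

    hu_lower: float = -700.0
    hu_upper: float = 200.0
    ibw_rule: str = "devine"
    diff_direction: str = "reference_minus_test"
    alpha: float = 0.05
    power: float = 0.80
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValidationError("power must be in (0, 1)")
        if self.hu_lower >= self.hu_upper:
            raise ValidationError("hu_lower must be < hu_upper")
        if self.diff_direction != "reference_minus_test":
            raise ValidationError("diff_direction is fixed to 'reference_minus_test'")

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self


def save_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for f in fields(config):
        v = getattr(config, f.name)
        lines.append(f"{f.name}={v!r}" if isinstance(v, float) else f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text(encoding="utf-8")
    known = {f.name: f.type for f in fields(RunConfig)}
    kv: dict[str, object] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}: line {lineno} is not key=value: {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key not in known:
            raise ValidationError(f"{path}: unknown config key {key!r}")
        if key in ("hu_lower", "hu_upper", "alpha", "power"):
            kv[key] = float(value)
        elif key == "seed":
            kv[key] = int(value)
        else:
            kv[key] = value
    return RunConfig(**kv)
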