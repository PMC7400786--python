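"""Run configuration with published default thresholds (3 reads/family,
2 supporting families, alpha 0.05)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    min_family_reads: int = 3
    min_alt_families: int = 2
    alpha: float = 0.05
    stage_groups: dict[str, list[str]] = field(
        default_factory=lambda: {"I-II": ["I", "II"], "III-IV": ["III", "IV"]}
    )
    count_emergent: bool = False
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)
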