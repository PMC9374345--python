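"""Run configuration shared by the CLI subcommands.

Every field has a documented default; the config round-trips through YAML so
a run can be reproduced from its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    #: CSV species table (core_data dialect); None means simulate one
    species_table: str | None = None
    #: sparse presence-absence CSV (pixel_id, species_id); None means simulate
    presence_absence: str | None = None
    #: scenarios to run, subset of CR/EN/VU/NT (progressive order)
    scenarios: list[str] = field(default_factory=lambda: ["CR", "EN", "VU", "NT"])
    #: diel niches to analyse
    niches: list[str] = field(
        default_factory=lambda: ["nocturnal", "crepuscular", "cathemeral", "diurnal"]
    )
    #: KDE settings
    bandwidth: str = "plugin"  # or "normal_scale"
    grid_size: int = 151
    grid_expand: float = 0.1
    #: null model
    reps: int = 100
    seed: int = 0
    #: pixels with <= this many niche species are excluded from FD maps
    exclude_threshold: int = 5
    #: synthetic generator preset when no inputs are given
    synth_preset: str = "global_mammals"  # or "default"
    n_species: int | None = None
    out_dir: str = "dielfd_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)
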