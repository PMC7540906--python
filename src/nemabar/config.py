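"""Pipeline configuration: thresholds, distance model, bootstrap depth.

Defaults are the analysis constants the pipeline is built around: retain a
sample above 1,000 nematode-derived reads and 65% nematode relative
abundance; count minor SVs above a 7% floor; call alleles within 5 edits;
drop phyla under 1% after aggregation; Jukes-Cantor distances; 1,000
bootstrap replicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

DEFAULT_REGION_SETS: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3,), (4,), (1, 2), (3, 4), (2, 3, 4), (1, 2, 3, 4),
)


def region_set_name(regions: tuple[int, ...] | list[int]) -> str:
    return "R" + "_".join(str(r) for r in regions)


@dataclass
class PipelineConfig:
    min_reads: int = 1000
    min_nem_frac: float = 0.65
    minor_floor: float = 0.07
    max_allele_edits: int = 5
    phylum_min_frac: float = 0.01
    distance_model: str = "jc"
    bootstrap: int = 1000
    seed: int = 0
    experiment_code: str = "Z01"
    region_sets: tuple[tuple[int, ...], ...] = DEFAULT_REGION_SETS

    def __post_init__(self) -> None:
        if self.distance_model not in ("jc", "p"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if self.bootstrap < 0 or self.min_reads < 0:
            raise ValueError("bootstrap and min_reads must be non-negative")
        for name in ("min_nem_frac", "minor_floor", "phylum_min_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        self.region_sets = tuple(tuple(int(r) for r in rs)
                                 for rs in self.region_sets)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_INT_KEYS = {"min_reads", "max_allele_edits", "bootstrap", "seed"}
_FLOAT_KEYS = {"min_nem_frac", "minor_floor", "phylum_min_frac"}


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a plain-text ``key = value`` configuration file.

    Lines starting with ``#`` are comments; ``region_sets`` is written as
    comma-separated region-set names, e.g. ``R1,R2,R1_2_3_4``.
    """
    values: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in _INT_KEYS:
            values[key] = int(val)
        elif key in _FLOAT_KEYS:
            values[key] = float(val)
        elif key == "region_sets":
            values[key] = tuple(
                tuple(int(x) for x in name.lstrip("Rr").split("_"))
                for name in val.split(",") if name.strip()
            )
        else:
            values[key] = val
    values.update(overrides)
    return PipelineConfig(**values)
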