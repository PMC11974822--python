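"""Run configuration: defaults, TOML loading and persistence."""

from __future__ import annotations

import dataclasses
import os
import tomllib
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Resolved parameters for one analysis run.

    Defaults follow the standard workflow: 2 kb/min elongation, termination
    6.7x release, triptolide initiation fold change 0.25 with a 5% clamping
    offset, a 50 bp pause window searched over 200 bp (PRO-seq) or 300 bp
    (GRO-seq) downstream of the TSS, gene body from 500 bp past the pause
    window, and the 90th percentile of ranked pause sums as full occupancy
    for libraries without UMIs.
    """

    assay: str = "proseq"  # "proseq" | "groseq"
    has_umis: bool = False
    treatment_minutes: float | None = None
    k_elong: float = 2000.0  # bp/min
    r: float = 6.7  # k_pre / k_rel(control)
    target_fc_kinit: float = 0.25  # initiation-inhibitor anchor
    clamp_offset: float = 0.05
    search_len: int | None = None  # None -> 200 (proseq) / 300 (groseq)
    window: int = 50  # bp
    body_offset: int = 500  # bp from pause end to body start
    occupancy_percentile: float = 90.0
    min_pause_sum: float = 10.0  # raw counts summed over samples
    control_min_length: int | None = None  # controlGenes length cutoff, bp
    recompute_pause_window: bool = False  # else fixed from control
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("proseq", "groseq"):
            raise InvalidParameterError(f"unknown assay {self.assay!r}")
        if self.search_len is None:
            self.search_len = 200 if self.assay == "proseq" else 300
        if self.search_len < self.window:
            raise InvalidParameterError("search_len must be >= window")
        if self.k_elong <= 0 or self.r < 0:
            raise InvalidParameterError("k_elong must be > 0 and r >= 0")
        if not 0 < self.clamp_offset < 1:
            raise InvalidParameterError("clamp_offset must be in (0, 1)")
        if not 0 < self.occupancy_percentile <= 100:
            raise InvalidParameterError("occupancy_percentile outside (0, 100]")


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Read a TOML config file; keyword overrides win over file values."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | os.PathLike) -> None:
    """Persist the resolved configuration as TOML next to the outputs."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if value is None:
            continue
        if isinstance(value, bool):
            text = "true" if value else "false"
        elif isinstance(value, str):
            text = f'"{value}"'
        else:
            text = repr(value)
        lines.append(f"{f.name} = {text}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
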