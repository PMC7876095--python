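"""Locus geometry, origins, barriers and simulation parameters.

A *locus* is the simulated world: a binned genomic window containing
replication origins and programmed fork barriers.  Two barrier flavours are
modelled:

``restart``
    A polar barrier at which an arrested canonical fork collapses and is
    restarted by homologous recombination after a fixed delay.  The restarted
    fork synthesises both strands with Pol delta and, by default
    (``canonical_only=True``), is immune to further restart barriers.
``pause``
    A polar barrier (rDNA Ter-type) at which a fork stalls transiently and
    then resumes unchanged.

Coordinates are 0-based base pairs; bins are half-open
``[start + k*bin_size, start + (k+1)*bin_size)``.  Origin and barrier
positions are snapped to the nearest bin boundary at simulation time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

RIGHTWARD = "rightward"
LEFTWARD = "leftward"

DEFAULT_FORK_VELOCITY = 1.8  # kb/min
DEFAULT_BIN_SIZE = 300  # bp


class ConfigError(ValueError):
    """A locus/parameter configuration violates the documented schema."""


class RangeError(ConfigError):
    """A position lies outside the locus domain."""


@dataclass
class BinGrid:
    """Half-open binned window ``[start, end)`` with fixed bin size (bp)."""

    start: int
    end: int
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ConfigError(f"grid: end ({self.end}) must exceed start ({self.start})")
        if self.bin_size <= 0:
            raise ConfigError(f"grid: bin_size must be positive, got {self.bin_size}")
        if (self.end - self.start) % self.bin_size != 0:
            raise ConfigError(
                f"grid: span {self.end - self.start} is not a multiple of bin_size {self.bin_size}"
            )

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.bin_size

    def bin_starts(self) -> np.ndarray:
        """Left edge coordinate of every bin."""
        return self.start + np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def snap(self, position: float) -> float:
        """Snap a position to the nearest bin boundary."""
        k = round((position - self.start) / self.bin_size)
        return float(self.start + k * self.bin_size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (self.start, self.end, self.bin_size) == (other.start, other.end, other.bin_size)


@dataclass
class Origin:
    """A replication origin.

    ``efficiency`` is the probability that the origin is licensed/competent in
    a given cell; a competent origin fires at a time drawn from
    ``Normal(mean_firing_time, firing_time_sd)`` truncated at zero, unless it
    is passively replicated first.  Suppressed origins never fire.
    """

    position: float
    efficiency: float = 1.0
    mean_firing_time: float = 0.0  # minutes
    firing_time_sd: float = 0.0  # minutes
    suppressed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ConfigError(f"origin at {self.position}: efficiency {self.efficiency} not in [0, 1]")
        if self.mean_firing_time < 0:
            raise ConfigError(f"origin at {self.position}: mean_firing_time must be >= 0")
        if self.firing_time_sd < 0:
            raise ConfigError(f"origin at {self.position}: firing_time_sd must be >= 0")


@dataclass
class Barrier:
    """A polar replication fork barrier.

    Arrest applies only to forks travelling in ``blocks_direction`` and
    triggers independently with probability ``arrest_probability`` at each
    encounter.  ``restart`` barriers hold the fork for ``delay`` minutes and
    resume it as an HR-restarted (delta/delta) fork at
    ``position -/+ |restart_offset|`` (behind the fork, re-replicating the
    intervening bins); ``pause`` barriers resume the fork unchanged.

    ``restarted_fork_delay`` imposes a deterministic transit pause on
    already-restarted forks crossing this barrier in the blocked direction —
    the knob used to ask whether HR-restarted forks feel a downstream barrier.
    """

    position: float
    blocks_direction: str
    kind: str = "restart"
    arrest_probability: float = 1.0
    delay: float = 0.0  # minutes
    restart_offset: float = 0.0  # bp, <= 0: distance behind the barrier
    canonical_only: Union[bool, None] = None
    restart_velocity: Union[float, str] = "inherit"  # kb/min or "inherit"
    restarted_fork_delay: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if self.blocks_direction not in (RIGHTWARD, LEFTWARD):
            raise ConfigError(
                f"barrier at {self.position}: blocks_direction must be "
                f"'{RIGHTWARD}' or '{LEFTWARD}', got {self.blocks_direction!r}"
            )
        if self.kind not in ("restart", "pause"):
            raise ConfigError(f"barrier at {self.position}: kind must be 'restart' or 'pause'")
        if not 0.0 <= self.arrest_probability <= 1.0:
            raise ConfigError(
                f"barrier at {self.position}: arrest_probability "
                f"{self.arrest_probability} not in [0, 1]"
            )
        if self.delay < 0:
            raise ConfigError(f"barrier at {self.position}: delay must be >= 0")
        if self.restart_offset > 0:
            raise ConfigError(f"barrier at {self.position}: restart_offset must be <= 0")
        if self.kind == "pause" and self.restart_offset != 0:
            raise ConfigError(f"barrier at {self.position}: pause barriers require restart_offset = 0")
        if self.restarted_fork_delay < 0:
            raise ConfigError(f"barrier at {self.position}: restarted_fork_delay must be >= 0")
        if self.canonical_only is None:
            # restart barriers are invisible to HR-restarted forks by default
            self.canonical_only = self.kind == "restart"
        if self.restart_velocity != "inherit":
            if not isinstance(self.restart_velocity, (int, float)) or self.restart_velocity <= 0:
                raise ConfigError(
                    f"barrier at {self.position}: restart_velocity must be positive or 'inherit'"
                )


@dataclass
class SimulationParams:
    """Ensemble simulation parameters.

    ``fork_velocity`` is the canonical fork speed in kb/min (default 1.8).
    ``alpha_fraction`` is the fraction of canonical lagging-strand synthesis
    attributed to Pol alpha; HR-restarted forks use no Pol alpha.
    """

    fork_velocity: float = DEFAULT_FORK_VELOCITY  # kb/min
    n_cells: int = 1000
    master_seed: int = 0
    alpha_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.fork_velocity <= 0:
            raise ConfigError(f"fork_velocity must be positive, got {self.fork_velocity}")
        if self.n_cells < 1:
            raise ConfigError(f"n_cells must be >= 1, got {self.n_cells}")
        if not 0.0 <= self.alpha_fraction <= 1.0:
            raise ConfigError(f"alpha_fraction {self.alpha_fraction} not in [0, 1]")


@dataclass
class LocusConfig:
    """A locus: grid, origins and barriers."""

    grid: BinGrid
    origins: list[Origin] = field(default_factory=list)
    barriers: list[Barrier] = field(default_factory=list)
    name: str = "locus"

    def __post_init__(self) -> None:
        for o in self.origins:
            if not self.grid.start <= o.position <= self.grid.end:
                raise RangeError(
                    f"origin position {o.position} outside domain "
                    f"[{self.grid.start}, {self.grid.end}]"
                )
        for b in self.barriers:
            if not self.grid.start <= b.position <= self.grid.end:
                raise RangeError(
                    f"barrier position {b.position} outside domain "
                    f"[{self.grid.start}, {self.grid.end}]"
                )
        seen = set()
        for b in self.barriers:
            key = (b.position, b.blocks_direction)
            if key in seen:
                raise ConfigError(
                    f"duplicate barrier at {b.position} blocking {b.blocks_direction}"
                )
            seen.add(key)

    def copy(self) -> "LocusConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Config file I/O (YAML mapping; keys match the dataclass field names)
# ---------------------------------------------------------------------------

_GRID_KEYS = {"start", "end", "bin_size"}
_ORIGIN_KEYS = {"position", "efficiency", "mean_firing_time", "firing_time_sd", "suppressed"}
_BARRIER_KEYS = {
    "position", "blocks_direction", "kind", "arrest_probability", "delay",
    "restart_offset", "canonical_only", "restart_velocity", "restarted_fork_delay",
}
_PARAM_KEYS = {"fork_velocity", "n_cells", "master_seed", "alpha_fraction"}


def _check_keys(mapping: dict, allowed: set, required: set, context: str) -> None:
    unknown = set(mapping) - allowed
    missing = required - set(mapping)
    bad = []
    if unknown:
        bad.append(f"unknown keys {sorted(unknown)}")
    if missing:
        bad.append(f"missing keys {sorted(missing)}")
    if bad:
        raise ConfigError(f"{context}: " + "; ".join(bad))


def load_config(path: Union[str, Path]) -> tuple[LocusConfig, SimulationParams]:
    """Load and validate a locus config file; returns (locus, params).

    Omitted optional fields take their documented defaults (e.g. fork
    velocity 1.8 kb/min).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, {"name", "grid", "origins", "barriers", "simulation"}, {"grid"}, str(path))

    _check_keys(raw["grid"], _GRID_KEYS, {"start", "end"}, "grid")
    grid = BinGrid(**raw["grid"])
    origins = []
    for i, o in enumerate(raw.get("origins") or []):
        _check_keys(o, _ORIGIN_KEYS, {"position"}, f"origins[{i}]")
        origins.append(Origin(**o))
    barriers = []
    for i, b in enumerate(raw.get("barriers") or []):
        _check_keys(b, _BARRIER_KEYS, {"position", "blocks_direction"}, f"barriers[{i}]")
        barriers.append(Barrier(**b))
    config = LocusConfig(grid=grid, origins=origins, barriers=barriers,
                         name=raw.get("name", path.stem))
    sim = raw.get("simulation") or {}
    _check_keys(sim, _PARAM_KEYS, set(), "simulation")
    params = SimulationParams(**sim)
    return config, params


def write_config(config: LocusConfig, params: SimulationParams,
                 path: Union[str, Path]) -> None:
    """Write a locus + params back to the YAML schema (round-trips)."""
    doc = {
        "name": config.name,
        "grid": asdict(config.grid),
        "origins": [asdict(o) for o in config.origins],
        "barriers": [asdict(b) for b in config.barriers],
        "simulation": asdict(params),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Preset loci approximating the engineered constructs
# ---------------------------------------------------------------------------

def _flanked(grid: BinGrid, inner_origins: list[Origin]) -> list[Origin]:
    """Add efficient flanking origins outside the region of interest so every
    cell completes replication of the window."""
    flank = [
        Origin(position=grid.start + 1500, efficiency=0.95,
               mean_firing_time=8.0, firing_time_sd=3.0),
        Origin(position=grid.end - 1500, efficiency=0.95,
               mean_firing_time=8.0, firing_time_sd=3.0),
    ]
    return [flank[0]] + inner_origins + [flank[1]]


def preset_locus(name: str) -> LocusConfig:
    """Fixture loci approximating the engineered-construct geometries.

    ``rts1_rrfb``
        Efficient early origin; RTS1 restart barrier (blocks rightward forks)
        3 kb downstream; rRFB pause barrier 12 kb further (blocks the
        converging leftward fork); late origin 30 kb from the early origin.
    ``rts1_only``
        Same without the rRFB.
    ``tandem_rts1``
        rts1_rrfb plus a second, co-oriented RTS1 copy 1.8 kb downstream of
        the first.
    ``inverted_rts1``
        Two opposing RTS1 copies ~30 kb apart isolating an origin-free region
        replicated only by HR-restarted forks.
    ``rrfb_only``
        The rRFB calibration locus: a strong early origin, the rRFB pause
        site far downstream positioned so the paused converging fork usually
        resumes before the opposing fork arrives, and a later origin beyond
        it.  Used to estimate the rRFB pause duration from the termination
        shift it causes.

    Distances between elements follow the constructs; absolute coordinates are
    fixture choices.
    """
    grid = BinGrid(start=0, end=60_000, bin_size=DEFAULT_BIN_SIZE)
    early = Origin(position=12_000, efficiency=0.9, mean_firing_time=5.0, firing_time_sd=2.0)
    late = Origin(position=42_000, efficiency=0.7, mean_firing_time=15.0, firing_time_sd=3.0)
    rts1 = Barrier(position=15_000, blocks_direction=RIGHTWARD, kind="restart",
                   arrest_probability=0.7, delay=11.0)
    rrfb = Barrier(position=27_000, blocks_direction=LEFTWARD, kind="pause",
                   arrest_probability=1.0, delay=6.0)

    if name == "rts1_rrfb":
        return LocusConfig(grid=grid, origins=_flanked(grid, [early, late]),
                           barriers=[rts1, rrfb], name=name)
    if name == "rts1_only":
        return LocusConfig(grid=grid, origins=_flanked(grid, [early, late]),
                           barriers=[rts1], name=name)
    if name == "tandem_rts1":
        rts1_b = Barrier(position=16_800, blocks_direction=RIGHTWARD, kind="restart",
                         arrest_probability=0.7, delay=11.0)
        return LocusConfig(grid=grid, origins=_flanked(grid, [early, late]),
                           barriers=[rts1, rts1_b, rrfb], name=name)
    if name == "rrfb_only":
        strong = Origin(position=3_000, efficiency=0.95, mean_firing_time=1.0,
                        firing_time_sd=1.5)
        later = Origin(position=57_000, efficiency=0.95, mean_firing_time=10.0,
                       firing_time_sd=1.5)
        rrfb_cal = Barrier(position=45_000, blocks_direction=LEFTWARD, kind="pause",
                           arrest_probability=1.0, delay=6.0)
        return LocusConfig(grid=grid, origins=[strong, later],
                           barriers=[rrfb_cal], name=name)
    if name == "inverted_rts1":
        left = Barrier(position=15_000, blocks_direction=RIGHTWARD, kind="restart",
                       arrest_probability=0.9, delay=11.0)
        right = Barrier(position=45_000, blocks_direction=LEFTWARD, kind="restart",
                        arrest_probability=0.9, delay=11.0)
        right_origin = Origin(position=48_000, efficiency=0.9,
                              mean_firing_time=5.0, firing_time_sd=2.0)
        return LocusConfig(grid=grid, origins=_flanked(grid, [early, right_origin]),
                           barriers=[left, right], name=name)
    raise KeyError(f"unknown preset locus {name!r}; choose from "
                   "rts1_rrfb, rts1_only, tandem_rts1, inverted_rts1, rrfb_only")
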