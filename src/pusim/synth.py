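"""Synthetic Pu-seq count datasets from simulated replication profiles.

Counts for each strain x strand x bin are drawn independently as
``Poisson(depth * u + background)`` where ``u`` is that strain's usage
channel (delta strain <- usage_delta, epsilon strain <- usage_epsilon, alpha
strain <- the unscaled alpha fraction).  Poisson sampling is the simplest
model consistent with count data; overdispersion is a documented extension
hook, not implemented.

Scenario datasets reproduce the study conditions: loci from
:func:`pusim.locus.preset_locus` with barrier parameters at their fitted
values, plus a ``truth.json`` recording every generating parameter so the
dataset can be regenerated bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .locus import ConfigError, LocusConfig, SimulationParams, preset_locus
from .simulate import simulate_ensemble, STRANDS
from .traces import (PuSeqCounts, PuSeqTrace, profile_to_trace, write_counts,
                     ALPHA_OVERLAY_SCALE)


@dataclass
class NoiseModel:
    """Sequencing-noise stand-in: per-bin expected depth and stray background."""

    depth_per_strain: float = 100.0  # expected counts per bin per strand at usage 1
    background: float = 1.0  # expected stray counts per bin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_strain <= 0:
            raise ConfigError("depth_per_strain must be positive")
        if self.background < 0:
            raise ConfigError("background must be non-negative")


def generate_counts(trace: PuSeqTrace, noise: NoiseModel) -> PuSeqCounts:
    """Poisson-sample strain counts from an (unmasked) usage trace."""
    for strand in STRANDS:
        if trace.mask[strand].any():
            raise ConfigError("generate_counts requires an unmasked trace")
    rng = np.random.default_rng(noise.seed)
    lam, b = noise.depth_per_strain, noise.background
    counts = {}
    for strand in STRANDS:  # fixed draw order: strand-major, strain-minor
        channels = {
            "delta": trace.usage[(strand, "delta")],
            "epsilon": trace.usage[(strand, "epsilon")],
        }
        if strand in trace.alpha_overlay:
            channels["alpha"] = trace.alpha_overlay[strand] / ALPHA_OVERLAY_SCALE
        for strain, u in channels.items():
            counts[(strain, strand)] = rng.poisson(lam * u + b)
    # Library totals emulate genome-wide sequencing depth, which is equal
    # across strains by construction here.  Realized sums over the small
    # simulated window would instead reflect locus-specific usage (e.g. more
    # delta synthesis downstream of a restart barrier) and would bias the
    # usage ratio in a way genome-wide normalisation does not.
    n = trace.grid.n_bins
    totals = {k: (lam + b) * n for k in counts}
    return PuSeqCounts(grid=trace.grid, counts=counts, library_totals=totals)


_SCENARIOS = {
    # scenario -> (preset, {barrier overrides}, note)
    "rts1_rrfb_wt": ("rts1_rrfb",
                     {"restart": {"arrest_probability": 0.7, "delay": 11.0}},
                     "endogenous rtf1: ~70% arrest, 11 min restart delay"),
    "rts1_rrfb_adh": ("rts1_rrfb",
                      {"restart": {"arrest_probability": 0.9, "delay": 11.0}},
                      "adh1-driven rtf1: 90% arrest"),
    "rts1_rrfb_pku70d": ("rts1_rrfb",
                         {"restart": {"arrest_probability": 0.7, "delay": 14.0,
                                      "restart_offset": 0.0}},
                         "pku70 deletion: restart delayed to 14 min, same restart point"),
    "inverted": ("inverted_rts1", {}, "opposing RTS1 pair, origin-free 30 kb"),
    "tandem": ("tandem_rts1", {}, "two co-oriented RTS1 copies 1.8 kb apart"),
    "barrier_off": ("rts1_rrfb", {"all": {"arrest_probability": 0.0}},
                    "rtf1-d: no barrier activity anywhere"),
    "rrfb_calibration": ("rrfb_only", {},
                         "rRFB near a strong origin: 6 min pause, no RTS1"),
}


def scenario_config(scenario: str, overrides: Optional[dict] = None) -> LocusConfig:
    """Locus for a named scenario with its generating barrier parameters."""
    try:
        preset, barrier_overrides, _ = _SCENARIOS[scenario]
    except KeyError:
        raise KeyError(f"unknown scenario {scenario!r}; choose from "
                       f"{sorted(_SCENARIOS)}") from None
    cfg = preset_locus(preset)
    for b in cfg.barriers:
        for selector, fields in barrier_overrides.items():
            if selector == "all" or b.kind == selector:
                for k, v in fields.items():
                    setattr(b, k, v)
    for k, v in (overrides or {}).items():
        # overrides address barriers as "barrier<i>.<field>" or the grid as
        # "grid.bin_size" (e.g. finer bins for sub-bin questions such as
        # restart-point displacement detectability)
        if k.startswith("barrier"):
            idx_str, fld = k[len("barrier"):].split(".", 1)
            setattr(cfg.barriers[int(idx_str)], fld, v)
        elif k == "grid.bin_size":
            from .locus import BinGrid
            cfg = LocusConfig(grid=BinGrid(cfg.grid.start, cfg.grid.end, int(v)),
                              origins=cfg.origins, barriers=cfg.barriers,
                              name=cfg.name)
        else:
            raise ConfigError(f"unknown override {k!r}")
    return cfg


def make_scenario_dataset(scenario: str, out_dir: Union[str, Path],
                          depth: float = 100.0, background: float = 1.0,
                          seed: int = 0, n_cells: int = 1000,
                          params: Optional[SimulationParams] = None,
                          overrides: Optional[dict] = None) -> dict:
    """Simulate a scenario, Poisson-sample counts, write bedGraphs + truth.json.

    Returns ``{"paths": {...}, "truth": {...}}``.  The truth file records the
    full locus, simulation parameters and noise model, sufficient to
    regenerate the dataset bit-exactly.
    """
    cfg = scenario_config(scenario, overrides)
    if params is None:
        params = SimulationParams(n_cells=n_cells, master_seed=seed)
    profile = simulate_ensemble(cfg, params)
    trace = profile_to_trace(profile)
    noise = NoiseModel(depth_per_strain=depth, background=background, seed=seed + 1)
    counts = generate_counts(trace, noise)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_counts(counts, out_dir, chrom=cfg.name)
    with open(out_dir / "library_totals.json", "w") as fh:
        json.dump({f"{k[0]}_{k[1]}": v for k, v in counts.library_totals.items()},
                  fh, indent=2)

    truth = {
        "scenario": scenario,
        "locus": {
            "name": cfg.name,
            "grid": asdict(cfg.grid),
            "origins": [asdict(o) for o in cfg.origins],
            "barriers": [asdict(b) for b in cfg.barriers],
        },
        "simulation": asdict(params),
        "noise": asdict(noise),
        "note": _SCENARIOS[scenario][2],
    }
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"paths": {f"{k[0]}_{k[1]}": str(v) for k, v in paths.items()},
            "truth_path": str(truth_path), "truth": truth}
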