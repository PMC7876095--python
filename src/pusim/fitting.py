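"""Line-search estimation of barrier parameters against Pu-seq traces.

The model-data discrepancy is the Euclidean norm of the difference between
the (smoothed) predicted and observed usage channels over a region of
interest.  Each fit varies exactly one parameter over a pre-registered grid,
simulating an ensemble per grid value with common random numbers, and
validates the arg-min with a larger ensemble under a fresh seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .locus import LocusConfig, SimulationParams, preset_locus
from .simulate import simulate_ensemble
from .traces import (PuSeqTrace, profile_to_trace, smooth_trace,
                     DEFAULT_SG_WINDOW, DEFAULT_SG_POLYORDER)

PARAMETERS = ("delay", "arrest_probability", "restart_velocity",
              "restart_offset", "pause_delay", "second_barrier_delay")

DEFAULT_CHANNELS = (("delta", "watson"), ("delta", "crick"))


@dataclass
class FitSpec:
    """One line-search: which parameter, on which barrier, over which grid."""

    parameter: str
    target_barrier: int
    grid: Sequence[float]
    roi: tuple[float, float]
    channels: Sequence[tuple] = DEFAULT_CHANNELS
    n_cells: int = 1000
    validation_n_cells: int = 10_000
    master_seed: int = 0
    smoothing: Optional[tuple[int, int]] = (DEFAULT_SG_WINDOW, DEFAULT_SG_POLYORDER)

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        if self.roi[1] <= self.roi[0]:
            raise ValueError("roi must be a non-empty interval")


@dataclass
class FitResult:
    """Grid, objectives and arg-min of one line-search."""

    parameter: str
    grid: list
    objectives: list
    best_value: float
    best_objective: float
    validation_objective: Optional[float]
    tie: bool
    channels: list
    seed: int
    n_cells: int
    validation_n_cells: int

    def to_json(self, path=None) -> str:
        doc = {k: getattr(self, k) for k in
               ("parameter", "grid", "objectives", "best_value", "best_objective",
                "validation_objective", "tie", "seed", "n_cells", "validation_n_cells")}
        doc["channels"] = [list(c) for c in self.channels]
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def model_error(predicted: PuSeqTrace, observed: PuSeqTrace,
                roi: tuple[float, float],
                channels: Sequence[tuple] = DEFAULT_CHANNELS) -> float:
    """Euclidean norm of predicted - observed over roi bins x channels.

    Bins masked in the observed trace are excluded from both vectors.
    """
    if predicted.grid != observed.grid:
        raise ValueError("predicted and observed traces are on different grids")
    xs = predicted.grid.bin_starts().astype(float)
    sel = (xs >= roi[0]) & (xs <= roi[1])
    total = 0.0
    n_used = 0
    for pol, strand in channels:
        p = predicted.channel(pol, strand)[sel]
        o = observed.channel(pol, strand)[sel]
        ok = np.isfinite(o) & np.isfinite(p)
        total += float(np.sum((p[ok] - o[ok]) ** 2))
        n_used += int(ok.sum())
    if n_used == 0:
        raise ValueError("no unmasked observed bins in the region of interest")
    return float(np.sqrt(total))


def apply_parameter(config: LocusConfig, spec: FitSpec, value: float) -> LocusConfig:
    """Return a copy of the locus with one barrier parameter set to value."""
    out = config.copy()
    b = out.barriers[spec.target_barrier]
    p = spec.parameter
    if p in ("delay", "pause_delay"):
        b.delay = float(value)
    elif p == "arrest_probability":
        b.arrest_probability = float(value)
    elif p == "restart_velocity":
        b.restart_velocity = float(value)
    elif p == "restart_offset":
        # grids are magnitudes (bp behind the barrier); stored as <= 0
        b.restart_offset = -abs(float(value))
    elif p == "second_barrier_delay":
        b.restarted_fork_delay = float(value)
    return out


def _smoothed(trace: PuSeqTrace, channels, smoothing) -> PuSeqTrace:
    if smoothing is None:
        return trace
    window, polyorder = smoothing
    out = PuSeqTrace(grid=trace.grid,
                     usage={k: v.copy() for k, v in trace.usage.items()},
                     alpha_overlay={k: v.copy() for k, v in trace.alpha_overlay.items()},
                     mask={k: v.copy() for k, v in trace.mask.items()})
    for pol, strand in channels:
        if pol == "alpha":
            out.alpha_overlay[strand] = smooth_trace(out.alpha_overlay[strand], window, polyorder)
        else:
            out.usage[(strand, pol)] = smooth_trace(out.usage[(strand, pol)], window, polyorder)
    return out


def line_search(spec: FitSpec, config: LocusConfig, params: SimulationParams,
                observed: PuSeqTrace) -> FitResult:
    """Grid-evaluate the objective and return the arg-min plus validation.

    All grid points share ``spec.master_seed`` (common random numbers) so the
    objective differences reflect the parameter, not ensemble noise; the
    validation rerun at ``validation_n_cells`` uses a fresh seed.
    """
    obs_s = _smoothed(observed, spec.channels, spec.smoothing)
    objectives = []
    for value in spec.grid:
        cfg_v = apply_parameter(config, spec, value)
        params_v = replace(params, n_cells=spec.n_cells, master_seed=spec.master_seed)
        try:
            profile = simulate_ensemble(cfg_v, params_v)
        except Exception as exc:
            raise RuntimeError(f"simulation failed at {spec.parameter}={value}: {exc}") from exc
        pred = _smoothed(profile_to_trace(profile), spec.channels, spec.smoothing)
        objectives.append(model_error(pred, obs_s, spec.roi, spec.channels))
    objectives = np.asarray(objectives)
    best_idx = int(np.argmin(objectives))  # ties break toward the smallest value
    tie = bool(np.sum(objectives == objectives[best_idx]) > 1)
    best_value = float(spec.grid[best_idx])

    validation_objective = None
    if spec.validation_n_cells and spec.validation_n_cells > 0:
        fresh_seed = (spec.master_seed * 69069 + 12345) % (2 ** 31)
        cfg_best = apply_parameter(config, spec, best_value)
        params_val = replace(params, n_cells=spec.validation_n_cells, master_seed=fresh_seed)
        profile = simulate_ensemble(cfg_best, params_val)
        pred = _smoothed(profile_to_trace(profile), spec.channels, spec.smoothing)
        validation_objective = model_error(pred, obs_s, spec.roi, spec.channels)

    return FitResult(
        parameter=spec.parameter,
        grid=[float(v) for v in spec.grid],
        objectives=[float(o) for o in objectives],
        best_value=best_value,
        best_objective=float(objectives[best_idx]),
        validation_objective=validation_objective,
        tie=tie,
        channels=list(spec.channels),
        seed=spec.master_seed,
        n_cells=spec.n_cells,
        validation_n_cells=spec.validation_n_cells,
    )


# ---------------------------------------------------------------------------
# Pre-registered fitting scenarios
# ---------------------------------------------------------------------------

def _barrier_index(config: LocusConfig, kind: str, which: int = 0) -> int:
    idx = [i for i, b in enumerate(config.barriers) if b.kind == kind]
    return idx[which]


_ROI = (12_000.0, 40_000.0)  # transition + termination zone of the presets


def scenario_spec(scenario: str, master_seed: int = 0,
                  n_cells: int = 1000, validation_n_cells: int = 10_000
                  ) -> tuple[LocusConfig, FitSpec]:
    """Registered (locus, FitSpec) pairs for the study's fitting questions.

    ``rts1_delay``            restart delay at RTS1, 0-20 min step 1
    ``rts1_efficiency``       arrest probability at RTS1, 0-1 step 0.05
    ``rrfb_delay``            pause duration at the rRFB, 0-30 min step 1
    ``second_barrier_delay``  transit delay of restarted forks at a second
                              RTS1 copy (tandem locus), 0-30 min step 1
    ``pku70_delay``           restart delay refit for the pku70-deletion
                              dataset, 0-30 min step 1
    ``restart_offset``        restart point displacement behind RTS1,
                              0-1000 bp step 50
    """
    common = dict(n_cells=n_cells, validation_n_cells=validation_n_cells,
                  master_seed=master_seed, roi=_ROI)
    if scenario == "rts1_delay":
        cfg = preset_locus("rts1_rrfb")
        spec = FitSpec("delay", _barrier_index(cfg, "restart"),
                       np.arange(0.0, 21.0, 1.0), **common)
    elif scenario == "rts1_efficiency":
        cfg = preset_locus("rts1_rrfb")
        spec = FitSpec("arrest_probability", _barrier_index(cfg, "restart"),
                       np.arange(0.0, 1.0001, 0.05), **common)
    elif scenario == "rrfb_delay":
        # calibrated on the rRFB-only locus: at the RTS1 locus the paused
        # converging fork is usually rescued at the barrier, which makes the
        # objective insensitive to the pause duration
        cfg = preset_locus("rrfb_only")
        spec = FitSpec("pause_delay", _barrier_index(cfg, "pause"),
                       np.arange(0.0, 31.0, 1.0),
                       **{**common, "roi": (30_000.0, 55_000.0)})
    elif scenario == "second_barrier_delay":
        cfg = preset_locus("tandem_rts1")
        spec = FitSpec("second_barrier_delay", _barrier_index(cfg, "restart", 1),
                       np.arange(0.0, 31.0, 1.0), **common)
    elif scenario == "pku70_delay":
        cfg = preset_locus("rts1_rrfb")
        spec = FitSpec("delay", _barrier_index(cfg, "restart"),
                       np.arange(0.0, 31.0, 1.0), **common)
    elif scenario == "restart_offset":
        # 100 bp bins: a displacement smaller than a bin cannot move any
        # left-edge assignment, so 300 bp bins carry almost no offset signal
        from .locus import BinGrid
        cfg = preset_locus("rts1_rrfb")
        cfg = LocusConfig(grid=BinGrid(cfg.grid.start, cfg.grid.end, 100),
                          origins=cfg.origins, barriers=cfg.barriers,
                          name=cfg.name)
        spec = FitSpec("restart_offset", _barrier_index(cfg, "restart"),
                       np.arange(0.0, 1001.0, 50.0),
                       **{**common, "roi": (13_000.0, 27_000.0)})
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return cfg, spec


def scenario_fits(scenario: str, observed: PuSeqTrace,
                  params: Optional[SimulationParams] = None,
                  master_seed: int = 0, n_cells: int = 1000,
                  validation_n_cells: int = 10_000) -> FitResult:
    """Run one registered scenario fit against an observed trace."""
    cfg, spec = scenario_spec(scenario, master_seed=master_seed,
                              n_cells=n_cells, validation_n_cells=validation_n_cells)
    if observed.grid != cfg.grid:
        raise ValueError(
            f"observed trace grid does not match the {scenario} preset locus"
        )
    if params is None:
        params = SimulationParams()
    return line_search(spec, cfg, params, observed)
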