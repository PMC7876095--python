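"""Pu-seq count tracks and polymerase-usage traces.

Polymerase usage sequencing (Pu-seq) maps, per strand, the ribonucleotides
laid down by mutant Pol delta and Pol epsilon strains.  After library-size
normalisation the per-bin usage fraction of Pol delta on strand *s* is

    usage_delta(s) = d(s) / (d(s) + e(s)),     usage_epsilon = 1 - usage_delta

where *d*, *e* are the normalised delta- and epsilon-strain densities.  Pol
alpha incorporates far fewer ribonucleotides; its track is kept outside the
delta/epsilon closure and exported only as a x10 overlay, explicitly not to
scale, because the relative incorporation rates of the three polymerases are
unknown.

On-disk format: 4-column bedGraph (chrom, start, end, value), one file per
strain x strand (counts) or channel (traces); masked trace bins are written
as ``NA``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .locus import BinGrid, ConfigError
from .simulate import ReplicationProfile, WATSON, CRICK, STRANDS, _interp_crossing, TransitionNotFoundError

STRAINS = ("delta", "epsilon", "alpha")
ALPHA_OVERLAY_SCALE = 10.0  # presentational x10, as in published traces

DEFAULT_MIN_DEPTH = 10
DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLYORDER = 3


class TrackFormatError(ValueError):
    """A count/trace file does not tile the expected grid."""


@dataclass
class PuSeqCounts:
    """Binned strand-specific ribonucleotide counts per strain."""

    grid: BinGrid
    counts: dict  # (strain, strand) -> int array per bin
    library_totals: dict = field(default_factory=dict)  # (strain, strand) -> float

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        for key, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.shape != (n,):
                raise ConfigError(f"counts for {key} have shape {arr.shape}, expected ({n},)")
            if np.any(arr < 0):
                raise ConfigError(f"negative counts for {key}")
            self.counts[key] = arr.astype(np.int64)
        for key in self.counts:
            self.library_totals.setdefault(key, float(self.counts[key].sum()))

    def strains(self) -> set:
        return {strain for strain, _ in self.counts}


@dataclass
class PuSeqTrace:
    """Per-strand polymerase usage fractions on a grid.

    ``usage[(strand, 'delta')] + usage[(strand, 'epsilon')] == 1`` on every
    unmasked bin; ``alpha_overlay`` is the x10 not-to-scale alpha channel.
    """

    grid: BinGrid
    usage: dict  # (strand, 'delta'|'epsilon') -> float array
    alpha_overlay: dict = field(default_factory=dict)  # strand -> float array
    mask: dict = field(default_factory=dict)  # strand -> bool array (True = masked)

    def __post_init__(self) -> None:
        for s in STRANDS:
            if s not in self.mask:
                self.mask[s] = np.zeros(self.grid.n_bins, dtype=bool)

    def channel(self, pol: str, strand: str) -> np.ndarray:
        if pol == "alpha":
            return self.alpha_overlay[strand]
        return self.usage[(strand, pol)]


# ---------------------------------------------------------------------------
# Count file I/O
# ---------------------------------------------------------------------------

def _read_bedgraph(path: Union[str, Path], grid: BinGrid,
                   value_dtype=np.int64) -> tuple[np.ndarray, int, str]:
    """Read one 4-column bedGraph onto the grid.

    Returns (values, n_missing_bins, chrom). Intervals must tile the grid
    exactly (no overlaps, bin-sized); missing bins become 0/NaN.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         na_values=["NA"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    fill = 0 if value_dtype is np.int64 else np.nan
    out = np.full(grid.n_bins, fill, dtype=float)
    seen = np.zeros(grid.n_bins, dtype=bool)
    chroms = df["chrom"].dropna().unique()
    if len(chroms) > 1:
        raise TrackFormatError(f"{path}: multiple chromosomes {list(chroms)}")
    chrom = str(chroms[0]) if len(chroms) else ""
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        start, end = int(row.start), int(row.end)
        if end - start != grid.bin_size or (start - grid.start) % grid.bin_size != 0:
            raise TrackFormatError(
                f"{path}:{line_no}: interval [{start}, {end}) does not match the "
                f"{grid.bin_size} bp grid"
            )
        k = (start - grid.start) // grid.bin_size
        if not 0 <= k < grid.n_bins:
            raise TrackFormatError(f"{path}:{line_no}: interval outside the grid")
        if seen[k]:
            raise TrackFormatError(f"{path}:{line_no}: overlapping interval at {start}")
        seen[k] = True
        out[k] = row.value
    n_missing = int((~seen).sum())
    if value_dtype is np.int64:
        out = np.nan_to_num(out, nan=0.0).astype(np.int64)
    return out, n_missing, chrom


def read_counts(paths: Mapping[tuple, Union[str, Path]], grid: BinGrid,
                library_totals: Optional[Mapping] = None) -> PuSeqCounts:
    """Read per-(strain, strand) bedGraph count files onto one grid.

    ``paths`` maps ``(strain, strand)`` (e.g. ``("delta", "watson")``) to a
    file path.  Missing bins are stored as zero; a warning count is attached
    to the returned object as ``n_missing``.  ``library_totals`` supplies the
    per-track normalisation constants (e.g. genome-wide totals); when absent
    the realized sums over the window are used.
    """
    counts = {}
    chroms = set()
    n_missing = 0
    for (strain, strand), path in paths.items():
        if strain not in STRAINS or strand not in STRANDS:
            raise ConfigError(f"unknown strain/strand key ({strain}, {strand})")
        values, missing, chrom = _read_bedgraph(path, grid, np.int64)
        counts[(strain, strand)] = values
        n_missing += missing
        if chrom:
            chroms.add(chrom)
    if len(chroms) > 1:
        raise TrackFormatError(f"count files disagree on chromosome: {sorted(chroms)}")
    totals = dict(library_totals) if library_totals else {}
    result = PuSeqCounts(grid=grid, counts=counts, library_totals=totals)
    result.n_missing = n_missing  # informational
    return result


def load_count_dataset(in_dir: Union[str, Path], grid: BinGrid) -> PuSeqCounts:
    """Load a ``counts_<strain>_<strand>.bedgraph`` dataset directory.

    Picks up ``library_totals.json`` (written alongside synthetic datasets)
    when present.
    """
    in_dir = Path(in_dir)
    paths = {}
    for strain in STRAINS:
        for strand in STRANDS:
            p = in_dir / f"counts_{strain}_{strand}.bedgraph"
            if p.exists():
                paths[(strain, strand)] = p
    if not paths:
        raise FileNotFoundError(f"no counts_*_*.bedgraph files in {in_dir}")
    totals = None
    totals_path = in_dir / "library_totals.json"
    if totals_path.exists():
        with open(totals_path) as fh:
            raw = json.load(fh)
        totals = {tuple(k.split("_")): v for k, v in raw.items()}
    return read_counts(paths, grid, library_totals=totals)


def write_counts(counts: PuSeqCounts, out_dir: Union[str, Path],
                 chrom: str = "locus") -> dict:
    """Write one bedGraph per strain x strand; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    starts = counts.grid.bin_starts()
    ends = starts + counts.grid.bin_size
    paths = {}
    for (strain, strand), values in sorted(counts.counts.items()):
        path = out_dir / f"counts_{strain}_{strand}.bedgraph"
        pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                      "value": values}).to_csv(path, sep="\t", header=False, index=False)
        paths[(strain, strand)] = path
    return paths


# ---------------------------------------------------------------------------
# Usage computation
# ---------------------------------------------------------------------------

def compute_usage(counts: PuSeqCounts, min_depth: int = DEFAULT_MIN_DEPTH) -> PuSeqTrace:
    """Library-size-normalised polymerase usage per strand.

    Bins whose raw delta+epsilon depth is below ``min_depth`` are masked.
    The alpha overlay is ``10 * a / (d + e)`` of the normalised densities —
    approximately on the usage scale, explicitly not quantitative.
    """
    for strain in ("delta", "epsilon"):
        for strand in STRANDS:
            if (strain, strand) not in counts.counts:
                raise ConfigError(f"required strain track ({strain}, {strand}) absent")
    usage = {}
    alpha_overlay = {}
    mask = {}
    for strand in STRANDS:
        d_raw = counts.counts[("delta", strand)]
        e_raw = counts.counts[("epsilon", strand)]
        d_tot = counts.library_totals[("delta", strand)]
        e_tot = counts.library_totals[("epsilon", strand)]
        d = d_raw / d_tot if d_tot > 0 else d_raw.astype(float)
        e = e_raw / e_tot if e_tot > 0 else e_raw.astype(float)
        m = (d_raw + e_raw) < min_depth
        denom = d + e
        with np.errstate(invalid="ignore", divide="ignore"):
            u_d = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), np.nan)
        m |= ~np.isfinite(u_d)
        u_d = np.where(m, np.nan, u_d)
        usage[(strand, "delta")] = u_d
        usage[(strand, "epsilon")] = 1.0 - u_d
        mask[strand] = m
        if ("alpha", strand) in counts.counts:
            a_raw = counts.counts[("alpha", strand)]
            a_tot = counts.library_totals[("alpha", strand)]
            a = a_raw / a_tot if a_tot > 0 else a_raw.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                ov = ALPHA_OVERLAY_SCALE * np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), np.nan)
            alpha_overlay[strand] = np.where(m, np.nan, ov)
    return PuSeqTrace(grid=counts.grid, usage=usage,
                      alpha_overlay=alpha_overlay, mask=mask)


def smooth_trace(values: np.ndarray, window: int = DEFAULT_SG_WINDOW,
                 polyorder: int = DEFAULT_SG_POLYORDER) -> np.ndarray:
    """Savitzky-Golay smoothing; NaN bins are linearly interpolated before
    smoothing and restored to NaN after.  Edges use polynomial extension
    (scipy's ``interp`` mode), which keeps polynomials of degree <= polyorder
    exact across the whole series."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and greater than polyorder, got "
            f"window={window}, polyorder={polyorder}"
        )
    values = np.asarray(values, dtype=float)
    if len(values) < window:
        return values.copy()
    nan = ~np.isfinite(values)
    work = values.copy()
    if nan.any():
        if nan.all():
            return values.copy()
        idx = np.arange(len(values))
        work[nan] = np.interp(idx[nan], idx[~nan], values[~nan])
    out = savgol_filter(work, window_length=window, polyorder=polyorder, mode="interp")
    out[nan] = np.nan
    return out


def profile_to_trace(profile: ReplicationProfile) -> PuSeqTrace:
    """Project a simulated profile into Pu-seq trace space.

    Pol alpha is folded into the delta channel to keep the delta/epsilon
    closure (Pu-seq's delta mutant reports delta-only synthesis, but the
    two-strain ratio spans the full lagging strand); the alpha fraction is
    exported separately as the x10 overlay.
    """
    usage = {}
    alpha_overlay = {}
    for strand in STRANDS:
        eps = profile.usage[(strand, "epsilon")]
        delta = profile.usage[(strand, "delta")] + profile.usage[(strand, "alpha")]
        usage[(strand, "epsilon")] = eps.copy()
        usage[(strand, "delta")] = delta
        alpha_overlay[strand] = ALPHA_OVERLAY_SCALE * profile.usage[(strand, "alpha")]
    return PuSeqTrace(grid=profile.grid, usage=usage, alpha_overlay=alpha_overlay)


def estimate_transition_position(trace: PuSeqTrace, strand: str,
                                 window: tuple[float, float],
                                 min_amplitude: float = 0.1) -> float:
    """Interpolated position where Pol epsilon usage crosses the midpoint of
    its local range — the estimator of the polymerase-switch (restart) point.
    """
    xs = trace.grid.bin_starts().astype(float)
    sel = (xs >= window[0]) & (xs <= window[1])
    u = trace.usage[(strand, "epsilon")][sel]
    x = xs[sel]
    ok = np.isfinite(u)
    if ok.sum() < 2:
        raise TransitionNotFoundError("fewer than two unmasked bins in window")
    u, x = u[ok], x[ok]
    lo, hi = float(np.min(u)), float(np.max(u))
    if hi - lo < min_amplitude:
        raise TransitionNotFoundError(
            f"epsilon usage range {hi - lo:.3f} below {min_amplitude}: no transition"
        )
    return _interp_crossing(x, u, (hi + lo) / 2.0)


# ---------------------------------------------------------------------------
# Trace file I/O
# ---------------------------------------------------------------------------

def _trace_channels(trace: PuSeqTrace):
    for strand in STRANDS:
        for pol in ("delta", "epsilon"):
            yield f"usage_{pol}_{strand}", trace.usage[(strand, pol)]
    for strand, ov in sorted(trace.alpha_overlay.items()):
        yield f"alpha_overlay_{strand}", ov


def write_trace(trace: PuSeqTrace, out_dir: Union[str, Path],
                chrom: str = "locus") -> dict:
    """One bedGraph per channel; masked bins are written as NA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    starts = trace.grid.bin_starts()
    ends = starts + trace.grid.bin_size
    paths = {}
    for name, values in _trace_channels(trace):
        path = out_dir / f"{name}.bedgraph"
        col = pd.Series(values).map(lambda v: "NA" if not np.isfinite(v) else f"{v:.6g}")
        pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                      "value": col}).to_csv(path, sep="\t", header=False, index=False)
        paths[name] = path
    return paths


def read_trace(in_dir: Union[str, Path], grid: BinGrid) -> PuSeqTrace:
    """Inverse of :func:`write_trace` (round-trips, including NA masks)."""
    in_dir = Path(in_dir)
    usage = {}
    alpha_overlay = {}
    mask = {}
    for strand in STRANDS:
        for pol in ("delta", "epsilon"):
            path = in_dir / f"usage_{pol}_{strand}.bedgraph"
            values, _, _ = _read_bedgraph(path, grid, float)
            usage[(strand, pol)] = values
        mask[strand] = ~np.isfinite(usage[(strand, "delta")])
        ov_path = in_dir / f"alpha_overlay_{strand}.bedgraph"
        if ov_path.exists():
            alpha_overlay[strand], _, _ = _read_bedgraph(ov_path, grid, float)
    return PuSeqTrace(grid=grid, usage=usage, alpha_overlay=alpha_overlay, mask=mask)
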