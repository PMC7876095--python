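# Methods

## The model

`pusim` simulates S-phase replication of a single genomic window ("locus")
in many independent cells and aggregates the per-cell outcomes into the
per-bin fractions that polymerase usage sequencing (Pu-seq) measures.

Per cell:

1. **Origins.** Each unsuppressed origin is competent with probability equal
   to its efficiency. Competent origins draw a firing time from a normal
   distribution (mean, SD per origin) truncated at zero. An origin whose
   position has already been replicated when its firing time arrives never
   fires (passive replication). Cells in which no origin is competent are
   redrawn (counted; vanishingly rare with the preset flanking origins).
2. **Forks.** Firing spawns two diverging forks moving at the canonical
   velocity v = 1.8 kb/min. Two converging forks terminate where their
   trajectories meet; a fork reaching the domain edge stops.
3. **Barriers** are polar: they act only on forks moving in the blocked
   direction, arresting each arriving susceptible fork independently with
   probability p.
   * A **pause** barrier (rDNA Ter-type) holds the fork for D minutes and
     releases it unchanged.
   * A **restart** barrier (RTS1-type) holds the fork for D minutes and
     releases it as an HR-restarted fork, optionally displaced |offset| bp
     behind the barrier (re-replicating the interval; the displaced-interval
     bins are attributed to the restarted fork, which passes them later in
     time). Restarted forks synthesise both strands with Pol delta, use no
     Pol alpha, and by default (`canonical_only`) ignore further restart
     barriers. A `restarted_fork_delay` field can impose a transit pause on
     restarted forks at a barrier — the knob for asking whether restarted
     forks feel a second RTS1 copy.
   * An arrested fork reached by a converging fork before its release time
     is cancelled (rescue); the converging fork completes the interval.
4. **Strand bookkeeping.** A bin belongs to the fork that synthesised its
   left-edge coordinate last. Canonical rightward forks put Pol epsilon on
   Watson (leading) and Pol delta on Crick (lagging), with a configurable
   fraction `alpha_fraction` (default 0.1) of lagging synthesis attributed
   to Pol alpha priming; leftward forks mirror this; restarted forks are
   delta/delta with no alpha.

The engine is event-driven in continuous time (origin firings, barrier
arrivals, releases, collisions, edge arrivals processed chronologically), so
trajectories are exact under piecewise-constant velocities — there is no
timestep. A deliberately different fixed-timestep engine
(`simulate_cell_fixed_step`, dt = 0.001 min) implements the same rules by
sweeping and is used as an independent oracle: on random small loci the two
must agree bin-for-bin on direction and fork type and to within dt on times.

Ensembles default to 1000 cells, with 10,000-cell validation reruns for
fits. Per-cell RNG substreams are spawned from one master seed
(`numpy.random.SeedSequence`), so ensembles are reproducible and
order-independent.

## Pu-seq traces

Pu-seq compares ribonucleotide incorporation by mutant Pol delta and Pol
epsilon strains, per strand. After dividing each strain x strand track by
its library total, the Pol delta usage on strand s is d/(d+e); epsilon is
the complement. Bins with fewer than `min_depth` (default 10) raw counts are
masked; masked bins are linearly interpolated before Savitzky-Golay
smoothing (default window 9 bins, polyorder 3, polynomial edge handling) and
re-masked after. The Pol alpha channel stays outside the delta/epsilon
closure: the three polymerases' ribonucleotide incorporation rates are not
assumed comparable, so alpha is exported only as a x10 "not to scale"
overlay, computed from counts as 10·a/(d+e).

Simulated profiles are projected into the same space by
`profile_to_trace`; the small alpha fraction is folded into the delta
channel there, because the two-strain ratio spans the full lagging strand.

## Fitting

Model-data discrepancy is the Euclidean norm of the difference between
predicted and observed channels (default: Pol delta usage on both strands;
epsilon is redundant given the closure) over a region of interest, after
identical smoothing of both sides; masked observed bins are excluded. Each
fit is a one-dimensional line search over a pre-registered grid:

| scenario | parameter | grid |
|---|---|---|
| rts1_delay | restart delay at RTS1 | 0–20 min, step 1 |
| rts1_efficiency | arrest probability at RTS1 | 0–1, step 0.05 |
| rrfb_delay | pause duration at the rRFB | 0–30 min, step 1 |
| second_barrier_delay | transit delay of restarted forks at a 2nd RTS1 | 0–30 min, step 1 |
| pku70_delay | restart delay (pku70-deletion data) | 0–30 min, step 1 |
| restart_offset | restart displacement behind RTS1 | 0–1000 bp, step 50 |

All grid points share one master seed (common random numbers), so objective
differences across the grid reflect the parameter rather than ensemble
noise; the arg-min is then re-evaluated with a 10,000-cell ensemble under a
fresh seed. Ties break toward the smallest grid value and are flagged.

## Preset loci

The engineered constructs are shipped as fixtures. Inter-element distances
follow the constructs; absolute coordinates are fixture choices (the real
strains live on *S. pombe* chromosome II, whose coordinates are not
reproduced here). All presets use a 60 kb window with 300 bp bins and
efficient flanking origins just inside the window edges so every cell
finishes replication.

* `rts1_rrfb` — early efficient origin (12 kb; efficiency 0.9, fires ~5 min),
  RTS1 restart barrier 3 kb downstream (blocks rightward forks; defaults
  p = 0.7, D = 11 min), rRFB pause site 12 kb further (blocks leftward
  forks, 6 min), late origin 30 kb from the early one (efficiency 0.7,
  ~15 min).
* `rts1_only`, `tandem_rts1` (second RTS1 copy 1.8 kb downstream,
  co-oriented), `inverted_rts1` (opposing RTS1 copies 30 kb apart, no
  origins between).
* `rrfb_only` — the rRFB calibration geometry: a strong early origin, the
  pause site placed so the paused converging fork usually resumes before
  the opposing fork arrives (otherwise rescue at the barrier pins the
  termination position and makes the pause duration unidentifiable), and a
  later origin beyond it.

Origin firing-time parameters (means 1–15 min, SDs 1.5–3 min) are chosen to
reproduce the qualitative timing of an early/late transition zone: the
early origin's rightward fork always reaches RTS1 well before the late
origin's converging fork arrives, and the restarted fork travels ~5–15 kb
before merging.

## Synthetic count data

`generate_counts` draws each strain x strand x bin independently as
Poisson(depth · u + background), defaults depth = 100, background = 1 —
comparable to a well-covered Pu-seq locus. Library totals recorded with
synthetic datasets are the (equal) expected depths, emulating genome-wide
library-size normalisation; realized sums restricted to a small window
would instead encode locus-specific usage and bias the ratio. What the
generator does **not** emulate: mappability and GC bias, overdispersion
(negative-binomial noise is a documented extension hook), ribonucleotide
excision-repair leakage, and alignment artefacts. Passing recovery tests
therefore show the estimator chain is consistent under sampling noise, not
that it is robust to those real-data effects.

## Numerical choices

* Bins are 0-based and half-open; positions snap to the nearest bin
  boundary at simulation time; the window span must be a multiple of the
  bin size (default 300 bp — a typical Pu-seq analysis window).
* Bin ownership is decided at the bin's left edge; at exact time ties the
  rightward fork wins. Termination/transition positions are linear
  interpolations of the 0.5-crossing (direction fraction) or the local
  mid-range crossing (epsilon usage), on left-edge coordinates.
* Sub-bin questions (the 100 bp restart-displacement detectability) are run
  on 100 bp bins, since a displacement smaller than a bin cannot move any
  left-edge assignment.
* One arrest Bernoulli per fork per barrier encounter; a fork restarted at
  a barrier is past it and does not re-encounter it after the offset jump.
* Replication times recomputed through different trajectory segments agree
  only to float rounding (~1e-12 min); tests compare times at 1e-9.

## Problem sizes

The shipped tests and the acceptance script use 1000-cell ensembles
(10,000 for validation reruns and the delay-monotonicity check), depth 100,
20 replicate datasets for the recovery-error medians, and 100 random loci
for the engine-equivalence check; the full suite runs in a few minutes on
one core.

## Known limitations

* One velocity per fork class; no fork-speed heterogeneity along the locus
  beyond barriers.
* Origin firing is an independent truncated normal per origin; no
  replication-timing correlation structure or checkpoint feedback.
* The delta/epsilon closure ignores ligation-junction effects and assumes
  the two mutant strains report symmetrically.
* Parameters are fitted one at a time (as in the original analysis); no
  joint optimisation or uncertainty intervals.
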