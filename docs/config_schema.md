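# Locus configuration file schema

One YAML mapping per locus. Keys mirror the library's dataclass fields.

```yaml
name: my_locus            # optional label (default: file stem)
grid:                     # required
  start: 0                # bp, inclusive
  end: 60000              # bp, exclusive; (end - start) % bin_size == 0
  bin_size: 300           # bp, default 300
origins:                  # optional list
  - position: 12000       # bp, required; snapped to the nearest bin edge
    efficiency: 0.9       # firing probability per cell, default 1.0
    mean_firing_time: 5.0 # minutes, default 0
    firing_time_sd: 2.0   # minutes, default 0 (0 = deterministic)
    suppressed: false     # suppressed origins never fire
barriers:                 # optional list
  - position: 15000             # bp, required
    blocks_direction: rightward # rightward | leftward, required
    kind: restart               # restart | pause, default restart
    arrest_probability: 0.7     # per-encounter Bernoulli, default 1.0
    delay: 11.0                 # minutes held before release, default 0
    restart_offset: 0           # bp <= 0, restart this far behind the
                                # barrier (restart kind only)
    canonical_only: true        # restarted forks immune? default: true for
                                # restart barriers, false for pause barriers
    restart_velocity: inherit   # kb/min of the restarted fork, or "inherit"
    restarted_fork_delay: 0.0   # minutes: transit pause imposed on already-
                                # restarted forks crossing this barrier
simulation:               # optional
  fork_velocity: 1.8      # kb/min, default 1.8
  n_cells: 1000           # ensemble size, default 1000
  master_seed: 0
  alpha_fraction: 0.1     # Pol alpha share of canonical lagging synthesis
```

Validation errors name the offending keys; positions outside
`[start, end]` raise a range error. `pusim.locus.write_config` writes this
format back and round-trips.
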