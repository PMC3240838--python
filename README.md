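# turntaking

Evolutionary agent-based simulation of conflict strategies in stable animal
groups. Individuals repeatedly enter dyadic conflicts over a resource; each
decides to escalate with a dyad-specific, experience-updated willingness
`w`, escalated conflicts become sequential-assessment fights (noisy
perception of relative strength accumulated in a decision variable `d`,
concession when `d` exceeds a heritable giving-up threshold `T`), and
generations evolve the two heritable parameters — the update factor `U` and
`T` — under fitness-proportional selection, mutation and migration.

Two regimes emerge: a **contest** strategy (positive `U`, high `T`; stable
dominance relationships, long fights, linear hierarchies) and a cooperative
**turn-taking** strategy (strongly negative `U`, low `T`; alternating
resource acquisition, short fights, non-linear hierarchies), bistable at
small benefits with turn-taking disappearing at large benefits.

## Layout

| module                    | contents |
|---------------------------|----------|
| `turntaking.core`         | `Individual`, `SimulationConfig` (+ YAML/TOML loading, `paper`/`desk` presets), population initialization |
| `turntaking.fights`       | per-round costs, noisy perception, `run_fight` |
| `turntaking.conflicts`    | escalation decisions, willingness updates, `run_conflict` |
| `turntaking.evolution`    | conflict rounds, selection/mutation/migration, `run_simulation` (compiled array engine + transparent object engine) |
| `turntaking.metrics`      | directional consistency index, Landau linearity with randomization over tied/unknown dyads, fight-length stats, strategy classification |
| `turntaking.synthetic`    | synthetic interaction patterns (alternating / despotic / random) for metric validation |
| `turntaking.experiments`  | benefit x initial-U sweep, strategy-competition experiments, sensitivity sweeps |
| `turntaking.cli`          | `turntaking` command-line interface |

## CLI

```bash
# single run (scaled-down preset), outputs CSV + JSON metadata
turntaking simulate --preset desk --benefit 1 --u-init -1 --seed 1 --out runs/b1

# main analysis: benefits 1..10 x initial U in {-1, 1}, 10 replicates
turntaking sweep --preset desk --benefits 1:10 --replicates 10 --seed 1 --out runs/sweep

# competition between two fixed (U, T) strategies over all frequencies
turntaking compete --u-a -0.95 --t-a 0.05 --u-b 0.8 --t-b 1.6 \
    --benefit 1 --group-size 10 --n-groups 20000 --seed 1 --out runs/compete

# sensitivity sweep over one parameter
turntaking sensitivity --axis sigma_eps --values 0.5,2 --preset desk \
    --seed 1 --out runs/sens

# recompute metrics from an interaction log
turntaking metrics runs/log.csv --out runs/metrics.csv
```

The full-scale design is `--preset paper` (1000 groups, 5000 generations,
200-run sweep); expect hours of compute.

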