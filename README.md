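# preyevo

Artificial evolution of camouflage patterns on oval artificial prey.

`preyevo` implements a closed-loop genetic-algorithm framework for
predation experiments: pattern genomes are decoded and rendered as oval
targets, prey are laid out in trays, the order in which they are
attacked determines fitness ranks, and the last-attacked patterns of
each tray survive and reproduce (with a "rescue" rule protecting
previously top-ranked patterns from one unlucky early attack). A fully
synthetic test world — procedural gravel-like backgrounds and a
simulated observer that attacks prey by softmax over camouflage
metrics — lets every stage run at desk scale with no field data.

## Modules

| module | contents |
|---|---|
| `preyevo.colour_vision` | CIELAB/sRGB conversion, colour-space boxes, configurable linear receptor models, receptor-noise-limited (RNL) chromatic ΔS and achromatic ΔL distances |
| `preyevo.genome_pattern` | 20-gene pattern genomes, genotype→phenotype decoding, deterministic oval-target rendering, mutation and uniform crossover |
| `preyevo.camo_metrics` | mean-colour ΔS/ΔL, frequency-weighted colour difference, granularity pattern distance, Gabor-based edge disruption (GabRat-style ratio in [0,1]) |
| `preyevo.evolution_engine` | fitness ranks from attack order, survivor selection with the rescue rule, breeding, random-drift control mode, run persistence |
| `preyevo.field_io` | tray assignment with anti-clustering, slot/string-colour labelling, CSV manifests, attack-record parsing, print sheets |
| `preyevo.synthetic_world` | procedural smooth/furrowed backgrounds, simulated observer, the closed evolution loop, OLS + bootstrap trend reports |

## CLI

Field workflow (generation directories with `genomes.csv`, `targets/`,
`manifest.csv`, `ranks.csv`, `record.json`):

```bash
preyevo init   --config run.yaml --out rundir           # generation 0
preyevo record --run rundir --generation 0 --attacks attacks.csv
preyevo next   --run rundir --generation 0              # breed generation 1
```

Attack CSVs have columns `tray,prey,attack_index` (plus optional `day`);
`prey` may be a prey id, a slot number, or a string colour
(`red,green,blue,yellow` left to right).

Desk-scale simulation and analysis:

```bash
preyevo simulate --config run.yaml --seed 1 --mode ranked --out rundir
preyevo replay   --run rundir                   # byte-identical re-execution
preyevo metrics  --targets dir --background bg.png --out metrics.csv
preyevo trends   --metrics rundir/metrics.csv
```

`run.yaml` holds the `RunConfig` fields (population/group structure, the
CIELAB colour box, GA rates, selection mode, seed). Defaults follow the
standard set-up: 24 prey in six groups of four, trials truncated after
three attacks per group, colour box L ∈ [0,100], a ∈ [−50,50],
b ∈ [−10,70].

## Notes

* All randomness flows through seeded `numpy` generators; simulated runs
  replay byte-for-byte from their stored seeds.
* Rendering is a pure function of (genome, size); repeated renders are
  bit-identical PNGs.
* The default visual system is a self-contained stand-in (identity
  receptor matrix on linear sRGB, Weber fractions 0.05); real
  camera-to-receptor mappings can be supplied as JSON via
  `VisualSystem.from_json`.
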