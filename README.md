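# cardiobool

Asynchronous Boolean network analysis of heart-field-specific cardiomyocyte
differentiation: attractor analysis of three packaged cardiac gene
regulatory networks, in-silico knockout/overexpression validation,
Markov-chain simulation of differentiation efficiency in heterogeneous cell
populations, and a continuous network relaxation with an RA dose–response
sweep.

## What is in the box

| module | purpose |
| --- | --- |
| `cardiobool.logic` | Boolean expressions (`&`, `\|`, `!` dialect), networks, bit-packed states, synchronous/asynchronous update semantics, knockout/overexpression perturbations |
| `cardiobool.attractors` | exhaustive fixed-point scan, terminal-SCC attractor detection, reachability, state transition graphs |
| `cardiobool.models` | packaged `cm_subtype` (9 nodes), `heart_field` (11 nodes) and `unified` (21 nodes) networks with cell-type signatures and steady-state table validation |
| `cardiobool.perturb` | the knockout/overexpression battery (8 experiments x 4 signaling conditions) scored against literature expectations |
| `cardiobool.population` | uniform single-node-update Markov chains to absorption; per-condition cell-type counts and the expected-lineage fraction |
| `cardiobool.synth` | random initial populations, random Boolean networks, exact absorption-probability solver (oracle for the Monte-Carlo path) |
| `cardiobool.bne` | continuous relaxation (AND→product, OR→probabilistic sum, NOT→complement), closed-form steady states, RA sweep and the atrial/ventricular crossover threshold |
| `cardiobool.io` / `cardiobool.cli` | `.bnet` read/write, DOT/GraphML STG export, run manifests, command line |

Model definitions live as editable `.bnet` files plus JSON sidecars under
`src/cardiobool/models/data/`. The heart-field rule set is a constrained
reconstruction (see the sidecar provenance notes) and can be swapped out
without code changes.

## Command line

```sh
cardiobool attractors --model unified --clamp WNT=1 --clamp RA=0
cardiobool validate-tables --model heart_field
cardiobool perturb --battery builtin --out battery.csv
cardiobool perturb --ko NR2F2 --condition WNT=0,RA=1
cardiobool simulate --model unified --runs 100000 --seed 1 --out results/sim
cardiobool bne-sweep --gamma 1 --nu 1 --grid 101 --out sweep.csv --plot sweep.png
cardiobool export --model cm_subtype --bnet-out cm.bnet
```

Every file-writing run also emits a `manifest.json` (command, model
checksum, seed, parameters, package version) for reproducibility; identical
manifests give identical outputs.

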