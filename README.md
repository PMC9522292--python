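# topocoil

Spatially resolved stochastic simulation of transcription coupled to DNA
supercoiling in *E. coli*.

Translocating RNA polymerase does not rotate with the DNA helix, so it
overwinds the DNA ahead of it and underwinds the DNA behind it (the
twin-domain effect). The resulting torsional stress diffuses along the
DNA, is relaxed by topoisomerase I and gyrase, is confined by dynamically
forming topological domains — and feeds back on transcription itself:
negatively supercoiled promoters initiate faster, and torque or extreme
supercoiling stalls elongating polymerases. `topocoil` simulates this
mechanochemical feedback exactly, as a chemical master equation on a 1-D
lattice of 60-bp DNA segments sampled with the Gillespie algorithm, for
researchers studying supercoiling-mediated gene regulation, transcriptional
bursting and the coupling of neighbouring genes.

## Model in brief

Each segment `k` carries an integer number of linking-number units
(1 unit = 0.1 turn; a relaxed segment holds Lk₀ = 57), giving a local
supercoiling density σ(k) = (Turn(k) − Lk₀)/Lk₀. The reaction catalog:
biased down-gradient supercoil hops at k_drift = D/Δx²; topoisomerase
binding/unbinding/catalysis (topo I removes one negative unit at σ < 0,
gyrase converts +1 supercoil to −1, i.e. −2 units, at σ > 0); promoter
initiation at the piecewise-linear rate

    k_i(σ) = { k_min,                          σ ≥ 0
             { k_min + (k_max − k_min)·σ/σ*,   σ* < σ ≤ 0     (σ* = −0.06)
             { k_max,                          σ ≤ σ*

one-segment RNAP translocation (60 bp/s) that pushes the entered
segment's turns one segment further downstream; counterrotation
(supercoil transfer across the RNAP at k_rot = 0.2/s); termination, mRNA
decay; and stochastic looping/unlooping of domain barriers. After every
event each RNAP's flank densities are converted to torque by the
three-branch response

    τ(σ) = { c_s·ω₀·σ                     |σ| ≤ σ_s      (twist)
           { ±[2pg/(1 − p/c_s)]^½ / ω₀    σ_s < |σ| < σ_p (coexistence)
           { p·ω₀·σ                       |σ| ≥ σ_p      (plectonemic)

and the RNAP stalls when τ_down − τ_up ≥ 10.5 pN·nm or a flank crosses
σ = ±0.6. See `docs/methods.md` for all parameters and defaults.

Two samplers share the catalog: a Python reference engine (with an exact
CTMC oracle used to verify it) and a numba-compiled kernel (~1.5 M
events/s) used for ensembles.

## Worked example

Transcriptional noise of a 2.4-kb gene in a 4.2-kb domain, open versus
dynamically looping (5-min closed / 1-min open dwells):

```python
from topocoil.engine import RunControl, run_replicates
from topocoil.scenarios import looping_domain_scenario
from topocoil import observables as obs

for mode in ("open", "dynamic"):
    sc = looping_domain_scenario(k_max=0.1, loop_mode=mode)
    run = RunControl(t_end=2000.0, seed=0, n_replicates=40)
    trajs = run_replicates(sc.config, run, engine="fast")
    fano, mean = obs.ensemble_fano(trajs)
    print(f"{mode:8s} mean mRNA = {mean:5.2f}   Fano = {fano:4.2f}")
```

```
open     mean mRNA = 22.10   Fano = 0.74
dynamic  mean mRNA = 11.45   Fano = 2.96
```

On open DNA the strong promoter (k_max = 0.1/s) produces mRNA at a
near-Poissonian steady state (Fano ≈ 1; here slightly below because
promoter occlusion regularizes initiation). When the domain loops
dynamically, torsional stress accumulates while the loop is closed and
transcription restarts in bursts when it opens: the mean halves and the
Fano factor rises well above 1 — the topological domain acts as a noise
generator.

The same pattern of builders covers the 9-kb single-gene construct
(`single_gene_scenario`, RNAP cooperation via supercoil cancellation),
its promoter-shut-off variant, the two-gene orientation constructs
(`two_gene_scenario`) and the diffusion × topo-I-unbinding phase sweep
(`phase_sweep`).

A CLI wraps the same functionality:

```bash
topocoil scenario loop-domain --k-max 0.1 --loop-mode dynamic > loop.yaml
topocoil run --config loop.yaml --replicates 40 --seed 0 --out runs/loop
topocoil analyze --run-dir runs/loop
```

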