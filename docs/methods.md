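# Methods

## Model

`topocoil` simulates transcription on a linear DNA segment treated as a
1-D lattice of 60-bp segments, chosen so that one segment accommodates an
RNAP footprint (~32 bp) while staying below a gyrase site (~137 bp).
Torsional state is an integer number of *linking-number units* per
segment, one unit = 0.1 helical turn: a relaxed 60-bp segment carries
60/10.5 = 5.7 turns, i.e. `lk0 = 57` units, and the homeostatic
*E. coli* state sigma ≈ −0.05 corresponds to 54 units. Supercoiling
density of a segment is `sigma = (turn − lk0)/lk0`. Twist and writhe are
not distinguished; a single "turn" species captures both.

Every process is a continuous-time Markov jump reaction and the whole
system is sampled exactly (Gillespie direct method):

* **Supercoil drift.** Biased walk: one unit hops to a neighbouring
  segment only down-gradient and only if the destination is not occupied
  by a bound protein, at rate `k_drift = D/dx²` per active pair
  (dx = 60 bp × 0.34 nm/bp; D = 0.02 µm²/s gives ~48 s⁻¹). An explicit
  (gradient-blind) random-walk mode exists for comparison; its
  per-direction hop rate is the same expression, so a tagged unit's
  variance grows as 2Dt.
* **Boundary relaxation.** An open domain end is reset to the chromosomal
  set point (53 units, sigma = −0.067) at 50 s⁻¹, modelling torsional
  exchange with the unmodelled rest of the chromosome. This is the only
  non-conservative channel besides topoisomerase catalysis, and both book
  their linking-number deltas so trajectories can be audited exactly.
* **Topoisomerases.** Pseudo-first-order binding per free segment
  (0.0018 s⁻¹·segment⁻¹ for both enzymes, derived from ~300 bound gyrases
  on 4 Mb with 2-s dwells, with a 0.8 correction for the deterministic
  approximation), unbinding (gyrase 0.5 s⁻¹; topo I default 1 s⁻¹, a free
  parameter of the phase diagram), and supercoiling-sensitive catalysis.
  A bound enzyme occupies its segment and blocks drift into it and RNAP
  passage. Topo I adds +1 unit per event and acts only at sigma < 0;
  gyrase adds −2 (one positive supercoil converted to one negative) and
  acts only at sigma > 0; events that would overshoot past relaxation are
  suppressed.
* **Initiation.** `k_i(sigma)` is piecewise linear in the promoter
  (TSS-segment) supercoiling density: `k_min` (default 0.001 s⁻¹) at
  sigma ≥ 0, rising to `k_max` at the critical density sigma* = −0.06 and
  saturating below it. Initiation requires the TSS and its immediate
  downstream segment to be free; the loading RNAP melts the TSS segment
  and displaces its units one segment downstream.
* **Elongation.** A processive RNAP steps one segment per second
  (60 bp/s) when the next *two* segments are free (the collision rule),
  pushing the entered segment's units onto the segment beyond — the
  twin-domain bookkeeping: a growing positive pile rides ahead, and the
  vacated, newly re-annealed DNA behind carries zero units (a local
  negative-supercoil deficit dispersed by drift). Counterrotation of the
  RNAP–mRNA complex transfers one unit across the polymerase
  down-gradient at `k_rot = 0.2 s⁻¹`.
* **Stalling.** After *every* event each RNAP's mode is re-evaluated from
  the supercoiling density at the nearest unoccupied segment on each
  side. Flank densities map to torque through the three-branch response
  (linear twist regime, constant coexistence torque
  `[2pg/(1 − p/c_s)]^{1/2}/omega0`, linear plectonemic regime), and the
  RNAP stalls when the net resisting torque (downstream minus upstream)
  reaches 10.5 pN·nm, or when an extreme flank is reached (upstream
  sigma ≤ −0.6, R-loop proxy; downstream sigma ≥ +0.6, unmeltable
  duplex). The threshold is one-sided — assisting torque never stalls —
  with a two-sided option in config.
* **Termination and decay.** On the gene's final segment the next firing
  releases the RNAP and credits one mRNA; mRNAs decay first-order at
  0.003 s⁻¹ (~5-min lifetime, typical for lacZ-class transcripts; config).
* **Topological domains.** A barrier pair loops (0.017 s⁻¹) and unloops
  (0.003 s⁻¹) the intervening DNA, atomically occupying/freeing both
  anchor sites; a looped domain confines supercoil diffusion. Dynamic
  barriers start looped (the stationary state is 85% looped); a
  `permanent` mode is the always-closed control.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| segment | 60 | bp | footprint compromise (see above) |
| lk0 | 57 | units/segment | 10.5 bp/turn, 0.1-turn units |
| initial turns | 54 | units/segment | sigma ≈ −0.05 homeostasis |
| D | 0.02 | µm²/s | writhe-diffusion measurements; swept 0.002–2 |
| boundary reset | 50 (to 53 units) | s⁻¹ | "every 0.02 s" to sigma = −0.067 |
| k_bind (both enzymes) | 0.0018 | s⁻¹·segment⁻¹ | single-particle tracking arithmetic |
| gyrase k_unbind | 0.5 | s⁻¹ | 2-s dwell |
| topo I k_unbind | 1.0 | s⁻¹ | free parameter; swept 0.001–100 |
| kcat_max | 600 | events·s⁻¹ | calibrated, see below |
| sigma_half | 0.05 | – | k_cat saturates at homeostatic stress |
| k_min, sigma* | 0.001, −0.06 | s⁻¹, – | initiation response |
| k_max | ≤ 0.2 | s⁻¹ | promoter strength, swept |
| k_elong | 60 | bp/s | constant NTP incorporation |
| k_rot | 0.2 | s⁻¹ | counterrotation, free parameter |
| stall torque | 10.5 | pN·nm | single-molecule stall measurements |
| sigma_stall | ±0.6 | – | extreme-density arrest proxy |
| c_s·omega0, p·omega0 | 200, 50 | pN·nm | torque response slopes (config) |
| g | 2.0036 | pN | sets coexistence torque tau0 = 7.0 pN·nm |
| mRNA decay | 0.003 | s⁻¹ | ~5-min lifetime |
| k_loop, k_unloop | 0.017, 0.003 | s⁻¹ | 1-min open / 5-min closed dwells |

**Torque-response defaults.** The three-branch parameters are exposed in
config and validated for branch continuity at construction (sigma_s and
sigma_p are derived from continuity when not given). The defaults were
chosen so that the coexistence torque tau0 = 7.0 pN·nm satisfies
tau0 < 10.5 < 2·tau0: one-sided torsional stress alone cannot stall an
RNAP, but the symmetric twin-domain situation (positive plectonemic
stress ahead *and* negative behind) does — precisely the asymmetry that
lets supercoil cancellation between co-transcribing RNAPs rescue
elongation. A candidate with tau0 = 5.5 pN·nm behaved indistinguishably
on the calibration features and was not adopted.

**k_cat calibration.** The catalytic response to supercoiling is a
configurable saturating-linear curve `kcat_max·min(|sigma|/sigma_half, 1)`
standing in for an assay-derived parameterization. Because binding is a
sparse pseudo-first-order visit process (a given segment is visited about
once per 10 minutes), `kcat_max` is an *effective per-visit* processivity,
not a single-turnover rate: 600 events/s over a ~1–2 s dwell removes up
to a few tens of turns per visit. The default was fixed once, by the
scripted sweep in `scripts/calibrate.py`, to the smallest decade at which
the single-gene construct shows the expected cooperation signature (the
empirical elongation rate rising with initiation rate to a plateau, with
adjacent-RNAP spacing near 500 bp at the plateau onset) while the open
4.2-kb construct transcribes Poissonian (Fano ≈ 1) and a dynamically
looping domain still accumulates enough unresolved stress to burst
(Fano ≫ 1). Weaker catalysis (kcat_max ≤ 100) lets intergenic
supercoiling in the two-gene construct saturate at the ±0.6 stall
threshold and over-suppresses elongation there.

## Simulation engines

Two samplers share one reaction semantics. The *reference engine*
(`topocoil.engine.run_ssa`) executes `ReactionChannel` objects with either
naive full-recompute or dependency-graph propensity updates; it also
powers the exact CTMC oracle (`ctmc_transient_oracle`), which enumerates
the reachable state space of a small system by BFS over the same channels
and exponentiates the generator. The *production kernel*
(`topocoil.fastsim.run_fast`, numba) implements the identical catalog on
flat arrays with block partial sums, localized propensity refreshes
(supercoil hops dominate the event stream ~10³:1 over everything else),
cached RNAP flank segments invalidated on occupancy changes, and a
periodic full recomputation that cancels floating-point drift in the
running sums. The test suite cross-validates the two distributionally
(state laws, initiation counts, loop occupancy) and audits the kernel's
per-frame linking-number ledger exactly. Throughput is roughly 1.5×10⁶
events/s on one core; a 1000-s single-gene replicate at the strongest
promoter is ~3×10⁶ events.

Randomness: replicate *i* of a condition uses seed `base + i`; the kernel
seeds numba's internal generator, the reference engine a PCG64 stream.
Same (config, seed, engine) → bit-identical trajectories.

Frames are recorded at 1-s cadence (config) using the state as of the
frame time; the macro event log keeps transcription-level events
(initiation with promoter sigma, termination and report-window crossing
with durations, loop toggles, promoter shut-off, optionally completed
stall episodes). Micro events are only logged by the reference engine on
demand. Stall episodes still open at the end of a run are censored and
excluded from duration statistics.

## What the scenarios emulate — and what they do not

The three constructs reproduce the study conditions: a 5.1-kb
lacZYA-like unit scored on its first 3,075 bp in a 9-kb relaxing domain;
a 2.4-kb gene in a 4.2-kb domain loopable at 0.06/4.14 kb; two 1.2-kb
genes around a 1.2-kb gap in 9.6 kb. They are synthetic idealizations:
constant elongation attempt rate (no sequence-dependent pausing),
initiation lumped into a single supercoiling-sensitive event, no
ribosome/R-loop chemistry beyond the sigma threshold proxy, no
replication, no 3-D geometry, no twist/writhe partition or plectoneme
hopping, and no length-dependent RNAP rotational drag. Passing tests
therefore demonstrate the mechanochemical feedback logic, not
base-pair-resolution realism.

Known quantitative limitation: the literal push rule (vacated segments
re-anneal with zero units) makes a freshly advanced RNAP wait for
up-gradient refill of its trailing segment, capping the realized
elongation plateau near ~22 bp/s rather than the 60 bp/s attempt rate.
Spacing between co-transcribing RNAPs at the cooperation plateau onset
(~470 bp) matches the expected ~500 bp, but the co-transcribing load at
that point (~5.5 within the scored window) runs ~30–40% above the ~4
expected from faster-moving polymerases; the discrepancy scales with
1/elongation and is documented in the acceptance results rather than
hidden by re-tuning.

## Analysis definitions

Empirical initiation rate: initiation events per unit time in the
750 s → end analysis window (the mRNA pool is stationary past ~750 s),
averaged over replicates. Empirical elongation rate: per-transcript
scored length over duration — report-window crossing for the lacZ proxy,
full length otherwise — for transcripts completing in the window.
Fano factor: variance/mean (ddof = 1) of per-replicate mRNA counts
snapshotted at the final frame (a pooled-frames variant is available).
Adjacent-RNAP correlation uses 1-s position increments of genomically
adjacent pairs pooled over co-transcription overlap; its normalization
anchors are cross-replicate pairing (independence, "0") and the
highest-expression condition of the same sweep ("1"). Spacing and load
are per-frame statistics over frames with at least one RNAP present,
restricted to the scored window when the gene declares one. The
cooperativity fit is a continuous hinge `y = k·min(x, x*) + b` with the
breakpoint grid-searched over the observed x-range and refined by
bounded minimization; it is skipped (flagged) when the condition never
reaches an empirical initiation rate of 0.05 s⁻¹. Loop-conditioned
initiation rates partition events and exposure time by the reconstructed
loop intervals.

## Problem sizes

Unit and property tests run on 3–30-segment systems in seconds. The
acceptance script uses desk-scale ensembles chosen to keep each condition
in the minutes range on one core: 30 replicates × 1000 s per promoter
strength for the cooperation sweep (6 strengths), 100 replicates × 2000 s
per promoter for the open-DNA noise conditions, and 40 replicates ×
2000 s per endpoint for the divergent two-gene construct. The acceptance
test suite uses the same scenarios at further reduced replicate counts
with correspondingly coarse assertions.
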