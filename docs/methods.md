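# Methods

## The conformational-equilibrium binding model

A pre-translocation ribosome interconverts between a high-FRET Classical
tRNA configuration and low-FRET Hybrid configurations. An E-site binder
blocks entry of the P-site tRNA 3′-CCA end and so shifts this equilibrium
toward Classical. With drug binding treated as pre-equilibrated, four
species contribute: Classical, Hybrid, Classical·I and Hybrid·I, with
Boltzmann weights 1, K_0, x and x/K_2 where x = [I]/K_I. The classical
fraction is therefore

    f_c([I]) = (1 + x) / (1 + K_0 + x (1 + 1/K_2)),   x = [I]/K_I

with limits f_c(0) = 1/(1+K_0) and f_c(∞) = 1/(1+1/K_2). f_c is monotone in
[I] with the sign of K_0 − 1/K_2. `equilibrium_occupancy` implements this
single expression; the titration fit and the simulator both delegate to it,
and a property test checks it against the explicit partition function.

Parameters and units:

| parameter | meaning | default (simulation) |
|---|---|---|
| K_I | drug dissociation constant, μM | per-drug (published values in studies) |
| K_0 | classical→hybrid equilibrium, drug-free | 4 (f_c(0) = 0.2) |
| K_2 | classical→hybrid equilibrium, drug-bound | 10 (plateau ≈ 0.91) |

K_0 and K_2 are not published; 4 and 10 are this package's synthetic
choices, set once so the drug-free state strongly favours hybrid and the
titration plateaus below unity, as observed. They are defaults of the
simulation studies, not claims about the measured systems.

## What the synthetic-data generator emulates

* **Hidden dynamics.** A three-state discrete-time Markov chain
  (Classical, Hybrid-1, Hybrid-2). The thermodynamic model only
  distinguishes classical vs hybrid; total hybrid occupancy is split
  between Hybrid-2 and Hybrid-1 by `hybrid_split` (yeast 0.6 toward
  Hybrid-2, human 0.4, reflecting the species' observed preferences).
  The chain uses an independence-sampler construction (redraw from the
  stationary law with probability frame_dt/mean_dwell per frame), which
  satisfies detailed balance, so long-run occupancies equal the model
  equilibrium exactly. Dwell kinetics are not published; the default mean
  dwell is 0.5 s (12.5 frames at 40 ms), configurable. Only equilibrium
  occupancies matter downstream.
* **Emissions.** Per live frame, FRET efficiency is drawn from the state's
  Gaussian (published means/SDs); donor = T(1−E) + noise and
  acceptor = T·E + noise with constant expected total intensity T.
* **Photophysics.** Exponential photobleach lifetime truncates the state
  path; donor blinks arrive as a Poisson process and zero both channels;
  channel noise is additive Gaussian. Chosen constants (invented, one-time):
  T = 800 photons/frame, shot noise 30/channel, background SD 15, bleach
  lifetime 12 s, blink rate 0.05 s⁻¹, blink duration 0.2 s, 750 frames at
  40 ms. These give signal/background ≈ 38 and signal/signal ≈ 14, so QC
  failures are dominated by genuinely short-lived or never-bleaching
  traces (as in real recordings), not by noise thresholds.
* **Reproducibility.** One master seed; `numpy.random.SeedSequence` spawns
  one child per concentration and one grandchild per trace.

Not emulated: camera gain/EM-CCD statistics, spectral crosstalk and gamma
correction, acceptor photophysics, stage drift, and any binding kinetics
(association is treated as equilibrated before acquisition). A green
recovery test therefore establishes that the analysis chain is unbiased
under the stated generative model — not that it is robust to instrument
systematics the model omits.

## Trace QC conventions

The selection criteria leave several quantities undefined; the package's
conventions (all configurable):

* signal/background-noise = mean pre-bleach total intensity / SD of the
  post-bleach total; signal/signal-noise = the same mean / SD of the
  pre-bleach total with blink frames excluded.
* The donor–acceptor correlation is computed on raw pre-bleach intensities
  (a moving-average-detrended mode exists; raw is the default).
* The ≥ 50-frame lifetime counts pre-bleach frames whose raw frame-wise
  FRET is ≥ 0.15 (idealization happens downstream).
* A blink is a pre-bleach interval (≥ 1 frame) at background in both
  channels followed by recovery.
* Photobleach detection: the background level is the lowest sustained
  intensity level (rolling median); the bleach frame is the start of the
  trailing background run; bleach steps are mean-shift-scan drops
  exceeding k·background_SD (k = 4, window 5) that never recover above the
  step midpoint — so blinks are never counted as partial bleaches, while a
  two-fluorophore staircase counts 2 and is rejected.

## Idealization

Gaussian-emission HMM with all transitions allowed. Default mode holds the
emission means and SDs fixed at the published per-species state values and
estimates only the transition matrix and initial distribution (shared
across traces within a condition); a free-fit mode re-estimates emissions.
Numerical choices: recursions in log space (batched implementation uses
the equivalent scaled linear form; scaling constants reproduce the
log-likelihood), variance floor 1e-4 with a `variance_floored` flag,
Viterbi ties break to the lowest state index, masked frames (blinks,
near-zero total intensity) contribute unit emission likelihood. EM stops
at a total log-likelihood gain below 1e-3 or 50 iterations. No explicit
dark state is modelled — QC removes blink-heavy traces first.

## Titration fitting

f_c per concentration is the pooled fraction of idealized frames assigned
to Classical (a per-trace-mean mode exists); its SEM is a seeded bootstrap
over traces (1000 resamples). The binding model is fitted by weighted
least squares (weights 1/SEM², unweighted if any SEM is zero) over
log(K_0, K_2, K_I) with multi-start initialization (K_0 from the drug-free
point, K_I over a log grid spanning the measured range, K_2 over
{3, 10, 30}); standard errors come from the Jacobian at the optimum via
the delta method. When the titration never approaches saturation, K_2 is
reported but flagged `weakly_identified` (relative SE > 1) rather than
silently trusted. Fits are per-drug; no parameters are shared across
drugs or species.

## Contact geometry

* Ring centroids are means of ring-atom coordinates; ring normals are the
  smallest principal direction of the centered ring atoms (sign: largest
  component made positive). For purines the six-membered ring is the
  default centroid (five-membered and fused options exist) — which ring
  center the original distance measurements used is not stated, so the
  choice is configurable and the default is the six-membered ring.
* Halogen–π: centroid distance ≤ 4.5 Å, face-on if the angle to the normal
  is ≤ 40°. Both cutoffs are conventions from the halogen-bonding
  literature, not published values, and are configurable.
* Polar contacts: heavy-atom screen at 3.6 Å; hydrogens are not required.
* Superposition: Kabsch (SVD with reflection guard); collinear sets raise.
  The exact atom selections behind the published pocket-superposition RMSD
  values are not specified; `superpose_rmsd` takes explicit pairings and
  the tests use constructed geometry plus an independent-library
  cross-check rather than claiming to reproduce those selections.

## Energy ledger

The dispersion-corrected DFT pipeline that produced the interaction
energies is out of scope; the packaged CSV carries the published per-
component values (kcal/mol, excluding deformation/desolvation) for the C45
and CL reduced pocket models. `compare_ledgers` reports signed per-
component differences, the signed net difference, and each table's
additivity gap (net minus component sum, the many-body part).

## Scale of the shipped studies

Full recovery studies use 500 traces per concentration; the shipped
acceptance script runs 150 traces × 25 seeds per design and the test suite
uses 9 seeds × 120 traces, keeping everything within a few CPU-minutes.
At 150 traces the pooled f_c SEM per point is already < 0.01, so the
median recovered K_I is insensitive to this reduction.

## Known limitations

* Dissociation-rate (kinetic) analysis is deliberately absent — residence
  times too long or too short to estimate motivated the equilibrium-only
  model, and dwell-time kinetics in the simulator are free parameters.
* The QC metrics assume a single FRET pair and no acceptor direct
  excitation.
* Bleach detection assumes the background level is reached within the
  recording; traces that never bleach are rejected rather than rescued.
* The HMM assumes Gaussian emissions on the efficiency scale; the
  intensity-ratio noise is only approximately Gaussian at low total
  intensity (such frames are masked instead).
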