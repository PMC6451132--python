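# ribofret

Quantitative analysis of how E-site-binding translation inhibitors
(lissoclimides such as chlorolissoclimide and its synthetic congener C45,
and the related glutarimide cycloheximide) shift the conformational
equilibrium of pre-translocation 80S ribosomes, as measured by
single-molecule FRET between P- and A-site tRNAs — plus the structural
contact geometry of the bound inhibitors.

The package is aimed at single-molecule and structural biophysicists who
want a tested, reproducible implementation of this analysis chain:

1. **Synthetic trace generation** (`ribofret.synthetic_data`) — donor/acceptor
   intensity time series from a three-state
   (Classical / Hybrid-1 / Hybrid-2) Markov chain with photobleaching,
   donor blinking and additive channel noise. State FRET signatures default
   to the published values (yeast: 0.65/0.40/0.22; human: 0.71/0.44/0.26).
2. **Trace QC** (`ribofret.trace_qc`) — the standard smFRET selection
   criteria: one catastrophic photobleach, signal/background-noise ≥ 8,
   signal/signal-noise ≥ 6, fewer than four donor blinks, donor–acceptor
   correlation < 0.5, and ≥ 50 pre-bleach frames at FRET ≥ 0.15.
3. **Idealization** (`ribofret.idealization`) — three-state
   Gaussian-emission HMM (all transitions allowed) with log-space
   forward/Baum–Welch/Viterbi; emission parameters fixed at the published
   state values by default, free-fit mode available.
4. **Titration fitting** (`ribofret.titration`) — the fraction of frames in
   the Classical state, f_c, versus drug concentration [I], fitted with the
   two-conformation / drug-binding equilibrium model

   ```
   f_c = (1 + [I]/K_I) / (1 + K_0 + ([I]/K_I) (1 + 1/K_2))
   ```

   where K_I is the drug dissociation constant and K_0, K_2 are the
   classical→hybrid equilibrium constants on the drug-free and drug-bound
   ribosome. Weighted nonlinear least squares on log-scale parameters with
   multi-start initialization yields K_I with curvature-based errors.
5. **Contact geometry** (`ribofret.contacts`) — halogen–π contacts
   (halogen to aromatic-ring-centroid distance, face-on angle to the ring
   normal), polar heavy-atom contacts, and Kabsch superposition RMSD, on
   mmCIF/PDB structures read through biotite.
6. **Energy ledger** (`ribofret.energy_ledger`) — component-wise comparison
   of published BLYP-D3 interaction energies of inhibitors in the E-site
   pocket.

## Worked example

Recover a dissociation constant through the full pipeline from synthetic
data generated at the yeast chlorolissoclimide affinity (K_I = 10 μM):

```python
import ribofret as rf

thermo = rf.ThermoParams(K0=4.0, K2=10.0, KI=10.0)   # generating truth
fit = rf.recover_titration(
    rf.yeast_model(), thermo, rf.synthetic_data.PhotophysicsParams(),
    concentrations=[0, 1, 3, 10, 30, 100], n_traces=150, seed=11)
print(f"K_I = {fit.thermo.KI:.2f} ± {fit.stderr['KI']:.2f} uM")
```

```
K_I = 8.63 ± 0.76 uM
```

The fitted K_I is the apparent dissociation constant in μM; the single-seed
estimate scatters around the generating 10 μM (the published yeast value),
and the median across ≥ 25 seeds recovers it to within a few percent. The
drug-free classical fraction is 1/(1+K_0) = 0.2 and the saturating fraction
is 1/(1+1/K_2) ≈ 0.91 under the default simulation constants.

Comparing the packaged interaction-energy table:

```bash
$ ribofret ledger-compare --a CL --b C45
PVF: -12.21 kcal/mol
Cyto: +0.28 kcal/mol
Gua: -0.26 kcal/mol
net (CL - C45): -12.23 kcal/mol (|net| = 12.23)
additivity gap CL: +0.43; C45: +0.47
```

The net row shows chlorolissoclimide's summed pocket interactions are
stronger than C45's by 12.23 kcal/mol, almost entirely from the
Pro-Val-Phe backbone hydrogen bonds that C45 cannot form.

A `ribofret` console script exposes `simulate`, `qc`, `idealize`, `fit`,
`contacts`, `superpose` and `ledger-compare` subcommands; run any of them
with `--help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the median pipeline-recovered K_I for
five drug/species titration designs (simulated with the published apparent
dissociation constants as generating truth, 150 traces per concentration,
25 seeds each), and the free-fit HMM estimate of the Classical-state
emission mean for both species (200 drug-free traces). Results are written
as JSON; the whole run takes a few minutes on one CPU.

See `docs/methods.md` for the model, the conventions chosen where the
criteria leave room, and known limitations.
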