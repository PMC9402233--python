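# karma

Kinetic Analysis of incorporation Rates in Macromolecular Assemblies
(KARMA): a Python toolkit for quantifying protein "age" in affinity
pulldowns from pulse-SILAC metabolic labeling experiments, and for turning
those labeling kinetics into statements about complex assembly.

## The problem

Large complexes such as the nuclear pore complex (NPC) assemble in an
ordered sequence of tiers (early → intermediate → late). When a cell
culture is switched to heavy-lysine medium, every newly synthesised protein
is heavy, so the fractional labeling of a protein,

    FL = H / (H + L),

measured from heavy/light precursor-ion intensities in a pulldown, is a
proxy for how *young* the captured molecules are. A bait that binds only
assembly intermediates pulls down unusually young — fast-labeling — copies
of the subunits it sees, while bulk proteins (traced by nuclear transport
receptors, NTRs) label with the culture's growth-dilution curve
`FL(t) = 1 − 2^(−t/T_d)`.

This package implements, as a tested library + CLI:

- **Labeling quantification** (`karma.labeling`): the full filter cascade —
  extraction-tool exclusion flags, proteotypic y-type single-lysine
  fragments detected in both channels, precursor presence across replicates
  at every post-labeling time point, per-protein two-pass median with
  pruning of the 50% highest-RMSE precursors — plus bait normalisation and
  treated/control ratios.
- **Label-free tier enrichment** (`karma.labelfree`): median normalisation
  across samples, top-3 precursor protein intensities, and the early/late
  fold-enrichment screen across multiple baits.
- **Lysate intermixing** (`karma.intermixing`): subunit exchange during
  purification, as subunit FL normalised to the mean FL of co-purified
  proteins in a mixed heavy/light lysate.
- **Kinetic state model** (`karma.kinetics`): a three-state linear
  compartment model free → accessible → inaccessible with growth dilution
  μ = ln2/T_d, whose fit yields the inaccessible-pool fraction
  φ = k_m/(k_m + μ) — the share of a subunit's assembled pool the bait
  cannot capture.
- **Fluorescence statistics** (`karma.fluorescence`): FRAP normalisation
  `(I_bl − I_bg)/(I_total − I_bg)` and recovery fitting (τ½, mobile
  fraction), intensity-profile SD filtering and cross-channel Pearson
  correlation, and Gaussian-fit peak-distance measurement on membrane line
  profiles.
- **Synthetic data** (`karma.simulate`): generators for all of the above
  with known ground truth, used by the test suite to verify every estimator
  by parameter recovery.

## Worked example

Simulate a pulldown time course (0/30/60/90 min, 3 replicates, log-normal
intensity noise σ = 0.1), run the quantification cascade and fit the
kinetic state model for one early-tier subunit:

```python
from karma import (SimDesign, simulate_karma_dataset, quantify_labeling,
                   fit_inaccessible_pool)

design = SimDesign(noise_sigma=0.1, missingness=0.02)
records, truth = simulate_karma_dataset(design, seed=7)
profiles, qc = quantify_labeling(records, min_reps_per_timepoint=2,
                                 discard_fraction=0.5)
sub = profiles[(profiles.protein_id == "early_nup_1")
               & (profiles.time_min > 0)]
res = fit_inaccessible_pool(sub["fl"], sub["time_min"], T_d=120.0,
                            protein_id="early_nup_1")
print(res.summary())
```

```
Kinetic state model fit
=============================================
protein:            early_nup_1
n observations:     9
doubling time T_d:  120 min
dilution mu:        5.776e-03 1/min
k_a (entry):        2.1848e-01 1/min
k_m (maturation):   5.4869e-03 1/min
inaccessible phi:   0.487   (phi = k_m / (k_m + mu))
residual SS:        8.344e-04
converged:          True
```

The simulated ground truth for this protein is φ = 0.5: about half of its
assembled pool has matured out of the bait's reach, which is why its
pulldown labels faster than the bulk reference. `res.plot()` draws the
observed trajectory, the fitted curve and the bulk-labeling reference.

The same analyses are available from the shell:

```sh
karma simulate --kind karma --seed 7 --out-dir run/
karma quantify-labeling --report run/fragment_report.tsv --out run/profiles.tsv
karma ksm-fit --labeling-table run/profiles.tsv --doubling-time 120 \
      --seed 7 --out run/fits.tsv
```

Every run writes a JSON manifest with row counts, filter-removal counts and
input hashes; fixed seeds give byte-identical outputs.

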