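# flavidyn

Lifetime-distribution and global kinetic analysis of
femtosecond-to-sub-millisecond time-resolved spectra of flavins and LOV
(light-oxygen-voltage) photoreceptors.

Blue-light absorption by the flavin chromophore (FMN) of LOV domains
such as the bacterial transcription factor EL222 triggers a cascade —
excited singlet → triplet (intersystem crossing, a few ns) → cysteinyl
adduct or ground state (sub-µs to hundreds of µs). `flavidyn` is for
spectroscopists who record this photocycle as transient visible
absorption (visTA) or femtosecond-stimulated Raman (FSRS) matrices and
want the time scales out of them with as few model assumptions as
possible.

## What it computes

**Lifetime-distribution analysis (LDA).** Every spectral channel trace
is inverted into a distribution of exponential decays on a fixed log
grid (41 points/decade, 10⁻¹³–10⁻³ s),

  y_i(t) = Σ_k a_{i,k} e^{−t/τ_k} + c_i ,

regularized by the maximum-entropy method with signed amplitudes
(a = p − n, Shannon–Jaynes entropy, flat prior) and a single
regularization weight per dataset chosen by the L-curve criterion.

**Dynamical content.** The lifetime density map is condensed per
spectral region to D(τ_k) = Σ_i a²_{i,k}; peaks of D with relative area
> 10% are the significant dynamical events, reported with D-weighted
geometric-mean lifetimes.

**Kinetic isotope effects.** Events matched across H₂O/D₂O datasets
give KIE = τ_D/τ_H per step; KIE ≈ 1 means no labile proton in the
rate-limiting step, KIE ≫ 1 (7–12 for the triplet→adduct conversion of
EL222) indicates rate-limiting proton transfer.

**Global kinetic analysis (GKA).** A sequential compartment model
Y ≈ C(τ)·E fitted by variable projection yields lifetimes plus
evolution-associated difference spectra (EADS) as a model-based
cross-check of the model-free LDA.

**Synthetic photocycle generator.** A forward model (sequential
kinetics at published mean lifetimes, Gaussian difference spectra,
resonance loss of dark photoproducts, 53 log-spaced delays from 100 fs
to 0.8 ms, 1% noise) provides ground-truthed fixtures for every stage.

See `docs/methods.md` for models, numerics, and design decisions.

## Worked example

Simulate the EL222 wild-type photocycle in both solvents, analyze, and
compute isotope effects:

```sh
flavidyn simulate --preset wt_h2o --seed 1 --out wt_h2o.tsv
flavidyn simulate --preset wt_d2o --seed 2 --out wt_d2o.tsv
flavidyn lda --in wt_h2o.tsv --out-map map_h.tsv
flavidyn peaks --map map_h.tsv --out-table ev_h.tsv --solvent H2O
flavidyn lda --in wt_d2o.tsv --out-map map_d.tsv
flavidyn peaks --map map_d.tsv --out-table ev_d.tsv --solvent D2O
flavidyn kie --h2o-table ev_h.tsv --d2o-table ev_d.tsv --out kie.tsv
```

prints

```
label      tau_h_s      tau_d_s      kie                   class
    1 2.590839e-09 2.593637e-09 1.001080                    none
    2 6.350032e-07 4.918401e-06 7.745474 proton_transfer_limited
```

Event 1 is intersystem crossing: its recovered lifetime (2.59 ns vs the
2.6 ns ground truth) is solvent-independent, KIE ≈ 1. Event 2 is adduct
formation: 0.635 µs in H₂O vs 4.92 µs in D₂O, KIE ≈ 7.7 — the
deuteration slowdown that marks rate-limiting proton transfer. The same
run through the sequential model agrees quantitatively:

```sh
flavidyn gka --in wt_h2o.tsv --init 2.6e-9,6.3e-7,1e-4 --out-eads eads.tsv
# tau_1 = 2.604e-09 s
# tau_2 = 6.275e-07 s
```

The `flavidyn run --config run.yaml` verb chains all stages
(simulate/load → region slicing → LDA → events → KIE/GKA) and writes a
machine-readable report that fully echoes its configuration.

As a library:

```python
from flavidyn import (simulate_preset, exclude_early_delays, fit_lda,
                      compute_dynamical_content, normalize_content,
                      detect_peaks, summarize_events)

ds, truth = simulate_preset("wt_h2o", seed=1)
amap, path = fit_lda(exclude_early_delays(ds))
events = summarize_events(
    detect_peaks(normalize_content(compute_dynamical_content(amap))))
```

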