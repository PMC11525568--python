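# relaxkit

Backbone ¹⁵N relaxation analysis for a slowly tumbling homotrimeric
enzyme (human dUTPase-like: ~50 kDa, rotational correlation time
τ_m ≈ 28 ns, three active sites, a flexible C-terminal arm that closes
over the active site on substrate binding).

The package implements, as a tested library plus a set of analysis
drivers, the quantitative machinery such a study needs:

* **Rate extraction** — R1/R1ρ/R2 from monoexponential intensity decays
  I(t) = I₀·e^(−Rt) with seeded Monte-Carlo errors; steady-state
  heteronuclear NOE from saturated/reference pairs; the tilted-frame
  correction R2 = R1ρ/sin²θ − R1·cos²θ/sin²θ.
* **Lipari–Szabo model-free analysis** — the spectral density
  J(ω) = (2/5)[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ/(1+(ωτ)²)], 1/τ = 1/τ_m + 1/τ_e,
  forward prediction of R1/R2/NOE from (S², τ_e, τ_m, R_ex) via the
  standard dipolar+CSA expressions, global τ_m from the trimmed R2/R1
  ratio, and per-residue fits of model 2 (S², τ_e) or model 4
  (S², τ_e, R_ex; two fields).
* **CPMG relaxation dispersion** — R2eff = −ln(I/I₀)/T_relax, the
  Luz–Meiboom fast-exchange and Carver–Richards general two-site models
  (Δω shared across fields in ppm), joint two-field fits, and F-test
  model selection against an exchange-free null at a P cut-off of 0.1.
* **Chemical-shift perturbation** — the weighted composite
  Δδ = √(Σᵢ(αᵢΔδᵢ)²/N) with α_H = 1, α_N = 0.14, α_C′ = 0.35;
  temperature-series CSP; intensity-trend classification; water-peak
  sign classification (same sign as exchange peaks ⇒ chemical exchange,
  opposite ⇒ dipolar ROE).
* **Subunit-state populations** — the binomial model for slow-exchange
  heterogeneity of an n-mer: group weights W_k = C(n,k)·w_c^k·w_o^(n−k).
* **Synthetic data generator** — every input above, generated with the
  statistical structure of the study (rigid core, negative-NOE
  C-terminal arm, exchange-bearing active-site patch, 600 + 850 MHz,
  Gaussian intensity noise), so the whole pipeline is testable by
  closure without raw spectra.

## Worked example: state populations of the trimer

The conformational step before catalysis has forward/backward rates of
21.2 and 3.7 Hz. Rounding the resulting closed:open balance to
per-subunit weights 4:1 and combining the three independent subunits
(microstate degeneracies 1:3:3:1):

```sh
$ python analysis/06_state_populations.py
conformational equilibrium from rates 21.2/3.7 Hz: closed:open = 5.73 (rounding to 4:1 is an explicit choice)
3-mer state groups (by closed count): 1:12:48:64 per 125 total
  3 closed: fraction 0.512
  2 closed: fraction 0.384
  1 closed: fraction 0.096
  0 closed: fraction 0.008  (possibly undetectable)
```

So a residue splitting into slowly exchanging species should show two
major peaks (64/125 and 48/125 of the signal), one minor and one
near-undetectable peak. Note the ratio phrasing trap: odds 5:1 would
give 1:15:75:125 per 216; fractions 4/5:1/5 give 1:12:48:64 per 125.
`SubunitEquilibrium` therefore takes explicit weights and never rounds
rates silently (see `docs/methods.md`).

The other drivers run the simulated study end to end:

```sh
$ python analysis/01_simulate.py            # writes results/synthetic/
$ python analysis/02_relaxation_rates.py    # R1, R2, NOE tables
$ python analysis/03_modelfree.py
global tau_m = 27.82 ns (R2/R1 trimmed median over 28 rigid residues)
fitted 80 residues (model 2); 10 with S2 < 0.5, concentrated at the C-terminus: ...
$ python analysis/04_dispersion.py
$ python analysis/05_shift_perturbation.py
$ python analysis/07_difference_report.py
binding abolishes Rex: dR2 over the 18 exchange residues is -11.29 1/s on average (all negative: True)
```

The recovered τ_m sits at the 28 ns ground truth, fitted S² drops
sharply over the C-terminal arm, and removing R_ex in the "holo"
condition produces uniformly negative ΔR2 for the exchange residues —
the three signatures the pipeline is built to detect.

## Layout

```
src/relaxkit/        library: data_io, rate_fitting, modelfree, dispersion,
                     shift_analysis, state_populations, synthetic_data, pipeline
analysis/            numbered drivers over the library (01_simulate ... 07_...)
tests/               pytest suite incl. property tests and acceptance checks
scripts/acceptance.py
docs/methods.md      models, parameter choices, numerical notes, limitations
```
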