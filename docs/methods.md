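# Methods

## System and scope

The package models the backbone dynamics workflow for a large (~50 kDa)
homotrimeric enzyme tumbling with a global rotational correlation time
near 28 ns, measured by ¹⁵N TROSY-type relaxation experiments at 600 and
850 MHz (¹H). Three dynamic regimes are treated: sub-nanosecond internal
motion (model-free order parameters), millisecond–microsecond two-site
exchange (CPMG dispersion), and slow conformational exchange resolved as
separate peaks (subunit-state populations). Spectral processing, peak
picking and assignment are upstream of this package; its inputs are
integrated peak intensities and chemical shifts as plain TSV tables.

## Relaxation rates

Delay series are fitted to the two-parameter decay I(t) = I₀e^(−Rt).
A baseline offset is a config switch, default off, as is standard for
constant-time TROSY series. Uncertainties are parametric-bootstrap
standard deviations: Gaussian noise at the spectral noise level σ is
added to the model-predicted intensities and the fit repeated
(default 500 reps, seeded). The asymptotic covariance estimate is
retained as an independent cross-check (`monoexp_asymptotic_error`);
the two agree within ~50% at typical noise.

The NOE is I_sat/I_ref with first-order error propagation
σ_NOE = (σ/|I_ref|)·√(1+NOE²). Low-signal records (|I_ref| < 3σ) and
non-converged fits are *flagged, not dropped*: in this system the
weakest resonances (the C-terminal arm) are precisely the scientifically
interesting ones, so downstream stages must see them with their flags.

R1ρ is converted to R2 via R2 = R1ρ/sin²θ − R1cos²θ/sin²θ with
θ = arctan(ω₁/Ω); tilt angles below 30° (configurable) flag the result
as unreliable rather than failing. Both the direct (CPMG-averaged T2)
and the R1ρ-corrected routes to R2 are supported; the output records
carry their provenance in the table comments.

## Model-free analysis

Spectral density: J(ω) = (2/5)[S²τ_m/(1+(ωτ_m)²) + (1−S²)τ/(1+(ωτ)²)]
with 1/τ = 1/τ_m + 1/τ_e. Rates follow the standard ¹⁵N dipolar + CSA
expressions with d = (μ₀/4π)ħγ_Hγ_N/r³ and c = ω_NΔσ/√3. Constants:
r_NH = 1.02 Å, Δσ = −160 ppm (the common literature defaults; both
config-overridable — they shift absolute S² by a few percent at most),
γ_H = 2.6752219×10⁸, γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹.

A consequence of the long τ_m worth stating explicitly: at 28 ns and
600 MHz the NOE is extremely τ_e-sensitive. A core-like residue
(S² = 0.85) has NOE ≈ 0.90 at τ_e → 0 but ≈ 0.53 already at τ_e = 50 ps.
Negative NOE — the signature of the flexible C-terminal arm — requires
τ_e roughly in 0.1–0.6 ns at low S²; τ_e near 1/ω_N (~2.6 ns) instead
*boosts* R1 and pushes the NOE positive again. The synthetic generator's
arm range (below) is chosen inside the negative-NOE window accordingly.

Global τ_m is estimated before any per-residue fit and then held fixed
(two-stage, no global/local alternation; per-residue fits stay
independent and parallelizable). Each rigid-looking residue's τ_m is
solved from the S²-independent rigid R2/R1 ratio by Brent root finding
on [1, 100] ns; residues with NOE < 0.65 are excluded (internal motion
violates the rigid assumption) and the estimate is the median after
symmetrically trimming 10% from each end, which absorbs
exchange-broadened residues in the upper tail.

Per-residue fits: model 2 fits (S², τ_e) to R1/R2/NOE at one field;
model 4 fits (S², τ_e, R_ex) to both fields, with R_ex parameterized at
the lower field and scaled by the squared field ratio (exchange
broadening in the fast limit scales as B₀²). Bounds: S² ∈ [0, 1],
τ_e ∈ [0, τ_m], R_ex ∈ [0, 100] s⁻¹. Model selection between 2 and 4 is
a configuration decision, not automated (an AIC helper is provided for
information only). Optimization is bounded trust-region least squares
from a 4×4(×4) start grid; the leading three coarse candidates are
polished to machine tolerance, the lowest χ² wins, and a tie (within
10⁻⁶ relative) breaks to the smaller τ_e. Two numerical points matter:
parameters are scaled (x_scale ≈ [0.1, 0.05τ_m, 1]) because τ_e lives
nine orders of magnitude below S², and the finite-difference step is
fixed at a relative 10⁻⁶ — the default √ε·x step at τ_e ~ 10⁻¹¹ s falls
below the double-precision resolution of the model and yields a noise
Jacobian. Records with zero stated error (noiseless closure data) are
weighted relatively (1/|obs|) so R2 does not drown R1 and NOE.

## CPMG relaxation dispersion

R2eff = −ln(I/I₀)/T_relax with σ_R2eff = σ_I/(I·T_relax); non-positive
intensities (signal below noise) are excluded point-wise and flagged.
Three profile models:

* no_exchange: per-field constant (closed-form weighted mean);
* fast_exchange (Luz–Meiboom): R2⁰ + (Φ/k_ex)[1 − (4ν/k_ex)tanh(k_ex/4ν)],
  Φ = p_A p_B Δω²;
* carver_richards: the full two-site closed form with equal intrinsic
  rates, R2eff = R2⁰ + k_ex/2 − ν·cosh⁻¹(D₊cosh η₊ − D₋cos η₋), with
  Ψ = k_ex² − Δω², ζ = −2Δω k_ex(p_A−p_B), η± = (τ_cp/√2)√(±Ψ+√(Ψ²+ζ²)),
  τ_cp = 1/(2ν). This "general exchange" model covers all time-scale
  regimes; which model produced a fit is recorded in the output.

The closed form is validated in the test suite against an independent
numerical Bloch–McConnell propagation (matrix exponential per τ-180-τ
element, 180° pulses as complex conjugation): agreement is ≤0.5% in
fast exchange, ~2% in the intermediate regime and ~4% towards slow
exchange — the known accuracy envelope of the closed-form
approximation. Δω is shared across fields in ppm; R2⁰ is per field;
R_ex is reported per field as model(ν_min) − model(ν→∞). Fits are
per-residue and independent (no global k_ex across residues). Errors on
R2eff come from spectral-noise propagation; duplicate-point scatter is
used instead when duplicates exist.

### F-test model selection and its calibration

Nested fits on identical data are compared by
F = [(χ²_null − χ²_alt)/(df_null − df_alt)]/[χ²_alt/df_alt] with
P from the F distribution; the exchange model is chosen iff P < 0.1
(configurable). A perfect alternative over a perfect null resolves to
the null (parsimony).

This F-test is *conservative*, and deliberately so documented: the
exchange family is bounded (R_ex ≥ 0) and monotone non-increasing in ν,
so it cannot chase upward-trending noise — roughly half of all null
realizations yield no χ² reduction at all, and the rest yield the
reduction of ~1 effective parameter rather than the nominal 2–3.
Measured over 1000 exchange-free profiles at 2% intensity noise, the
exchange model is selected in ~0.5–2% of cases at the 0.1 cut-off, not
10%; equivalently, null P-values are stochastically larger than
uniform. The test is therefore valid (type-I ≤ nominal) but not exact;
power remains high (≥95% detection of R_ex = 8 s⁻¹ profiles at 2%
intensity noise). Users who need exact calibration should calibrate the
cut-off by simulation at their own noise level — the machinery here
makes that a few lines.

## Chemical-shift perturbation

Composite CSP between two conditions: Δδ = √(Σᵢ(αᵢΔδᵢ)²/N) over the
nuclei present in both rows, α_H = 1.0, α_N = 0.14, α_C′ = 0.35 (the N
and C′ weights reflect their larger shift dispersion; taken as given,
not re-derived; all overridable). Dividing by N (mean convention)
keeps H,N and H,N,C′ analyses on one scale; the pure-sum variant is a
config switch. Residues with no usable resonance in the target
condition are reported with an `undetectable_target` status — the
"red-bar" residues that vanish on ligand binding — rather than a value.

Temperature series: composite CSP of each temperature against a
reference table, NaN + flag for residues undetectable at the reference.
Intensity-versus-temperature trends are classified by the OLS slope
sign when its two-sided p < 0.05, else flat — the labels are binary
annotations, so a linear model suffices. Water cross peaks are
classified by sign relative to the exchange-peak reference: same sign ⇒
chemical exchange with bulk water, opposite ⇒ dipolar (ROE) contact.

The Δω-vs-CSP correlation is the squared Pearson correlation over the
pairwise-complete intersection, with n reported and n < 5 flagged as
degenerate.

## Subunit-state populations

Each subunit of an n-mer independently occupies closed/open states with
weights (w_c, w_o); the 2ⁿ microstates group by closed count into
W_k = C(n,k)w_c^k w_o^(n−k), Σ W_k = (w_c+w_o)ⁿ, implemented both as
the closed form and as exhaustive enumeration (cross-checked in tests
up to n = 10). Integer weights give exact integer group weights.

The worked trimer example uses weights (4, 1): groups 1:12:48:64 per
125, i.e. two major species (0.512, 0.384), one minor (0.096) and one
near the detection floor (0.008). The underlying rate pair
(21.2/3.7 Hz ⇒ ratio 5.73) is carried unrounded by
`SubunitEquilibrium.from_rates`; rounding is always the caller's
explicit act, because "about 5:1" is ambiguous between odds 5:1
(⇒ 1:15:75:125 per 216) and fractions 4/5:1/5 (⇒ 1:12:48:64 per 125) —
the two readings give different printed ratios and only the caller
knows which was meant. Both are supported; the package never converts a
ratio phrase silently.

## Synthetic data generator

The generator is the package's stand-in for the raw spectra and defines
the study conditions: τ_m = 28 ns, fields 600 and 850 MHz, constant-time
CPMG T_relax = 40 ms, reference intensity I₀ = 1000 with Gaussian noise
σ = 2% of I₀, 310 K. Regions and parameter ranges:

| region | share | S² | τ_e | exchange |
|---|---|---|---|---|
| core | 0.65 | U(0.75, 0.95) | U(10, 100) ps | none |
| c_terminal_arm | 0.12 | U(0.02, 0.3) | U(0.1, 0.6) ns | none |
| active_site_patch | 0.23 | U(0.75, 0.95) | U(10, 100) ps | k_ex ∈ U(500, 3000) s⁻¹, p_A ∈ U(0.9, 0.99), Δω ∈ U(0.5, 3) ppm |

The arm occupies the C-terminal end of the sequence; its τ_e window is
chosen inside the negative-NOE regime (see above). The arm share
mirrors a ~16-residue arm on a ~140-residue construct; the patch share
mirrors roughly a third of integrable residues showing dispersion.
Forward models are imported from the analysis modules themselves —
closure tests therefore test fitting, not a second transcription of the
equations. R2 decay series include the residue's R_ex (transverse
relaxation during CPMG-averaged T2 carries the exchange contribution);
dispersion profiles are generated as intensities and pushed through the
same R2eff conversion the pipeline uses, so their error bars carry the
propagated spectral noise. Shift tables realize a regional CSP
magnitude m as (Δδ_H, Δδ_N, Δδ_C′) = (m, m/0.14, m/0.35)·(1 ± 0.2
scatter), making the default-weight composite equal m on average.

What the generator does **not** emulate: peak overlap and lineshape
effects, temperature dependence of τ_m, anisotropic diffusion,
correlated noise between experiments, biexponential decays. Passing
closure tests therefore demonstrate correctness of the estimators under
the stated statistical model, not robustness to every pathology of real
spectra.

All generators are bit-reproducible from (config, seed); sub-streams
are derived per dataset so adding one dataset never shifts another.

## Pipeline

`run_pipeline` executes simulate → rates → model-free → dispersion →
CSP → populations from one YAML-serializable config whose defaults are
the study's stated choices (fields 600/850, models 2/4, P cut-off 0.1,
α = 0.14/0.35, trimer weights 4:1). Every output is stamped with a
SHA-256 hash of the scientific parameters (the output path is excluded)
and the seed; reruns are byte-identical. One residue failing a fit is
logged and skipped, never fatal, and quality flags travel as a table
column — which residues drop out is itself a result. The difference
report (holo − apo) is antisymmetric by construction; residues missing
from either condition appear with NA differences and an explicit
`undetectable_*` flag (they plot as zero contribution, but the flag
preserves the reason).

Problem sizes in the shipped drivers and tests (80 synthetic residues
in the drivers; 200-residue/1000-replicate simulation studies in the
acceptance properties) are desk-scale choices that keep a full run in
minutes on one core while leaving the Monte-Carlo assertions
well-resolved.

## Known limitations

* Isotropic overall tumbling only; no diffusion-tensor anisotropy and
  no extended (two-time-scale) model-free variant.
* Carver–Richards assumes equal intrinsic R2 in both exchange states.
* The F-test is conservative (see above); reported P-values are upper
  bounds on evidence strength, not exact tail probabilities.
* PDB handling is single-model, first chain set, no insertion codes —
  the B-factor writer exists to paint per-residue values for structure
  viewers, nothing more.
* Construct/crystal numbering is opaque user input; no remapping.
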