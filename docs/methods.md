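# Methods

This note documents the models implemented in `g4screen`, the assumptions
behind them, the tunable parameters, what the synthetic generators do and
do not emulate, and the numerical choices made where the design was open.

## Sequential-binding equilibrium

The binding model is strictly sequential and limited to two sites:
M + L ⇌ ML (K_D1) and ML + L ⇌ ML₂ (K_D2), with concentrations in µM
throughout. Higher stoichiometries (3:1, 4:1 complexes occasionally seen
with short foldamers on polythymine) are outside the fitting model; the
species-table layer folds any ligand count ≥ 2 into the ML₂ channel so
their intensity is at least conserved.

`solve_equilibrium` parameterizes the system by free ligand x: the DNA
partitions as M = M₀/(1 + x/K_D1 + x²/(K_D1 K_D2)), and the bound-ligand
total is strictly increasing in x, so the ligand balance has exactly one
root in [0, L₀]. Brent's method with tolerances of 1e−15 gives mass
balances at the 1e−9 relative level demanded by the round-trip tests.

**Censoring.** A single-concentration screen cannot distinguish very weak
binders from non-binders: when a species sits below the detection floor the
corresponding K_D is reported as a one-sided bound (`Censored`), using a
configurable pseudo-concentration floor (default 1e−3 µM). Non-positive
free ligand — possible with noisy intensities — likewise produces a
censored value, never a negative K_D. Censored values propagate to an
`undetermined` cooperativity class.

**Cooperativity band.** The statistical-factor boundary K_D2 = 4 K_D1 is
compared with a relative half-width of 1e−6; the source analysis defines
only strict inequalities, so the band exists purely to keep floating-point
equality deterministic.

## Titration fitting

The objective compares per-point species *fractions* (each point's M, ML,
ML₂ intensities divided by their sum) rather than raw intensities, which
removes the unknown per-point spray-efficiency scale. The dT₆ internal
standard enters through the response-drift step: the total-DNA/standard
ratio is regressed linearly against ligand concentration (configurable to
constant), and each point is renormalized to the zero-ligand ratio before
fitting. Response factors r_ML and r_ML2 (r_M ≡ 1) absorb stoichiometry-
dependent transmission differences.

Parameters are log₁₀-transformed and bounded: K_D ∈ [1e−4, 1e4] µM,
responses ∈ [0.01, 100]. Initialization uses the single-point estimator at
the mid-titration point with unit responses — on equal-response data this
starts essentially at the optimum. Weights are Poisson-like (σ ∝ √I,
floored at 3σ_noise and at a small epsilon so noise-free synthetic data do
not divide by zero). Standard errors come from the Gauss–Newton quadratic
approximation at the optimum (pseudo-inverse of JᵀJ scaled by the reduced
cost) and are reported on the K_D scale via the delta method; with a weakly
populated second site they are honest about K_D2 being poorly determined
(single 5%-noise runs can push K_D2 to its bound — medians over replicates
are reported in the analysis driver).

## Ion mobility

The stepped-field fit regresses apex arrival time on the reduced inverse
voltage x = L²pT₀/(p₀T·ΔV); the slope is 1/K₀ and the intercept the dead
time. Apexes are picked by three-point parabolic interpolation (sub-bin
precision without assuming a peak shape). Records must agree in p and T to
5% by default. Drift-tube length defaults to 78.1 cm.

Constants follow the Loschmidt convention T₀ = 273.15 K, p₀ = 760 Torr,
N₀ = 2.6868×10²⁵ m⁻³. (One source prints 275.15 K; we treat that as a typo
for the standard convention. The registry value is a single constant, and
all acceptance-grade checks are synthesize-then-analyze round trips that
cancel the choice.) Helium mass 4.0026 Da; reduced mass uses the full
adducted ion mass, though at 7+ kDa the helium reduced mass is insensitive
to it.

CCS distributions transform each arrival time through K₀(t) = x/(t − t₀)
and Mason–Schamp; the abundance is rescaled by |dt/dCCS| so integrated area
is preserved. The transform is strictly monotone, hence mode counts carry
over — multimodal arrival distributions directly indicate conformational
heterogeneity. Points at or before t₀ are dropped with a warning.

## K⁺ adduct specificity

Candidates are channels exceeding both neighbors by a factor of 1.5
(edge channels compare to their single neighbor). The Poisson background is
then fitted by conditional maximum likelihood with all candidate channels
treated as missing, which keeps a large specific peak from inflating λ. A
candidate is confirmed only if it exceeds the background prediction by more
than 3 "background standard deviations", where the standard deviation
combines (i) Poisson counting noise of the channel, (ii) the sampling
variance of the unmasked amplitude, and (iii) the delta-method variance
propagated from the fitted λ (inverse observed information). Component
(iii) matters: at small λ the n = 0 channel is always a ratio candidate on
pure background, and the prediction for a masked channel is strongly
anticorrelated with its observed count — ignoring that inflates false
positives well above 1%. With it, measured false-positive rates on pure
Poisson draws of 10⁴ ions are ≲0.3% across λ ∈ [0.15, 2], while 5-fold
spikes are always detected. Both thresholds (ratio 1.5, 3σ) are config
keys and are echoed in the output metadata. n specific K⁺ ⇒ n+1 quartets;
when several n are specific all are reported and the count uses the
maximum.

## Optical curves

CD conversion divides blank-subtracted ellipticity (mdeg) by 32980·c·l.
Melting baselines are ordinary least-squares lines in the lowest and
highest 15% of the temperature span by default; which flank is "folded"
follows the monitored wavelength (295 nm: folded absorbs higher; 260 nm:
inverted). A 335 nm channel, when supplied, is subtracted as an additive
drift reference before conversion. The folded fraction is not clipped to
[0, 1]; noise excursions are information. T_m is linearly interpolated at
the first θ = 0.5 crossing in ramp order; additional crossings trigger a
multimodality flag (biphasic complex melts are detected, not fitted — the
two-transition case is reported as first-crossing plus flag only).

A baseline window that overlaps the transition is flagged by comparing the
fit residual scale to the full melting amplitude (plain R² misfires on
flat, noisy baselines). Accurate T_m extraction with the *default* windows
requires the transition to be resolved from both scan edges; with a 4–90 °C
scan and van't Hoff enthalpies near 220 kJ/mol this holds for T_m roughly
in the 20–60 °C range, and the recovery tests operate there. For melts near
a scan edge, pass explicit windows.

## Synthetic generators

Defaults state the experimental world: 10 µM DNA; screening at 20 µM
ligand with 4 µM dT₆; titration grid 0/5/10/15/20/30/40 µM; free DNA
carrying 1 specific K⁺ and complexes 2 (the 2-quartet → 3-quartet
selection scenario); nonspecific adduct λ = 0.5; charge states 5−/4−;
drift tube 78.1 cm at 3.95 Torr / 296 K with t₀ = 0.3 ms; melting scans
4–90 °C with enthalpy 200 kJ/mol. Spectra are sums of Gaussian peaks
(σ = 0.4 Th) with additive Gaussian noise; titration tables optionally get
multiplicative log-normal noise (covering the counting and detector-gain
regimes); CD spectra are fixed Gaussian band sets per topology — fixtures
for testing conversion and sign conventions, not predicted spectra.

Not emulated: isotope fine structure, peak-shape asymmetry, spray physics,
charge-state-dependent transmission, Na⁺/K⁺ mixed adducts, and instrument
transfer functions. A green recovery test therefore establishes that the
analysis inverts its own stated forward model at the stated noise — not
that it is robust to every instrumental artifact.

Every generator takes a seed and is bit-reproducible; every generator
returns a ground-truth ledger (true areas, equilibrium states, apex times,
θ(T)) that the recovery tests compare against.

## Known limitations

- The screening and titration models stop at two ligand sites.
- Overlapping integration windows of different stoichiometry are excluded
  and flagged, not deconvolved (signal splitting would need peak-shape
  models the data do not constrain).
- Biphasic melting curves yield a flag and the first T_m only.
- The mzML support is a deliberate minimal subset (single MS1 spectrum,
  64-bit uncompressed arrays, zlib accepted on read) sufficient for
  round-tripping the generator's output; general mzML should go through a
  dedicated reader.
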