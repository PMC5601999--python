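# Methods

`memfluo` quantifies how a soluble protein binds to, oligomerizes on,
inserts into and finally crosses a lipid membrane, from four kinds of
fluorescence data: z-scan FCS on giant unilamellar vesicles (GUVs),
single-molecule spot brightness on supported bilayers, confocal GUV
translocation images, and binding titrations.  This note records the
models, the conventions chosen where the field has more than one, and
what the built-in synthetic data do and do not establish.

## 1. The membrane FCS model

The autocorrelation of the detected intensity is modeled as

    G(τ) = 1 + [ (1/PN2D)·(1 + τ/τ2D)⁻¹
               + (1/PN3D)·(1 + τ/τ3D)⁻¹·(1 + SP·τ/τ3D)^(−1/2) ]
             · (1 − T + T·e^(−τ/τT)) / (1 − T)

with a 2D term for membrane-bound fluorophores, a 3D term for free
fluorophores in solution, and a triplet-blinking factor.  PN2D and
PN3D are effective particle numbers in the Gaussian detection area
π·w0² and volume; T is the triplet fraction and τT its lifetime.

**Axial-factor convention.** Renderings of the 3D term differ across
the z-scan FCS literature; we use the standard elongated-Gaussian
factor (1 + SP·τ/τ3D)^(−1/2) with SP = (w0/wz)².  The exponent is an
argument (`sp_exponent`) so the (1 + SP·τ/τ3D)⁻¹ convention can be
selected if an instrument was calibrated that way.

**Beam waist.** w0 is an instrument property that must be calibrated;
the package default is 0.25 µm, a typical 488-nm confocal waist, which
places surface concentrations computed from typical particle numbers
in the 0.1–1 nmol/m² range.  Every quantitative result scales simply
with w0 (D ∝ w0², c ∝ 1/w0²), so the default is a placeholder, not a
claim.

## 2. Correlator

`correlate_trace` is a software multiple-tau correlator: 16 linear
lags per block, factor-2 coarsening between blocks, symmetric
normalization (product sums divided by the means of the leading and
trailing sub-traces), first reported lag two bin widths.  Symmetric
normalization makes G(τ) → 1 exactly for uncorrelated signals and
suppresses slow-drift bias.  A brute-force direct-sum correlator
(`direct_correlation`) is kept as the oracle; the two agree exactly at
level-0 lags by construction and that identity is tested.

## 3. Curve fitting

Trust-region least squares (`scipy.optimize.least_squares`) with
per-lag weights 1/se² when standard errors are available.  The model
is multi-modal at low SNR, so fits start from a 3×3×3 grid over
(PN2D, τ2D, T) around the heuristic initial guess (amplitude →
1/PN2D, half-amplitude lag → τ2D); the three cheapest starts are
polished and the best kept.  Bounds: PN > 10⁻³, times in [10⁻⁶, 10] s,
T ∈ [0, 0.5]; cost tolerance 10⁻⁹.  Non-convergence is flagged, never
silent.  Parameter standard errors come from the Gauss–Newton
covariance; they feed the z-profile weighting below.

Lack of fit is declared when the reduced χ² against known per-lag
errors exceeds 3 (or, without known errors, when the raw rms residual
exceeds 3× a noise floor estimated from successive differences).  The
χ² route matters because ACF noise is strongly heteroscedastic in lag.

## 4. z-scan analysis

Scanning the membrane through the focused beam makes the illuminated
area grow as w(z)² = w0²·(1 + (λz/(π·n·w0²))²), so PN2D(z), τ2D(z) and
the mean intensity are all exactly parabolic in z.  The chain is:
fit each z's curve (bulk amplitude free); fit weighted parabolas
(weights 1/se from the per-z fit covariance) to PN2D(z) and τ2D(z)
over the converged z-points; refit the vertex-nearest curve with
1/PN3D pinned to zero (the bulk contribution vanishes at the membrane
plane); evaluate the intensity parabola at the PN2D vertex.  Then

* ϕ_cluster = (I − background)/min PN2D,
* oligomeric state = ϕ_cluster/ϕ_monomer,
* D = w0²/(4·min τ2D),
* c = state·min PN2D/(π·w0²), converted to nmol/m²
  (1 molecule/µm² = 10²¹/N_A nmol/m²; conversions live in
  `memfluo.units` and are unit-tested).

The error-weighted parabolas are essential: τ2D estimates at the dim
profile wings carry several-fold larger errors than at the waist, and
unweighted quadratics occasionally go non-convex there.  A parabola
falls back (flagged) to the sample minimum when its curvature is
non-positive, its vertex leaves the scanned range, its vertex value is
non-positive, or its predicted rise across the scan is below 0.1% of
the vertex value (flat profile = no membrane).

**Monomer reference.** ϕ_monomer is produced by running the identical
pipeline on monomer-control scans (≥ 5) and pooling ϕ_cluster — the
same dilute non-oligomerizing-mutant strategy used at the bench.

**Bilayer QC.** The membrane-marker channel must fit a free
single-component 2D model at the vertex with D ∈ [0.5, 20] µm²/s and
no lack of fit; otherwise `qc_pass` is false.  A double fall-back of
both protein-channel parabolas also fails QC.

## 5. Brownian-dynamics photon simulator

The oracle for the whole FCS chain.  Clusters of n monomers diffuse on
a periodic box of side ≥ 20·w0 (step sd √(2·D·dt) per axis); optional
bulk monomers diffuse in a slab of height 8·wz; the detection weight
is exp(−2r²/w0²)·exp(−2z²/wz²); an oligomer of size n emits n× the
monomer brightness; bin counts are Poisson of the summed rate plus
background.  Blinking is a two-state Markov chain whose dark dwell is
τT and whose equilibrium dark fraction is T (particles start bright; the
transient relaxes within a few τT).

**Time step.** Brownian increments are exact at any dt, and
point-sampled bins reproduce the continuous-time ACF exactly at
integer lag multiples, so the default is one step per counting bin;
sub-steps are introduced only to resolve triplet kinetics
(dt ≤ τT/10), or on request.  The `substeps` argument restores finer
integration when intensity integration within bins is itself under
study.

**Mean-intensity conservation.** The expected count rate has the
closed form background + Σ density·n·q·(π·w0²/2) (+ bulk term
conc·q·(π/2)^{3/2}·w0²·wz); simulated traces match it within 2%.  Note
that 2D diffusion is recurrent: the time-averaged occupancy of the
detection area has variance ∝ (τ2D/T)·ln(T/τ2D)/PN, so sparse, slow,
short traces legitimately wander several percent from the ensemble
mean — dense/fast configurations are used where the mean itself is
asserted.

**z-scan modes.** `fast` generates per-z curves analytically from the
beam-expansion formulas with seeded noise; `oracle` runs the particle
simulator at every z with the local beam radius.  Both hold the
beam-center brightness fixed along z (no pinhole model), so the mean
intensity scales with the illuminated area; only the value at the
waist enters any recovered quantity, making the convention immaterial
for results.  Cross-mode agreement of the full analysis is tested at
15%.

**Fast-mode noise law.** Per-lag Gaussian noise with
sd = scale·(G(0)−1)·√(τ/T_trace) — the Koppel-type √τ growth with an
amplitude-proportional prefactor, calibrated against the oracle
simulator (a baseline-proportional prefactor would imply tens of
percent baseline noise at tail lags, which no measured 60-s curve
shows).  The generated curves carry these sds as `se`, so fits are
correctly weighted.

## 6. Spot brightness and mixtures

Diffraction-limited spots are local maxima (merged below a minimum
separation, brighter one kept) fitted with a 2D Gaussian
amp·exp(−((x−x0)²+(y−y0)²)/(2σ²)) + offset in a window; fits with σ
outside 0.7–1.9× the nominal PSF σ are rejected.  Pixels are 0-based
with coordinates at pixel centers.  Counts per cluster are
peak/ϕ_monomer; the labeling-efficiency correction (÷DOL) is off by
default and the DOL travels as metadata.  The monomer brightness
standard is the single-component mode of the same pipeline run on a
monomer-control image.

Subunit distributions are deconvolved with 1D Gaussian mixtures
(scikit-learn EM, free variances with a 10⁻² variance floor, 10 seeded
restarts per k) and k = 1..8 selected by BIC, which penalizes spurious
components at the ~10³-sample sizes typical for cluster counts.

## 7. FRAP

I(t) = I0 + A·(1 − e^(−t/τ)); mobile fraction
(I0 + A − I_post)/(I_pre − I_post).  The diffusion constant uses
D = L²/(4τ) with L half the bleach-square side; this geometry
convention is declared, not derived, and both L and the factor 4 are
configurable (`geometry_factor`).  Non-exponential or overshooting
recoveries are flagged; near-zero amplitudes leave τ unconstrained and
say so.

## 8. GUV scoring

Per vesicle: ring detection in the membrane channel (radial-profile
argmax alternating with intensity-weighted ring-centroid refinement,
with collapse guards for border-clipped rings, which are flagged and
excluded); 1-px annulus radial profiles; lumen mean over r < 0.6·R and
exterior mean over r > 1.4·R, both after camera-offset subtraction —
the region bounds exclude the membrane peak and its PSF skirt and are
configurable.  The display profile is normalized to its maximum, but
ratios are always computed on offset-subtracted raw means so they do
not couple to membrane brightness.  Classification: pore if the
small-tracer ratio ≥ 0.6, translocation if the cargo (GFP) ratio
≥ 1.6, boundaries counting as positive; thresholds configurable.
Population statistics are per-replicate percentages with
cross-replicate mean and sd.

The camera offset should be supplied from instrument metadata; the
corner-patch estimator exists for images whose corners are known to be
fluorophore-free and is not a safe default when the surrounding buffer
itself fluoresces.

## 9. Binding assays

Combined chemical-shift perturbation Δδ = √(δH² + (0.15·δN)²) (the
0.15 nitrogen weight is configurable).  Titrations are fitted
per-residue with the depletion-aware quadratic two-state model by
default — at P = 80 µM protein and K_D of tens of µM the free-ligand
approximation fails — with the hyperbolic model available; the
reported K_D is the mean over residues with its sd.  Residues whose
fitted Δδmax is below 3× the median residual (or below 10⁻³ ppm, the
practical shift-tracking resolution) carry no binding information and
are excluded; series whose largest ligand concentration is below the
fitted K_D are flagged non-saturating.

**Identifiability.** With absolute per-point noise of 5% of each
residue's Δδmax on a 10-point titration, the Cramér–Rao bound for the
8-residue mean K_D is ~13% relative sd at K_D = 16 µM (and ~41% at
K_D = 1 µM, where titration against 80 µM protein is nearly
stoichiometric).  The estimator is unbiased and reaches this bound, so
recovery medians around 9–10% are the information limit of the design,
not an algorithmic deficiency; K_D values far below the protein
concentration cannot be recovered precisely by any method from such
data.

Competition series are normalized as
100·(signal − background)/(control − background), with the
half-maximal competitor concentration interpolated log-linearly at the
first downward 50% crossing (absent when the series never crosses).
Long-chain-competitor concentrations are carried in disaccharide-unit
molarity with an explicit unit tag.  Degree of labeling:
DOL = (A_dye/ε_dye)/((A280 − A_dye·CF)/ε_prot), the standard dye
A280 correction.

## 10. Validation studies and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) re-run the
recovery studies from scratch: the heavy one is oracle equivalence —
four replicate 60-s Brownian traces per condition (N = 5 and 20 at
D = 2.5 µm²/s, 0.2 ms bins, ~2500 particles for N = 20), chosen
because single 60-s membrane ACFs fluctuate by a few percent of their
amplitude at long lags (the recurrent-diffusion tail again), so a
stable deviation measure needs replicate averaging.  The z-scan
recovery studies use fast-mode generation (10 replicates per
condition); the mixture, GUV, titration and FRAP studies use their
stated cohort sizes (20 runs × 1200 clusters; 200 vesicles; 10
datasets per K_D; four mobile fractions).

What passing these studies shows: the estimators are consistent and
calibrated under the generative models stated above.  What it does not
show: robustness to optics the generators omit — pinhole rejection and
aberrated PSFs, membrane undulations, detector afterpulsing and
dead-time, photobleaching during acquisition, vesicle shape
fluctuations, spectral bleed-through.  Real-data use should treat the
QC flags as first-class outputs.

## Known limitations

* Single-species analysis: the correlation fit assumes one membrane
  component (plus bulk); two-component membrane mixtures are detected
  (lack of fit) but not resolved.
* The oligomeric state from brightness is the brightness-squared
  weighted mean over cluster species (verified against theory for
  monomer/8-mer mixtures), not a size distribution.
* No two-color cross-correlation, photon-counting histograms or
  afterpulsing correction.
* Fast-mode z-scan supports exactly one cluster species and no bulk
  term.
* GUV scoring is 2D (equatorial section); no volumetric ratios.
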