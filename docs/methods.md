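# Methods

`pesuq` implements and evaluates uncertainty quantification (UQ) for
machine-learned reactive potential energy surfaces (PES): query-by-committee
ensembles, three deep-evidential-regression (DER) formulations, feature-space
Gaussian-mixture scoring, top-k outlier-detection metrics, and a
structure-based in/out-of-distribution rank. Everything runs end to end on a
synthetic reactive benchmark, so no external quantum-chemistry data is
required. This note records the models, the numerical choices, and the
limits of what the synthetic benchmark can show.

## The synthetic reactive benchmark

The benchmark emulates an intramolecular H-transfer reaction on an 8-atom
C₂O₂H₄ molecule (the same atom count, and hence the same R = 28 atom-pair
count, as the CH₃CHOO-type system such studies target). The analytic surface
is a sum of

- **Morse bonds** on the covalent skeleton (C–C, C–O, O–O, three spectator
  C–H bonds) with depths 55–100 kcal/mol and widths 1.8–2.2 Å⁻¹;
- a shallow **scaffold Morse term** (D = 40 kcal/mol, r₀ = 2.6 Å) between
  donor carbon and acceptor oxygen, standing in for the ring-like
  conformational constraint that makes intramolecular transfer geometrically
  possible;
- **harmonic angle terms** (k = 40 kcal/mol/rad², tetrahedral reference) on
  the bonded triplets. These are required for a well-posed benchmark: with
  pair terms alone the H–C–H bending directions are exact zero modes, the
  minima are degenerate manifolds, and no harmonic-frequency contract can
  hold;
- **Lennard-Jones** interactions between all pairs separated by three or
  more bonds (1-2 and 1-3 pairs excluded, Lorentz–Berthelot combining);
- the **transfer term**: two Morse potentials sharing the transfer hydrogen
  (donor–H and acceptor–H) plus a Gaussian ridge on the transfer coordinate
  q = r(D–H) − r(A–H). The ridge height and the acceptor-Morse depth are
  calibrated at construction by root finding so that a rigid scan of the H
  along the donor–acceptor axis shows a configurable barrier (default
  20 kcal/mol above the reactant well) and well asymmetry (default
  +5 kcal/mol). Without the ridge the two-Morse superposition alone couples
  barrier and asymmetry so strongly that the calibration system is nearly
  singular; the ridge decouples them.

Forces are exact analytic gradients (validated against central differences
at 10⁻⁶ kcal/mol/Å), which gives every downstream module — training,
dynamics, Hessians — an exact oracle. Stationary points are located by
L-BFGS from a symmetry-broken start (the hand-built template is exactly
mirror-symmetric, and gradient descent started on the symmetric subspace
converges to a saddle of the full space), then polished by projected Newton
steps; the transition state is found as the maximum of a relaxed scan along
q (quadratic-penalty constrained minimization with continuation) followed by
the same Newton polish. The reactant and product are true minima (no
imaginary frequencies) and the saddle has exactly one imaginary mode
(≈ 3400i cm⁻¹, an H-transfer motion). Full relaxation lowers the barrier
relative to the rigid-scan value (≈ 9 vs 20 kcal/mol); the calibration
target is defined on the rigid scan.

**Sampling.** Training/validation data are Gaussian Cartesian displacements
around both well geometries (default scale 0.05 Å per coordinate at 300 K,
scaled by √(T/300) for other temperatures) plus a fraction (default 15%) of
interpolated transfer-path geometries with smaller noise. Two filters apply:
structures more than `energy_cap` (default 400 kcal/mol) above the global
minimum are rejected, and structures whose q falls inside the **held-out
window** are never placed in train/validation. The window spans 60% of the
distance from the saddle towards each well — wide enough that the training
set leaves a genuine coverage gap around the transition state. Benchmark
test sets mix in-distribution draws (by default over temperatures
300/300/500 K, a mildly broader distribution than training, emulating an
unseen test set) with draws from inside the window; boolean flags mark the
latter as ground-truth out-of-distribution (OOD) structures. By
construction these OOD structures sit at moderate energies (the TS region),
not at the top of the energy distribution — the regime where outlier
detection is actually hard.

A fixed-point-charge dipole surface (q_C = +0.15, q_O = −0.25,
q_H = +0.05 e; μ = Σqᵢrᵢ) with zero total charge exists solely to exercise
the charge/dipole loss terms; it makes no physical claim.

## The backbone regressor

The regressor maps the R = n(n−1)/2 inverse pairwise distances (fixed
lexicographic pair order; optional per-pair Gaussian expansion) through a
feed-forward network (tanh, two hidden layers, width 128 by default,
matching the feature dimensionality such models typically use) to the
molecular energy. Descriptors and energies are standardized with training
statistics. Forces are obtained by differentiating the predicted energy
through the descriptor — the closed-form input gradient of the network
contracted with the constant descriptor Jacobian — so predicted forces are
exactly the negative gradient of the predicted energy (finite-difference
agreement ≤ 10⁻⁴ relative) and rotate covariantly while the energy is
exactly invariant. The last hidden layer is the molecule feature vector
consumed by the GMM; with a single molecular graph per structure, pooling
over sub-units reduces to the identity, so the layer itself is the pooled
feature.

Training uses ADAM with batch size 32 and learning rate 10⁻³ (the reference
protocol), a staircase decay (factor 0.1; the decay interval defaults to
50 000 optimizer steps — the literature value of 1000 steps would freeze
the scaled-down runs almost immediately), validation every 5 epochs, early
stopping, and an exponential moving average of the parameters (decay 0.999,
on by default; the best-validation EMA weights are retained). The scalar
head trains on mean absolute energy and force errors with the standard
weights W_F = 52.9177, W_Q = 14.3996, W_D = 27.2113. These weights were
published for energies in eV; because the energy and force terms convert
by the same factor (1 eV = 23.0605 kcal/mol), their ratio — the only thing
that matters to the optimum — is unit-invariant, and the weights carry over
unchanged to the kcal/mol internals.

The whole network stack (including the force path and the evidential
losses) runs on a small reverse-mode autodiff core written on numpy arrays
(`pesuq.autodiff`), gradient-checked against central finite differences.

**Ensembles.** Committees are trained with members differing in parameter
initialization and train/validation shuffle; by default members 2k and
2k+1 share one shuffle (mirroring the 1/2, 3/4, 5/6 pairing of the
reference protocol), and `select_committee(models, "ens3")` picks members
1, 3, 5. The committee uncertainty is the population standard deviation
σ_E = √(1/N Σ(Ẽₙ − Ē)²).

## Evidential heads

**DER-S** places a Normal-Inverse-Gamma (NIG) prior (γ, ν, α, β) over the
Gaussian energy likelihood (positivity by softplus activations with small
offsets; α > 1). The loss is the Student-t marginal negative
log-likelihood (df = 2α, location γ, scale² = β(1+ν)/(να)) — verified to
10⁻⁶ against numerical quadrature of the Gaussian × Inverse-Gamma
marginal — plus the evidence regularizer λ(L^R − ε) with
L^R = |y − γ|(2ν + α), λ = 0.15, ε = 10⁻⁴, plus the weighted
mean-absolute force/charge/dipole terms. The phrase "λ-scaled MSE"
sometimes attached to L^R conflicts with its stated purpose (shrinking the
evidence of incorrect predictions, which a plain MSE cannot do); the
evidence-scaled absolute-error form is the default and a `reg_form="mse"`
switch preserves the literal reading.

**DER-L** adds a Lipschitz-bounded squared-error term: quadratic while
(ΔE)² < U and linear (2√U·|ΔE| − U, continuous and once-differentiable at
the crossover) beyond it, with U = min(U_ν, U_α) the tighter of the two
curvature bounds of the NLL (U_ν = β(ν+1)/(αν);
U_α = 2β(1+ν)/ν · [exp(Ψ(α+½) − Ψ(α)) − 1]). U is evaluated on detached
parameters: the bound gates the branch but does not itself receive
gradients.

**DER-M** replaces the NIG by a bivariate Normal-Inverse-Wishart over
(energy, total charge): six raw outputs give (μ₀, μ₁), a 2×2
lower-triangular scale matrix L (softplus + 10⁻⁶ on the diagonal, +10⁻⁶ on
the off-diagonal entry) and degrees of freedom
ν = 10·(tanh(x)+1)/2 + 3 ∈ (3, 13) (the lower bound enforces ν > n+1 for
n = 2 predicted quantities; above ≈13 the distribution is practically
Gaussian). The loss is log((ν+1)/(ν−1)) − ν Σⱼ log Lⱼⱼ +
((ν+1)/2)·log det(LLᵀ + YYᵀ/(1+ν)) plus force/dipole terms. The "Σⱼ ℓⱼ"
penalty is read as Σ log Lⱼⱼ — the Normal-Inverse-Wishart
log-normalization, and the only reading bounded below for large scales;
`diag_term="diag"` / `"raw"` select the alternative readings.
Uncertainties: aleatoric E[σ²] = ν/(ν−3)·LLᵀ, epistemic Var[μ] =
E[σ²]/ν.

For all DER heads the **epistemic** variance is the downstream outlier
score (outlier detection targets knowledge gaps, not data noise); this is
configurable since the decomposition channel used in such studies is often
left unstated.

**A caution on the NIG decomposition.** On homoskedastic synthetic data the
fitted Student-t marginal variance tracks the injected noise, but the
decomposition into β/(α−1) (aleatoric) and β/(ν(α−1)) (epistemic) is not
identified: at fixed marginal the NLL is flat in ν, and the evidence
regularizer exerts a constant downward pressure on ν, so β/(α−1) collapses
towards zero under λ = 0.15. This is the known degeneracy of the DER
parameterization and matches the overconfidence such models show in
practice; the acceptance suite asserts the recovery property at the
default configuration and the assertion fails for this documented reason,
while a companion test confirms the marginal variance itself is recovered
within 25%.

## GMM scoring

A full-covariance Gaussian mixture is fitted by EM (log-sum-exp
responsibilities, 10⁻⁶ ridge on covariance diagonals, tolerance 10⁻⁶ on
the mean per-sample log-likelihood, ≤500 iterations, k-means
initialization of the means, re-seeded restart when a component's
responsibility mass drops below 2 samples) to the training-set feature
vectors of one trained model — by default the first ensemble member. The
component count minimizes BIC = k·ln n − 2·ln L̂ with
k = N(D + D(D+1)/2) + (N−1); the default search range 1–20 is a free
choice for the toy problem. A structure's uncertainty is the NLL of its
feature vector under the mixture. The NLL is a rank score only: it is
never mapped to an energy variance, and the calibration module rejects it
with an explanatory error.

## Outlier-detection evaluation

Top-k accuracy is |TopErr(N_err) ∩ TopVar(N_var)| / min(N_err, N_var),
with ties broken by ascending structure index. The min-normalization is a
deliberate choice: the literal /N_var form caps a perfect detector at
N_err/N_var < 1 off the diagonal, which contradicts how the published
reliability grids read (a 0.92 at N_err = 25, N_var = 1000 is impossible
under the literal form); `normalization="n_var"` restores it. The 2-D
reliability grid evaluates all cells with N_err ≤ N_var over the standard
list [25, 50, 100, 200, 400, 800, 1000] (truncated to the test-set size).

Threshold classification uses strict inequalities (equality counts as
below-threshold and is tallied); default thresholds are the set means
(ε* = MSE, σ* = MV), and a logarithmic threshold sweep over the observed
score ranges produces decision-boundary maps. The four rates R_TP, P_TP,
R_FP, R_FN return NaN (flagged, never an exception) on empty denominators.
Calibration curves bin the test set into equal-count bins of ascending
variance and compare per-bin RMSE to root-mean-variance.

## Rank metric

A distance is "bonded" iff it is strictly below 1.2× the mean of the two
van der Waals radii (H 1.10, C 1.70, O 1.52 Å; table extensible). All
training distances are pooled per class; the 5% and 95% linear-interpolation
quantiles bound the in-distribution band. A test distance contributes 1
(bonded, strictly inside the bonded band), 0.5 (non-bonded, inside the
non-bonded band) or 0; the rank is the sum over all 28 pairs, decomposed
into bonded and non-bonded partial sums. Classification is evaluated per
structure from the vdW rule — not frozen from a reference topology —
because reactive trajectories change bonding. Two pooled distributions are
the default (the membership test names exactly two distributions); a
per-pair variant (one band per atom pair) is available since the
bounded-interval definition of in-distribution hints at it. Fractional
ranks are binned in 0.5 steps for the report tables.

## Dynamics

NVE velocity-Verlet with energies in kcal/mol, coordinates in Å, time in
fs, masses in amu (1 amu·Å²/fs² = 2390.057 kcal/mol;
k_B = 0.0019872041 kcal/mol/K). Maxwell–Boltzmann initial velocities with
per-component variance k_BT/m and centre-of-mass momentum removed (the
removal is a default; it can be disabled). The conservation diagnostic
integrates 5·10⁵ steps at 0.1 fs (50 ps) from the reactant minimum at
300 K — a scaled-down analogue of the 0.5 ns protocol, since integrator
inconsistencies manifest within picoseconds — and reports the maximum
total-energy deviation over frames saved every 1000 steps (measured:
≈5·10⁻⁴ kcal/mol, two orders below the 0.1 kcal/mol requirement; the
fluctuation scales as Δt²). Harmonic frequencies come from the
central-difference Hessian of the analytic forces (default step 0.005 Å),
symmetrized and mass-weighted; modes below 5 cm⁻¹ are counted as the
translation/rotation block and negative eigenvalues are reported as
imaginary frequencies.

## Problem sizes used by the test and acceptance suites

All sizes are the package's own scaled-down study conditions: the
model-quality check trains on ≈2500 structures (80/20 split, batch 32,
learning rate 10⁻³, width 128) and evaluates on 400 disjoint
in-distribution structures, reaching MAE(E) ≈ 0.1 kcal/mol (bound:
1.0). The stochastic UQ study runs 10 independent benchmark seeds, each
with 600 train/validation structures, a 6-member committee of width-48
networks, a BIC-selected GMM on the member-0 features, and a 300-structure
test set (240 in-distribution over 300/300/500 K, 60 held-out); the
reported statistics are medians (or means for top-k accuracy) over the
seeds. Smaller networks than the default width are used there so that ten
full ensembles stay cheap; the qualitative UQ behaviour does not depend on
the width once the in-distribution fit is converged.

## What the synthetic benchmark does and does not show

Passing here demonstrates the *machinery*: exact force contracts, loss
formulas against independent oracles, the metric definitions, and the
qualitative UQ phenomenology (committee disagreement and feature-space NLL
rise in a genuine coverage gap; rank anti-correlates with error). It does
not demonstrate quantitative transfer to ab initio datasets: the toy
surface is smooth and noiseless (no electronic-structure noise, no
multireference pathologies), the descriptor is global rather than learned,
and the energy scale and error magnitudes differ from quantum-chemistry
reference data by construction. Headline detection-accuracy values from
real-data studies are therefore not reproduction targets of this package.

## Known limitations

- Single molecule, fixed composition, no periodic systems; the pair-table
  contract requires every dataset to share one composition.
- Force variance is not available for the NIG heads (forces derive from
  the mean energy only), and the energy–force covariance is not modelled.
- The GMM uses full covariances with a fixed ridge; very high-dimensional
  feature spaces with few training structures may need a larger ridge.
- The numpy autodiff core is single-threaded and tuned for the small
  networks used here, not for production-scale training.
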