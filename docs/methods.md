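# Methods

## Fiber-diameter models

Both models map the five electrospinning covariates — concentration
(% w/v), flow rate (cc/h), voltage (kV), needle–collector distance (cm),
collector speed (rpm) — to mean fiber diameter (nm).  They are
interpolation models over a 29-run design; neither should be extrapolated
far outside the design ranges (concentration 10–12 %, flow 0.1–0.6 cc/h,
voltage 12–30 kV, distance 8–12 cm, speed 200–2500 rpm).

### Covariate encoding

Concentration enters the polynomial model as a mass fraction (10 % →
0.10); the other covariates enter in their natural units.  The fraction
encoding is forced by the published model itself: its `502124·X1⁴` term
contributes a physically sensible ~50 nm only for X1 ≈ 0.1, and with that
reading the model predicts sample 1 at 135.1 nm against a measured
134.19 nm.  The encoding is an explicit, overridable affine map on the
model object rather than a hidden convention, and the design-table fixture
stores concentration as printed (percent).

### GMDH polynomial network

A model is a short stack of polynomial neurons.  Each neuron is a
polynomial over a subset of its available inputs (encoded covariates
and/or earlier neurons); the candidate term family is the constant plus
pure powers x^k, k = 1..`max_degree` (default 4) — the family spanned by
the published model, which uses X1⁴, X3², X2⁴ and N1³ but no
cross-products.

Training is classic self-organizing GMDH with some small-sample
hardening:

* **Structure selection.** For each input subset (size ≤ 5), terms are
  added greedily; a term set is scored by the squared error on held-out
  *selection* rows of coefficients fitted on the complementary *fit* rows.
  The score is averaged over 5 random 70/30 fit/selection partitions plus
  5 "extreme-holdout" partitions that hold out the rows farthest from each
  covariate's median.  A single random partition of 20 training rows makes
  the criterion so noisy that term stacks which memorize the 6 selection
  points survive; the extreme-holdout partitions additionally penalize
  candidates whose high-degree terms misbehave toward the design edges.
* **Conditioning guard.** Regressor columns are standardized internally
  and any fit whose standardized coefficients exceed 2·std(y) is rejected.
  Near-collinear power stacks (x, x², x⁴ with huge cancelling
  coefficients) fit the training hull and explode outside it; the cap
  removes them without biasing ordinary fits, whose standardized
  coefficients are at most ~std(y).
* **Coefficient estimation.** Once a structure is accepted, its
  coefficients are refitted by ordinary least squares on the whole
  training sample — the external criterion chooses *structure*, all data
  estimates *parameters*.
* **Growth and stopping.** The best `max_neurons_per_layer` (3) neurons
  survive per layer and join the input pool of the next; growth stops
  after `max_layers` (3), when a layer fails to improve the best selection
  error by ≥ `min_improvement` (2 %), or when the error reaches the
  numerical floor (exact fit).  Ties rank by fewer terms, then
  lexicographic input names, making builds deterministic for a given seed
  and dataset.

Noiseless data generated from any member of the candidate family is
recovered exactly (training MSE at the numerical floor, coefficients to
better than 6 significant digits).  On the 29-run design, 70/30 training
typically generalizes at single-digit held-out MARD; a known limitation is
that some splits strip an entire corner of the design (e.g. every
high-collector-speed run) and no quartic-family model fitted on the
remaining hull predicts that corner within 10 % — an instance of the
general rule that these models do not extrapolate.

### Feed-forward network

One hidden layer of logistic units and a linear output.  Diameters are
affinely scaled to [0.1, 0.9] (so are inputs, from their training
ranges); the linear output keeps regression targets unbounded while the
hidden deltas retain the O(1−O) sigmoid-derivative form.  Biases are
weights from a constant-1 input.  Weights start uniform in [−0.5, 0.5]
under the configured seed.

* **Back-propagation** runs in batch mode (sum over patterns) by default,
  matching the batch squared-error objective and keeping runs
  deterministic; a per-pattern online mode is available behind a flag.
* **Levenberg–Marquardt** (the default) solves
  (JᵀJ + λI)Δ = Jᵀr on the full Jacobian, computed analytically by the
  same backward recursion as the deltas; λ starts at 10⁻³, ×10 on a
  rejected step, ÷10 on an accepted one.  Training stops on relative MSE
  improvement below `convergence_tol` or `max_iterations` (default 300);
  the best-seen-MSE model is returned.
* **Architecture selection.** The hidden size is not dictated by theory;
  with `hidden_sizes=None` it is picked from {3,…,10} by error on an
  internal 80/20 holdout of the training set, then the winner is retrained
  on the full training set.

The gradient computation is verified against central finite differences
(10⁻⁶ relative, random 5-3-1 networks) — the core correctness oracle for
the delta recursions.

### Accuracy metric

MARD% = (100/N)·Σ|d_obs − d_pred|/d_obs.  One source prints this formula
with a 1/100 prefactor and no 1/N; that normalization cannot produce a
few-percent MARD from ~29 few-percent deviations and is treated as a typo
— the 100/N form used here is the standard definition and the one
consistent with the reported accuracies.  Evaluating the frozen published
polynomial over all 29 design runs gives MARD 3.32 %; the reported figure
for that model is 3.56 %, and since the original train/test membership was
never published, the all-sample evaluation is the only deterministic
reconstruction (the gap is consistent with the figure having been computed
on a subset).  Trained LM networks reach best-seed full-data MARD ≈ 0.9–1.6
across 20 seeds against a reported 2.28 % — reproducible in distribution
only, since the original topology, iteration count and split are unknown.

## Synthetic data

`generate_dataset` samples covariates uniformly and independently in the
design ranges and adds Gaussian noise (`noise_sd`, default 0) to a
configurable polynomial ground truth, truncating diameters below at 1 nm
(after noise) to avoid non-physical values at high noise.  A grid mode
reuses the 29 printed covariate rows and regenerates only responses.

What this emulates: the covariate ranges, response scale and noise level
of the real design.  What it does not: the real design's hand-picked
one-factor-at-a-time structure (uniform sampling is the neutral choice for
recovery tests), correlated measurement error, batch effects, or any
electrospinning physics (no jet dynamics).  Passing recovery tests
therefore certifies the *estimators*, not the physical truth of any
particular fitted model.

## Oxygen transport

Geometry is one-dimensional in depth: lateral boundaries are zero-flux,
so the dressing–skin problem reduces to x ∈ [0, L1+L2] with the surface
at x = 0.  The dressing (0 < x < L1) only diffuses; the skin
(L1 < x < L1+L2) diffuses and consumes oxygen with Michaelis–Menten
kinetics v_m·c/(k_m+c), which reduces to first-order k·c for c ≪ k_m and
to a constant sink v_m for c ≫ k_m.  Boundary conditions: c = C_atm at
the surface, flux continuity at the interface, zero flux at the bottom.

### Parameters

| parameter | default | note |
|---|---|---|
| D_skin | 2.54×10⁻⁵ cm²/s | literature oxygen diffusivity for tissue |
| D_wd | 2.54×10⁻⁵ cm²/s | electrospun mats are highly porous and not a barrier; independently configurable |
| k_spec | 3.33×10⁻⁵ s⁻¹ | literature specific consumption rate; its units match first-order kinetics, so `first_order` is the default mode and Michaelis–Menten requires explicit v_m, k_m |
| L1 | 0.01 cm | a ~100 µm electrospun mat |
| L2 | 0.2 cm | full-thickness skin scale |
| C_atm | 0.2 | typical dissolved-oxygen concentration scale (mol m⁻³); the first-order problem is linear in c, so results scale with C_atm |
| initial | 0 | anoxic tissue when the dressing is applied |
| t_end | 86 400 s | one day of wear |

### Discretization

Node-centred finite volumes with a node pinned exactly at the interface
(the node's half-volumes carry their own layer's diffusivity, and only the
skin half consumes).  The flux balance at that node enforces interface
flux continuity exactly at steady state.  Time stepping is backward Euler
(unconditionally stable; first-order in time), with the nonlinear sink
solved per step by Newton iteration on an analytic tridiagonal Jacobian,
tolerance 10⁻¹⁰·C_atm on the Newton update.  The Newton step is damped by
residual-monitored halving, and a step that still stalls is retried as two
half steps (recursively, ≤ 12 levels) — needed only in the strongly
saturated Michaelis–Menten regime k_m ≪ c, where the sink is nearly
discontinuous at c = 0.

Verification: the first-order steady state has a closed form (linear
profile in the dressing joined to a cosh profile of decay length
√(D_skin/k) in the skin, flux-matched at the interface); the time stepper
marched to steady state matches it to ~10⁻⁹·C_atm at nx = 201 and
converges at second order in the mesh (observed orders ≈ 2.00 over
nx = 22→169).  Maximum-principle bounds (0 ≤ c ≤ C_atm), the
Michaelis–Menten→first-order and →zero-order limits, and one-sided
interface-flux agreement are asserted in the test suite.

`solve_to_steady` marches with geometrically growing steps (backward
Euler tolerates arbitrarily large dt) until max|dc/dt| < 10⁻¹²·C_atm/s.

### Limitations

Only depth is resolved: no 2-D/3-D wound geometry, no moisture or heat
coupling, no cell-population dynamics, no microstructure-resolved
diffusivity.  Numerical Michaelis–Menten constants are not bundled (the
literature values are system-specific); the first-order default with the
stated specific consumption rate is the documented operating point.

## Problem sizes

The test suite and the acceptance script run the 29-row design table
throughout; synthetic recovery uses 20–40 rows; PDE verification uses
nx = 22–201 with one-day horizons; network training uses ≤ 300 LM
iterations and 20 seeds.  These sizes keep the full suite around a minute
on one CPU while leaving every numerical check comfortably away from its
tolerance.
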