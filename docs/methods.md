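# Methods

This note documents the models, numerical choices and synthetic-data design
behind `mousebrainsim`, in the spirit of a simulator's model reference.

## Tracer-based connectome construction

A connectome is assembled from anterograde tracer injection experiments.
Each experiment injects one right-hemisphere structure and reports, per
target structure and laterality, a *projection density* (detected pixels in
the target normalized by the target's pixel count) and a *projection
energy* (detected intensity normalized the same way); the experiment also
carries its *injection density* (fraction of source voxels infected) and
infected-voxel count.

Pipeline stages:

1. **Clean to square.** The structure universe is restricted to the
   intersection of injection structures and target structures so the
   connectome is a square matrix.
2. **Filter.** A structure is retained only if its volume is *strictly*
   greater than `min_region_volume_mm3` (default 2 mm³) and at least one
   injection into it infected *strictly* more than `min_infected_voxels`
   voxels (default 50).  Both inequalities are strict, matching the ">"
   wording of the reference configuration; the set is re-cleaned to square
   afterwards.
3. **Weights.** Connection strength is one of three definitions:
   projection density, projection energy, or density divided by the source's
   injection density (the default).  The weight of a pair (i, j) is the
   arithmetic mean over all experiments injecting i that *report* target j.
   An unmeasured pair is treated as absent — it contributes nothing to the
   mean's denominator — and a pair with no measurements at all gets weight
   0.  Averaging zeros in would conflate "unmeasured" with "no projection".
   Ipsilateral and contralateral targets are averaged in separate blocks.
4. **Mirroring.** Injections exist only for the right hemisphere; the left
   hemisphere is its mirror image.  With regions ordered right hemisphere
   first, then left (identical intra-hemisphere order), the weight matrix is
   `[[RR, RL], [RL, RR]]` and satisfies R-R = L-L and R-L = L-R exactly.
5. **Geometry.** Region centres are unweighted voxel centroids of each
   structure in the right half of the annotation volume (voxel indices
   scaled by the grid resolution — 25, 50 or 100 µm — into mm); left centres
   are their mirror images across the midplane.  Tract lengths are the
   Euclidean distances between centres.  The region-volume mapping relabels
   the annotation volume with connectome row indices, −1 for background and
   excluded structures.

The diagonal of every weight matrix is forced to zero: a self-projection is
degenerate with the local recurrence term of both node models, which already
carry within-region coupling explicitly.

## Resting-state model (reduced Wong-Wang / eMFM)

Each region is one NMDA gating variable `S` with (time in ms, rates in Hz):

    dS_i/dt = -S_i/tau_s + (1 - S_i) * (gamma/1000) * H(x_i) + sigma eta_i(t)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))
    x_i     = w J_N S_i + J_N G sum_j C_ij S_j + I_0

with gamma = 0.641, tau_s = 100 ms, a = 270 nC⁻¹, b = 108 Hz, d = 0.154 s,
J_N = 0.2609 nA.  `H` is continuous and strictly increasing; at a·x = b the
removable singularity evaluates to 1/d.  Because `H` is in Hz while the
integration step is in ms, the gain term carries an explicit 1/1000.

**Local parameters and bistability.** The defaults are w = 1.0 and
I_0 = 0.32 nA.  This pair places each isolated region in the bistable
regime — a low-activity stable fixed point near S ≈ 0.10 and a
high-activity one near S ≈ 0.48, separated by an unstable root — which is
the regime in which the coupled network shows the switching, non-stationary
functional connectivity this package analyzes ("enhanced nonlinearity"
mean-field model).  A numerical root scan shows that with I_0 = 0.30 nA the
isolated node is *monostable* (a single stable root near S ≈ 0.04), so the
bistability that defines the model class would be lost; 0.32 nA is the
smallest round value restoring it, and both w and I_0 remain configurable.
The global coupling G = 0.096 and noise amplitude sigma = 5.1e-3 are the
reference values for resting-state runs.

`S` is a channel fraction: after every stochastic step it is clamped to
[0, 1].  The deterministic flow is forward-invariant on [0, 1] anyway
(drift ≥ 0 at S = 0, ≤ 0 at S = 1); the clamp only guards against noise
kicks across the boundary.

## Hemodynamics (Balloon-Windkessel)

The gating variable drives a vasodilatory signal s, inflow f, venous volume
v and deoxyhemoglobin q:

    ds/dt = u - kappa s - gamma_f (f - 1)         df/dt = s
    tau_h dv/dt = f - v^(1/alpha)
    tau_h dq/dt = f (1 - (1 - rho)^(1/f))/rho - v^(1/alpha) q/v
    y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))

with kappa = 0.65 s⁻¹, gamma_f = 0.41 s⁻¹, tau_h = 0.98 s, alpha = 0.32,
rho = 0.34, V0 = 0.02, k1 = 7 rho, k2 = 2, k3 = 2 rho − 0.2 — the standard
parameter set of this hemodynamic model, all configurable.  Rest
(s = 0, f = v = q = 1) is an exact fixed point with y = 0.  The neural
series is decimated to 1 ms before explicit-Euler integration to bound
cost; BOLD is then resampled to one sample per TR (2 s) over 20 min — 600
samples per region with the defaults.

## Functional connectivity and its dynamics

FC is the Pearson correlation matrix of the regional BOLD series.  The FCD
divides the series into 180-s windows overlapping by 176 s (stride 4 s;
256 windows for a 20-min series at TR 2 s) and correlates the vectorized
*strict* upper triangles of the window FCs — the diagonal FC entries are
constant 1 and would only inflate the correlation.  Windows of mutually
similar FC form blocks around the FCD diagonal: epochs of stable FC.

## Epoch segmentation by spectral embedding

The FCD is read as a weighted graph over windows.  Negative entries are
clipped to zero (a signed Laplacian would lose positive semidefiniteness);
with W the clipped FCD, L = D − W, and L⁺ the eigendecomposition
pseudoinverse with null modes zeroed, the commute distance is

    c_ij = vol(V) (e_i - e_j)^T L+ (e_i - e_j),   vol(V) = sum_ij w_ij,

the expected number of steps of a random walk from window i to j and back.
The embedding is defined as z_i = sqrt(vol) · (row i of U (Λ⁺)^(1/2)), which
makes ||z_i − z_j||² = c_ij an exact identity — verified against an
independent commute-distance computation in the tests.  (Taking the square
root of Λ⁺ and the sqrt(vol) scaling is what turns the pseudoinverse
eigendecomposition into a distance-preserving map; without them the
identity fails.)  A disconnected affinity graph is an error: commute
distance is undefined across components.

Windows are then clustered with seeded k-means (50 restarts) on the leading
embedding coordinates.  The number of clusters, when not fixed, is the
position of the largest Laplacian eigengap, capped at 6.  Cluster labels
are smoothed so only maximal contiguous runs of at least 3 windows survive;
the runs are reported as epochs (the raw per-window labels are also kept,
since a cluster may in principle recur in disjoint runs).

**Boundary resolution.** A 180-s window sliding by 4 s means roughly 45
windows straddle any true switch point, and their FCs interpolate between
the flanking states.  Even for noise-free, analytically mixed window FCs
the k-means assignment flips a few strides away from the true switch when
epochs are asymmetric.  Detected boundaries are therefore meaningful to
about one window length — the method's intrinsic resolution — and that is
the tolerance the recovery tests assert.

## Functional hubs

Hubs follow the eigenvector-centrality reading of the FC matrix: for the
three largest eigenvalues, a region is a hub of eigenvector phi if
|phi_i| ≥ frac · max_j |phi_j| (frac = 0.5 by default; with frac = 1 only
the argmax region survives).  Each eigenvector's sign is fixed so its
largest-magnitude component is positive.  An eigenvalue tie at the cut is
flagged and all tied vectors are reported.  Hub maps can be painted onto
the region-volume mapping (|component| inside the parcellation, −1
outside) for NIfTI export.

## Seizure model (networked Epileptor)

Six state variables per region — fast ensemble (x1, y1), slow permittivity
z, spike-wave ensemble (x2, y2), and the low-pass memory g:

    dx1/dt = y1 - f1(x1, x2, z) - z + I1
    dy1/dt = 1 - 5 x1^2 - y1
    dz/dt  = r (4 (x1 - x0) - z - 0.1 z^7 [z<0]) + Ks sum_j C_ij (x1_j - x1_i)
    dx2/dt = -y2 + x2 - x2^3 + I2 + 0.002 g - 0.3 (z - 3.5)
    dy2/dt = (-y2 + f2(x2)) / tau
    dg/dt  = x1 - gamma_g g

    f1 = x1^3 - 3 x1^2                 if x1 < 0
       = (x2 - 0.6 (z - 4)^2) x1       if x1 >= 0
    f2 = 0                             if x2 < -0.25
       = 6 (x2 + 0.25)                 if x2 >= -0.25

with I1 = 3.1, I2 = 0.45, tau = 10, gamma_g = 0.01, Ks = −60, and the slow
timescale r = 3.5e-4 (the conventional permittivity value; configurable).
The 0.1 z⁷ term applies only for z < 0, and the network enters through the
permittivity coupling — weighted differences of the fast variables — in the
z equation.  The per-region epileptogenicity x0 decides autonomy: bisection
on the isolated, noise-free node locates the equilibrium → spontaneous-
seizure transition at |x0| ≈ 2.06; x0 = −1.9 yields recurrent onset-offset
cycles, x0 = −2.1 rests at equilibrium and can only be recruited.

**Coupling scale.** The permittivity coupling enters dz/dt *directly*, not
scaled by r.  Since r ≈ 3.5e-4 while |Ks| = 60, the product of Ks, a row
sum of C and an order-one x1 difference must stay comparable to the r-scale
terms for the slow variable to remain in its working range; in practice
network weights of order 1e-5 give physiological recruitment, while weights
of order one drive z through the steep z⁷ guard and the integration
diverges (reported with a step/region diagnostic).  Synthetic seizure
connectomes are scaled accordingly.

**Integration.** Stochastic Heun at dt = 0.04 ms; additive white Gaussian
noise of variance 0.0025 on x2 and y2 only (the same Wiener increment in
predictor and corrector).  Signals are down-sampled to 1 ms; the monitored
local field potential is −x1 + x2, kept together with z.

**Initial conditions.** Each node starts from its own deterministic
relaxation (5 s, coupling and noise off, one relaxation per distinct x0
value): sub-critical nodes reach their equilibrium, epileptogenic nodes
land on their autonomous cycle, and seizures in the network emerge from the
dynamics rather than from initial transients.

**Onset detection.** A node's seizure onset is the first time x1 exceeds a
threshold and stays above it for ≥ 100 ms.  The generic analysis function
defaults to threshold 0; the seizure pipeline defaults to −0.5, because
with the reference noise level the ictal fast discharges dip below zero
often enough that sustained super-zero runs hover right at the 100-ms dwell
limit, whereas −0.5 separates cleanly the interictal level (≈ −1.4) from
the ictal oscillation range.  Both are configurable.  A region group's
onset is the mean over member nodes (never-seizing nodes are flagged absent
and excluded); latencies are reported relative to the epileptogenic zone's
onset.  The epileptogenicity *classifier* used for the boundary bisection
instead smooths x1 over 100 ms and requires a complete rising-falling
crossing of −0.8 — a cycle detector, not an onset timer.

## Integrators and reproducibility

Euler-Maruyama (default for the mean-field model, dt 0.1 ms) and stochastic
Heun (default for the Epileptor, dt 0.04 ms) are fixed-step schemes.  Two
noise conventions are supported and logged: `wiener_sigma` (an increment is
sigma·sqrt(dt)·xi — the default, reading the drift's sigma literally as an
SDE amplitude; the Epileptor's "variance 0.0025" becomes sigma = 0.05) and
`tvb_nsig` (sqrt(2·nsig·dt)·xi).  All randomness flows from one seeded
PCG64 generator with draws in fixed (step, variable, region) order, so
results are independent of chunking; identical seeds give bit-identical
series.  The hot loops are JIT-compiled with numba, with equivalent pure-
Python fallbacks.  Non-finite states abort the run with the step and region
identified.

## Synthetic data: what it emulates, what it does not

* `make_connectome` — modular nonnegative weights with *exact* hemispheric
  block symmetry and mirrored centres.  It emulates the structure of a
  mirrored tracer connectome, not the statistics of real projection
  strengths (no log-normal tail, no distance dependence).
* `make_tracer_set` — experiment records constructed by inverting the
  builder's averaging: per source, strengths truth·(1 + eps_k) with eps
  summing to zero, so the built weights equal the planted matrix exactly
  under the density-over-injection definition.  Distractor structures
  violating the volume or infected-voxel thresholds exercise the filters.
  It reproduces the record *schema*, not imaging artifacts, registration
  error, or cross-laterality leakage.
* `make_switching_bold` — piecewise-stationary one-factor Gaussian series:
  region i is loading·pattern(i)·f(t) plus idiosyncratic noise, with ±1
  patterns that flip sign on half the regions between states.  Correlation
  switches are instantaneous and states are strongly separated; real BOLD
  drifts, mixes states and has autocorrelated noise.  Passing segmentation
  tests therefore demonstrates correctness of the FCD/embedding/clustering
  chain, not field performance on scanner data.
* `make_onset_series` — baseline at −1.6 then a supra-threshold oscillation
  from the scheduled onset; recovery to within one sample validates the
  onset timer, nothing more.

All generators are pure functions of (parameters, seed).

## Problem sizes in the tests

The shipped tests and examples run minutes-long simulations on networks of
4-16 regions (e.g. 2-6 min of resting state, 20-60 s of seizure dynamics,
20-min synthetic BOLD), which exercises every code path at full numerical
fidelity (the integration steps are never coarsened).  The reference
configuration — 20-min resting-state runs on a ~100-region tracer
connectome — uses the same code with larger inputs.

## Known limitations

* Tract-length-based conduction delays are stored but not used by the
  coupling (undelayed interactions only).
* The builder consumes pre-extracted records; it does not reproduce image
  registration or segmentation of the raw tomography data.
* Commute-distance segmentation requires a connected (clipped) FCD graph;
  strongly anticorrelated window sets can only be segmented because
  transition windows bridge the states.
* The Balloon-Windkessel stage is wired to the mean-field gating variable;
  for the Epileptor the driving quantity is left to the caller (any scalar
  per-region series is accepted).
* No adaptive step-size control; stability is the user's responsibility
  when parameters leave the reference ranges (diagnostics name the failing
  step and region).
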