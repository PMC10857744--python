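# Methods

`necrosim` implements two mechanistic models of how a brain metastasis (BM)
behaves after stereotactic radiosurgery (SRS), together with the
growth-exponent analysis that separates the two clinically confusable
outcomes: tumor recurrence and radiation necrosis (RN, an inflammatory
reaction of the irradiated brain that mimics regrowth on MRI).

## The growth exponent

All classification rests on the simplified Von Bertalanffy law

    dV/dt = alpha * V^beta.

`beta < 1` is sublinear growth (decelerating; a surface-limited front gives
2/3), `beta = 1` exponential, `beta > 1` superlinear ("explosive") growth.
Three observations `(t_i, V_i)` determine `(alpha, beta)` exactly: after
eliminating `alpha`,

    [1 - (V1/V0)^(1-beta)] / [1 - (V2/V0)^(1-beta)] = (t1-t0)/(t2-t0),

solved by bracketed root finding (`brentq` on an `expm1` form that is
continuous through the removable `beta = 1` singularity; exactly
exponential triples are detected first and return `beta = 1`).  The
identity depends only on volume ratios and time differences, so estimates
are invariant under volume rescaling and time shifts; both invariances are
property-tested.  Default bracket `[-2, 5]`, expanded geometrically up to
four times; a triple with no bracketed root (e.g. volumes returning exactly
to `V0`) is reported as non-converged rather than silently dropped.

For simulated lesions the exponent is estimated the way clinics image
patients: observation triples are drawn at random (either `t0` in
(180, 195) days post-treatment with 80–100-day gaps — the *windowed*
scheme — or one time per equal third of a configured window — *slotted*),
volumes are read off the simulated curve by linear interpolation, and the
reported `beta_hat` is the median over 20 triples of the estimates that
converged.  Measured volumes are floored at 0.05 cm^3 before fitting,
the approximate detection/segmentation limit of contrast-enhanced MRI;
without a floor, a lesion re-emerging from complete response produces
arbitrarily large volume ratios that the estimator maps to spurious
sublinear exponents.

## Compartmental model of radiation necrosis

Three populations from the first post-treatment MRI (t = 0, ~3 months
after SRS):

    dT/dt = rho * T
    dN/dt = H(t) - lambda_N * I * N
    dI/dt = gamma * N + theta * I - lambda_I * I

Tumor cells `T` regrow exponentially.  Necrotic cells `N` are fed by
`H(t) = k (tanh(t_N - t) + 1)/2`: healthy cells lethally damaged by SRS die
when they attempt renewal, at an approximately constant rate during the
renewal window `t_N = 60` days and not after (the tanh argument is the
remaining window in days; the integral of `H` is ~`k t_N`).  Immune cells
`I` are activated by necrosis (`gamma N`) and self-amplify (`theta I`)
against a fixed death rate `lambda_I = 0.07`/day (a two-week effector
half-life).  The MRI-visible volume is `(T + N + I) / cell_density`.

The death intensity `k` follows from lesion geometry: the irradiated
margin is a 1 mm shell around a sphere of the initial volume, so
`k = 4 pi r^2 * w * cell_density / 60`.  The thin-shell form (surface times
width) with a single global density of 5.1e4 cells/mm^3 reproduces all five
reference per-lesion intensities of the bundled RN-cohort anchors within
0.8%; the exact outer-minus-inner shell does not admit any single density
(back-solved values spread ~9%), which identifies the thin-shell form as
the generating model.

Numerics: LSODA with analytic Jacobian, rtol 1e-8, atol 1 cell.  An
explicit scheme is unusable here — once `I` is large the clearance term
gives `N` a relaxation time `1/(lambda_N I)` that can reach 1e-10 days,
i.e. the system becomes genuinely stiff.  Populations are clipped at zero
for reporting only.  With `theta > lambda_I` the immune pool grows without
bound; the model is integrated as specified over finite horizons only.

Per-lesion fitting minimizes the sum of squared volume residuals over
`(lambda_N, gamma, theta)` with Nelder–Mead on log10-transformed parameters
(the rates span ten orders of magnitude), `rho` fixed from the first two
observations and `k` from the shell rule.  `theta` and `gamma` are well
identified; `lambda_N` is practically unidentifiable from volumes alone
(clearance barely changes the total) and its fitted value should not be
over-interpreted.

The randomized RN sweep draws, per initial volume on a 0.5–3.0 cm^3 grid,
500 parameter sets uniformly from the fitted-cohort ranges
(`lambda_N` in [1.8, 2.4]e-11, `gamma` in [1.8, 2.1]e-7, `theta` in
[0.14, 0.25] per day) and `rho` uniformly in [0.003, 0.0075]/day — the
span of the anchor lesions' observed pre-treatment rates.  (A fixed large
`rho` of 0.07/day, the value of the package's worked single-trajectory
example, makes every event exponential, `beta ≈ 1`, and cannot produce the
superlinear regime; the patient-like range does.)  Each event is simulated
for 9 months, observed at one random time per 3-month slot, and inverted
to a growth exponent.  Medians per volume land at 1.55–1.75 with roughly
two thirds of all events inside (1, 2).

## Discrete stochastic voxel simulator

State: an `L x L x L` lattice (1 mm voxels, L = 60) of integer counts for
six populations — tumor, necrotic, healthy, damaged tumor, immune, damaged
healthy — with carrying capacity `K = 2e5` cells per voxel; immune cells
count toward occupancy with weight `q = 3/2` (activated immune cells are
~50% larger).  Every 4 h step, event counts are binomial draws per voxel
and population with probabilities `dt/tau` modulated by occupancy: division
is space-limited, migration crowding-driven, tumor death switches on above
75% occupancy (hypoxia), healthy displacement above 45%; immune activation
scales with the necrotic-to-immune ratio and free space, clearance with the
inverse ratio.  All draws in a step use start-of-step counts; removals are
clamped to the drawn population; migrating cells spread over the 26 Moore
neighbours with weights 1 : 1/2 : 1/3 (face : edge : vertex), renormalized
at the lattice boundary, and arrivals into voxels already at weighted
capacity stay where they came from (each voxel holds at most ~K cells).

Radiosurgery: per voxel the undamaged tumor survival is
`S_f = clip(Sf_hat * tanh(10 (n_n - 0.45 K)/K), 0, 1)` — only hypoxic,
necrosis-rich voxels shelter survivors.  Of the non-survivors a fraction
`eps` dies immediately, the rest become damaged cells that die by mitotic
catastrophe with constant hazard `dt/(k tau_tp)` (mean delay of two cell
cycles).  Healthy cells inside the irradiation field — the tumor-occupied
region dilated by one voxel, the standard 1 mm clinical margin — survive
with probability `Sn`; the complement becomes damaged healthy tissue that
dies much later, with hazard `P_hd = tanh((t - k tau_hr)/(2 sigma))/2 + 1/2`
centred on the k-th renewal attempt (~390 days).  Immune cells are seeded
at SRS at 10% of the pre-damage healthy count in the shell around the
tumor; seeding after the damage draw would make the immune response weakest
exactly when healthy damage is largest, inverting the necrosis mechanism.

Lesion volume is the number of voxels whose weighted occupancy exceeds
0.45 K, in mm^3 — a proxy for contrast enhancement at high cell density.
Background brain tissue sits at 0.35 K (the value is not biologically
pinned; anything below the 0.45 K imaging threshold behaves equivalently),
so intact brain reads as zero volume.

### Free parameters resolved here

* `tau_hm` (healthy displacement time) is not tabulated; it defaults to
  the tumor migration time `tau_tm`.
* `sigma` (the compression parameter of the delayed healthy-death step)
  has no published value.  It is set to 800 h, which places the bulk of
  the delayed death wave at ~6–9 months post-SRS — between the
  compartmental model's own placement of healthy-cell death (the 60-day
  renewal window starting ~3 months post-SRS) and the 13-month midpoint
  of the hazard step, and inside the clinically reported RN onset window.
  Because death is driven by the accumulated hazard, the wave completes
  well before the nominal 390-day midpoint for any sigma of this order.
* The 45% volume rule counts immune cells with weight `q`, consistent
  with their enlarged activated size.

### Engine

The implementation is vectorized numpy over a compacted index of *active*
voxels — those that can generate an event (tumor, damaged, immune or
damaged-healthy cells present, or displaced healthy tissue above 0.45 K).
Necrotic-only and background voxels have no event with non-zero
probability until immune cells reach them, so skipping them is exact; the
cost scales with occupied voxels, not lattice size.  Migration is sampled
per cell (categorical direction) for sparse sources and as a batched
multinomial for dense ones — both exact.  Two forms of temporal
coarse-graining keep the large diffuse halo of stray cells cheap: *micro*
voxels (non-background cells below 2.5% of capacity, plus immune-only
voxels of any size, below the displacement threshold) are updated every
6th step, and
immune death/migration every 2nd step, always with exactly compounded
per-event probabilities `1 - (1-p)^s`.  Constant-hazard processes compound
exactly; for the occupancy-modulated ones the approximation error is the
drift of the modulating occupancy over at most one day.  Full per-step
fidelity (`micro_stride = 1`, the `step()` default) is used by all
property and ledger tests.

### Desk scale

Published-scale runs (K = 2e5, L = 60) cost minutes per simulated lesion.
The desk preset divides the carrying capacity by 40 (K = 5e3) and trims
the lattice to L = 44.  Every probability depends on occupancy fractions
only, so mean dynamics, voxel-count volumes and all time scales are
unchanged; demographic noise grows ~6-fold and the per-step sampling cost
drops accordingly (~8 s per lesion life cycle).  Desk cohorts use 40
included simulations per arm, diagnostic volumes of 0.5–1.5 cm^3 and a
400-day follow-up — the estimator samples no later than day 395 — versus
200 per arm, 0.5–2 cm^3 and 420 days in the published protocol.  Lesions
whose volume never re-emerges above the detection floor after treatment
(typically small lesions whose young, oxygenated cores shelter no
surviving tumor cells) admit no exponent and are excluded, matching the
published restriction to lesions displaying post-treatment growth.

## Cohorts, inclusion and classification

Two cohorts: *no damage* (`Sn = 1`, `Sf_hat ~ U(0,1)`; all relapse, group
R) and *damage* (`Sn ~ U(0.1, 0.7)`; group I when `Sf_hat <= 0.1`, R&I
otherwise).  So that both damage sub-groups are populated, half the damage
draws take `Sf_hat` log-uniform on (1e-3, 0.1] and half uniform on
(0.1, 1).  Basal characteristic times are uniform in their tabulated
ranges, `eps ~ U(0,1)`.  Each simulation grows from 10^3 cells (0.5% of a
voxel's capacity, scaled with K) to its diagnostic volume, is irradiated,
and followed for 420 days.  Mirroring the clinical requirement of an
initial response, a simulation whose volume at day 120 exceeds its volume
at day 14 is excluded ("early growth"; day 14 rather than day 0 lets the
immediate post-treatment swell of immune activation settle).  A lesion is
also excluded if none of its 20 observation triples admits a solution of
the three-point identity — by construction these are completely resolved
lesions with no measurable regrowth, not classifiable either way.

ROC analysis treats inflammation (I) as the positive class against
progression (R and R&I): AUC by the rank (Mann–Whitney) formulation with
midrank tie handling, operating threshold by Youden's J over midpoints
between adjacent observed exponents with ties broken toward the larger
(more progression-specific) threshold.  Group comparison is a one-way
ANOVA on the exponents.  The `S_f`-bound sweep relabels the damage cohort
at bounds between 0.04 and 0.4 and re-runs the ROC.

ABC-rejection calibration of the basal rates samples from the tabulated
prior ranges, simulates pre-treatment growth, and accepts draws whose time
to diagnostic volume and early volume-doubling time fall in configurable
plausibility windows (defaults: 60–700 days and 8–150 days); priors shrink
to the accepted hull and iteration stops when the accepted fraction is
stable within 5%.  The summary statistics and windows are a design choice
of this package — exposed in `AbcConfig` — as is the stability rule.

## What the synthetic data do and do not show

The generators produce exactly the structures the estimators assume:
closed-form growth laws for the exponent solver, ODE trajectories with
multiplicative noise for the fitter, and simulator lesions for the
pipeline.  Passing tests therefore demonstrate internal consistency —
correct inversion, correct sampling distributions, conservation laws, and
that the *mechanisms* (late inflammatory swell vs. tumor regrowth)
separate in the exponent — not agreement with clinical imaging data.
Real lesions add segmentation error, inter-rater variability, irregular
scan scheduling and biological heterogeneity that none of these
generators emulate.

## Known limitations

* In this implementation the immune response clears treated lesions
  nearly completely within ~3–4 months, so simulated volumes pass through
  a deep nadir before regrowth.  The growth exponent of a curve
  re-emerging from the detection floor is dominated by the early relative
  rise, which compresses the separation between the inflammation and
  relapse groups relative to the published experiment (reflected in a
  lower optimal threshold at desk scale).  The ordering — inflammation
  grows faster than relapse — is robust.
* The compartmental model has no saturation; fitted or simulated volumes
  at late times can exceed any physical lesion size.  Only volume *ratios*
  inside the observation window enter the exponent, which is why the sweep
  remains meaningful.
* `lambda_N` is reported by the fitter but not identifiable from volumes.
* No tumor–immune attack, clonal heterogeneity, vasculature or tissue
  repair; treated-and-cleared voxels stay empty.
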