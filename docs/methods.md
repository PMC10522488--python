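# Methods

## Model and assumptions

One host-passage cycle is modelled deterministically for a homogeneous
bacterial population. The host-associated load `n(t)` (cells) obeys

    dn/dt = f·W(t) + r·n·(1 − n/(K·W(t))) − δ·n,    W(t) = g·t + W0.

Assumptions baked into this form:

* **Plate bacteria are always in excess.** Immigration into worms is
  limited only by worm biomass and the feeding rate `f`; there is no
  plate-side depletion bookkeeping.
* **Linear worm growth.** `W(t)` grows linearly with slope `g`,
  subsuming worm reproduction and development; host benefit does not
  evolve within the model. With the defaults `W0 = 10`, `g = 711` d⁻¹,
  `W` is best read as a worm-count-equivalent ("larval-equivalent
  units"): 10 worms seeded, ~2500 worm-equivalents after 3.5 days.
* **Single cycle, no spatial structure.** Only host-associated bacteria
  at `t_f` matter; serial-passage dynamics across cycles and gut spatial
  structure are out of scope.
* **Initial condition.** `n(0) = 0` by default: assay worms are raised
  on a non-colonizing food strain before exposure, so the cycle starts
  with empty hosts and the immigration term seeds colonization. This is
  a package default, configurable via `SimulationSettings(n0=...)`.

Parameters and units: all rates (`r`, `δ`, `f`, `g`) are per day; `K` is
cells per worm-biomass unit; loads are cells. Default trait bounds
(log10): `r ∈ [−1, 1.25]`, `δ ∈ [−0.5, 4]`, `K ∈ [4, 6.25]`,
`f ∈ [3, 7.5]` — spanning from a small fraction to about twice the
on-plate growth rate, microbiome half-loss times from seconds to days,
the measured order of magnitude of per-worm load, and empty-worm
colonization times from seconds to days respectively.

## Numerical solution

`solve_lifecycle` integrates with SciPy's LSODA (Adams/BDF with
automatic stiffness switching); the trait box is genuinely stiff at its
corners (`δ` up to 10⁴ d⁻¹ against a 3.5 d horizon). An analytic
Jacobian is supplied. Defaults: `rel_tol = 1e-8`, `abs_tol = 1e-6`
cells. The absolute tolerance is deliberately a small *fixed* number of
cells rather than a fraction of capacity: at low-load corners (e.g.
`f = 10³`, `δ = 10⁴`) the endpoint load is only ~250 cells, and any
abs-tolerance comparable to the state would destroy the relative
accuracy the elasticity stencils need. Nonnegativity is asserted
post-hoc (failure if `n < −abs_tol`) instead of projecting, so solver
defects surface as `IntegrationError`s naming the trait point;
excursions within tolerance are clipped to zero.

Two independent oracles cross-check the solver:

* `closed_form_linear_r0` — exact integrating-factor solution for
  `r = 0` (re-derived and verified against quadrature in the tests);
* `closed_form_logistic_constW` — logistic solution for `f = 0`,
  `g = 0` with net rate `ρ = r − δ` and effective capacity
  `K_eff = K·W0·(1 − δ/r)`, all sign branches;
* `final_load_fixed_step` — classic RK4 at a fixed step (default
  1e-5 d), sharing no machinery with the adaptive path.

## Elasticities and strategy classification

`E_x = ∂ln n_f/∂ln x` is computed by a central difference in log space,
step `h = 1e-3` (natural log), with a second stencil at `h/2` providing
a Richardson-style error estimate per component. A trait equal to zero
has elasticity exactly 0 (a multiplicative perturbation of 0 is a
no-op). Stencils at grid boundaries perturb beyond the nominal trait
range — the bounds constrain the grid, not the derivative. The dominant
strategy is the trait of maximum |E|, ties broken deterministically in
the order (r, δ, f, K), with direction "increase" for a positive
elasticity and "decrease" otherwise. Choosing |E| rather than the signed
value means a strongly negative removal elasticity reads as "decrease
δ" — increased persistence — which is the natural selection-gradient
reading.

The default sweep grid is 12 log-uniform points per axis including both
bounds (20 736 points, ~9 ODE endpoint solves per point for the value
stencils plus 8 more for the error estimates); this resolves the region
structure at desk scale in a few minutes on one CPU. The sweep is
deterministic (byte-identical CSV on re-run), records per-point failures
with a flag instead of aborting, and supports chunked/resumable and
parallel execution.

### Analytic regimes used for validation

* **Linear regime** (`r = 0`, `n0 = 0`): `n_f ∝ f`, so `E_f = 1` and
  `E_K = 0` exactly.
* **Fast turnover** (`δ ≫ r`, `n ≪ K·W`): the load tracks the
  quasi-steady value `f·W/(δ − r)`, giving `E_delta = −δ/(δ − r)`,
  `E_f = 1`, `E_r = r/(δ − r)`; since `|E_delta| > 1 > E_r` the strategy
  is (δ, decrease) throughout — persistence wins. Validation points use
  `r ≥ 0.3` so the dominance margin `~r/δ` stays well above the
  finite-difference noise floor (`~rel_tol/2h ≈ 5e-6`).
* **Near capacity** (`f·W ≪ r·K·W`, fast equilibration): the load tracks
  `K·W(t)·(1 − δ/r)` with a lag `g/ρ` in biomass units
  (`n_f ≈ K_eff·(W(t_f) − g/ρ)`, `ρ = r − δ`). The equilibrium parts of
  `E_r` and `|E_delta|` are *identical* (`δ/(r − δ)`), and the lag term
  adds `+g/(ρ·(W − g/ρ))` to `E_r` only, so `E_r` exceeds `|E_delta|`
  strictly in this regime. Consequently the four-trait dominance along a
  δ-transect switches (K, increase) → (r, increase), while the
  *K-vs-δ* comparison — `|E_delta| = δ/(r − δ)` crossing `E_K ≈ 1` —
  switches at `δ = r/2`. The validation suite checks that this crossing
  brackets `r/2` within one grid step (observed within 0.3% of `r/2` at
  the tested resolution); the r-dominated band between the K- and
  δ-dominated regions is a genuine feature of the growing-host model,
  not a numerical artefact.

## Synthetic assay generator

The generator emulates the worm-sample/supernatant structure of
dilution-plating colonization assays:

* true per-worm load = `n_f / W(t_f)` (c.f.u.s are reported per worm;
  this normalization by final worm-equivalents is a documented package
  choice — the mapping from total model load to per-worm counts is not
  otherwise pinned down);
* per-replicate lognormal noise, SD `sigma_rep` (default 0.5) on the
  natural-log scale, centred on the log truth;
* serial dilution in 10-fold steps, the plate chosen as the smallest
  dilution with ≤ 300 expected colonies (falling back to the most
  concentrated plate below 30), Poisson colony counts, CFU recorded as
  count × dilution. `plate_count_law="exact"` gives the infinite-count
  limit used by noiseless recovery tests. Zero expected colonies at
  every dilution sets a `zero_expected` flag rather than a silent 0;
* optional residual background (`background_cfu`) appearing in both the
  worm sample and the supernatant, cancelled by the background
  subtraction;
* defaults follow the assay design: 5 worms per replicate, 6 replicates.

The two-strain competition generator integrates the shared-capacity
system `dn_i/dt = f_i·W + r_i·n_i·(1 − (n₁+n₂)/(K·W)) − δ_i·n_i` (common
`K` required). This is purely a data-generating device — a minimal
symmetric extension for producing co-colonization tables — and is never
used to support any dynamical claim. The optional release design
records `release_fraction` (default 0.1) of the per-worm load into a
second supernatant; the fraction is likewise a synthetic device, since
no release dynamics are modelled.

What the generator does *not* emulate: morphotype diversification,
worm-to-worm load heterogeneity within a replicate, pipetting/dilution
volume errors, plate miscounting, or correlated replicate noise between
co-colonizing strains. Tests passing on these tables therefore establish
correctness of the metrics pipeline under the stated noise model, not
robustness to every feature of real assay data.

## Assay statistics

`cfu_per_worm` and `released_per_worm` floor negative differences at 0
and set an explicit flag (counts cannot be negative; the convention for
this degenerate case is the package's). Release is reported per worm.
The ratio-vs-1 test is a standard two-sided one-sample t-test per group
with Benjamini–Hochberg FDR across groups. A log-ratio variant (testing
`log ratio` against 0) is provided and is the *calibrated* form under
multiplicative noise: ratios of lognormal quantities are themselves
lognormal with mean > 1 under the null, so the raw-ratio test is
anti-conservative there, while the log form is exact. The raw-ratio
test remains the default; calibration checks use `log_ratios=True`.

## Validation problem sizes

The validation suite runs at desk scale by design: 100 random draws per
closed-form regime, 200 ordered pairs for monotonicity, 20 points for
the linear-regime elasticities, 18 fast-turnover points, a 12-point
δ-transect for the boundary, the full 12⁴ sweep (run twice to confirm
byte-identical output), 10⁴ synthetic competition replicates and 10⁴
null t-test groups. The acceptance script reports the same quantities
with a 6⁴ grid for the strategy fractions.

## Known limitations

* Single-cycle only; no serial-passage evolution, mutation supply or
  adaptive walks on the gradient.
* The elasticity is a local, first-order object; no second-order
  sensitivities.
* The strategy classification depends on the dominance convention
  (max |E|, fixed tie-break); alternative conventions could relabel
  points where components are nearly tied, as in the near-capacity
  regime above.
* Plotting is limited to the tabular 2-D slices (`marginal_slice`);
  no figure generation is built in.
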