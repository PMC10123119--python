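# Methods

## Scope and model philosophy

`mirella` models how miRNA-mediated downregulation of one transgene (the
*miTarget*) redistributes shared post-transcriptional resources onto
co-expressed genes. Two deterministic mass-action ODE models share a common
miRNA module:

* **Translation model** — the miTarget and a constitutive *capacity
  monitor* compete for a constant ribosome pool `r_total`. Competition
  enters through the instantaneous free-ribosome level (a competitive
  binding quasi-steady state), which multiplies both translation rates.
* **Degradation model** — the miTarget and an *endogenous* gene compete
  for a finite RNase pool `z_total`. mRNAs form degrading mRNA:RNase
  complexes; catalytic completion consumes the mRNA and releases the
  enzyme.

All concentrations are in nM, time in hours; second-order binding
constants in nM⁻¹h⁻¹. Free miRNA `q` binds the target mRNA with rate
constant `eta_plus` (the tunable proxy for target-site count: one site =
one unit, three sites = three units) and dissociates at `eta_minus`.
The bound complex is degraded `lambda_TQ`-fold faster than the free
mRNA (`beta_TQ = lambda_TQ * beta_T`); complex degradation releases the
miRNA (catalytic RISC), so the free miRNA settles at
`q = alpha_Q / beta_Q` regardless of binding. The boolean `sigma`
encodes target-site location: in the 5'UTR (`sigma = 0`) the bound
complex is translationally silent (steric hindrance at the start codon),
in the 3'UTR (`sigma = 1`) it is translated like the free transcript.

## Translation model and its closed form

State: free target mRNA `m_T`, bound complex `m_Q`, monitor mRNA `m_C`,
free miRNA `q`, proteins `p_T`, `p_C`. Free ribosomes:

    r = r_total / (1 + m_T/kappa_T + sigma*m_Q/kappa_T + m_C/kappa_C)

with `kappa` the effective ribosome–mRNA dissociation constants. The
steady state is exactly expressible through dimensionless *resource
demand coefficients* (`rho_T`, `rho_TQ`, `rho_C` in
`mirella.analytics`); the proteins follow a shared-pool partition

    p_T = (gamma_T/delta_T) * (rho_T + sigma*rho_TQ) / D * r_total
    p_C = (gamma_C/delta_C) * rho_C / D * r_total,   D = 1 + rho_T + sigma*rho_TQ + rho_C

and `r = r_total / D`. The identity between the mass-action scheme and
these closed forms is verified two ways: symbolically with sympy
(`tests/test_symbolic.py` solves the steady state exactly) and
numerically (random parameter sets, integration vs closed form at
relative tolerance 1e-5).

Ribosomal density is reported per *total* transcript of a gene:
`density_C = r/kappa_C` and
`density_T = r * (m_T + sigma*m_Q) / (kappa_T * (m_T + m_Q))` — for
5'UTR placement the silent complexes dilute the average. Note the free-
ribosome denominator is written with the `sigma`-gated demand
`rho_T + sigma*rho_TQ + rho_C` for consistency with the protein
partition; an ungated form (all three demands) is sometimes quoted for
the 3'UTR case, where the two coincide.

## Degradation model

State: `m_T`, `m_Q`, `m_E` (free mRNAs), `q`, and three enzyme
complexes: `s_TF` (RNase on free target mRNA), `s_TQ` (RNase on
miRNA-committed mRNA) and `s_E` (endogenous). Free enzyme is the
conserved remainder `z = z_total − s_TF − s_TQ − s_E`. Tracking the two
miTarget complex sub-species keeps the provenance bookkeeping exact
(which pool a complex came from determines whether a miRNA is released
on completion).

miRNA commitment changes the enzyme kinetics of the target transcript in
two opposed ways:

* association is boosted: `betaTQ_assoc >> betaT_assoc` (the committed
  mRNA is rapidly captured by the machinery), so the *target* degrades
  faster overall (`beta_TQ_eff > beta_T_eff` as instantaneous
  first-order equivalents, `mirella.model_core.effective_degradation_rate`);
* per-complex catalytic completion is slower: `betaTQ_cat < betaT_cat`
  (a committed substrate occupies the machinery longer than a basal
  turnover event).

The second property is the package's modelling choice and is what makes
enzyme *queueing* possible: at steady state the enzyme occupancy of any
route is (flux through the route)/(catalytic rate of the route), and the
total miTarget flux is fixed by transcription, so shifting flux from the
fast-completing basal route to the slow-completing miRNA route increases
the RNase occupancy monotonically with `eta_plus`. With a single shared
catalytic rate the occupancy would be independent of miRNA activity and
no queueing (nor any slowdown of the endogenous transcript) could occur
at any binding strength.

### Transcription-halt decay

`transcription_halt_decay` brings the system to steady state, zeroes all
production rate constants, and records the t0-normalised total mRNA of
each gene (free + complexed). Under queueing the endogenous profile is
biphasic: nearly flat while miTarget-derived complexes hold most of the
enzyme, then fast once the target pool is exhausted and the enzyme is
released. The control (`eta_plus = 0`) is a single exponential, and
regulated profiles lie pointwise above the control (slower decay, longer
half-life).

### Phase detection

`detect_decay_phases` fits one- and two-segment continuous piecewise
linear models to log-abundance vs time (breakpoint on the sample grid,
hinge least squares) and calls two phases when the BIC improvement
exceeds 10. The Gaussian BIC is evaluated at a fixed measurement
resolution (default 0.1 in log units, ~10% in abundance — the scale of
qPCR replicate error) rather than a residual-estimated variance:
noiseless simulated profiles otherwise make the comparison degenerate,
since any smooth curvature gives an unbounded likelihood gain.
Deviations below the resolution are treated as measurement-level, not
phase structure. `biphasic_threshold` bisects `eta_plus` (log scale, 5%
bracket) on the detector's verdict; with the shipped defaults the onset
is at `eta_plus ≈ 1.7 nM⁻¹h⁻¹`.

`half_life` interpolates the first crossing of 0.5 linearly in
log-abundance and flags extrapolation when the profile never crosses.

## Default parameters

Defaults live in `src/mirella/data/*.yaml` (flat YAML, strict unknown-key
rejection) and are configuration, not code.

**Translation** (`translation.yaml`): mRNA decay 0.2 h⁻¹ (t½ ≈ 3.5 h),
protein dilution 0.1 h⁻¹, baseline ribosome demand `rho_T = rho_C = 5`
(a strongly loaded cell, total demand ≈ 10), `lambda_TQ = 10`,
`eta_minus = 1 h⁻¹`, pool 1000 nM. The free miRNA level is low
(`alpha_Q/beta_Q = 3 pM`, an effective free-RISC concentration; most
cellular miRNA is target-bound) so that miRNA→complex conversion stays
unsaturated across the full sweep grid (10⁻²–10² nM⁻¹h⁻¹): this keeps
the 5'UTR target ribosomal density — an average over silent complexes —
monotonically increasing over the grid, and keeps `beta_TQ` comparable
to `eta_minus` so `lambda_TQ` remains identifiable from fold-change
panels. The absolute mRNA scale (alpha and kappa jointly, which leaves
demands, proteins and fold changes invariant) is set so the slowest
coupled mode (miRNA buffered by the bound pool) equilibrates well within
the fixed 10 000 h integration span.

**Degradation** (`degradation.yaml`): endogenous transcript with
effective half-life ≈ 2.3 h at `eta_plus = 0` (the hours-scale regime
of typical unstable mammalian mRNAs); basal complexes complete fast
(20 h⁻¹ — low occupancy, so the control decays as a clean single
exponential) while miRNA-committed complexes associate 10× faster and
complete at 0.8 h⁻¹. The RNase pool (60 nM) exceeds the maximal
steady-state demand (~51 nM when all target flux is miRNA-routed), so a
steady state exists at every `eta_plus` while strong regulation drives
free enzyme down ~7-fold. This calibration places the biphasic-decay
onset near 2 nM⁻¹h⁻¹.

## Solver protocol and numerical choices

* Radau (implicit, stiff) with `rtol = 1e-6`, `atol = 1e-9`; steady
  states taken as the terminal value of a [0, 10 000] h integration from
  the zero state, plus an explicit residual check (‖RHS‖ below 1e-8 of
  the largest production/turnover flux) that warns on non-convergence
  rather than silently accepting a drifting state.
* Random-parameter consistency studies draw log-uniformly over ~4
  decades per rate constant and reject draws whose slowest Jacobian
  eigenvalue at the analytic steady state is slower than 2e-3 h⁻¹, i.e.
  sets that could not equilibrate within the fixed span
  (`mirella.sampling`).
* `eta_plus = 0` is handled as the exact limit (`rho_TQ = 0`), never a
  division.
* Phase detection floors non-positive profile values at 1e-9 with a
  warning before taking logs.

## Fitting

`FoldChangeModel` (statsmodels-style: model object over a data panel,
`fit()` returns a results object with `params`, `loss` and `summary()`)
ties the translation model to the five-condition design — Control (no
target sites), 1TS and 3TS in the 3' or 5' UTR — with
`eta_plus = ts_count * eta_unit`. Both reporters are expressed as fold
change versus Control (Control ≡ 1), which removes unidentifiable
absolute scales; the data vector has 10 entries. The loss is

    L(theta) = ||y − yhat(theta)||² + lambda * ||theta||²,  lambda = 0.001

with theta pre-scaled by bound midpoints so all components are of order
one, minimised by SciPy differential evolution (Sobol initialisation,
seeded and reproducible). The default free mask is
`{eta_unit, lambda_TQ, kappa_ratio}`: a 10-point panel cannot identify
the full parameter set, and these three carry the regulation strength,
the enhanced-decay fold and the relative ribosome affinity. On noiseless
synthetic panels the fit recovers the generating values to a few percent;
the residual bias is the L2 regulariser, which at `lambda = 0.001` is
well below the 10% level.

`generate_synthetic_foldchanges` emulates the five-condition panel:
noiseless predictions at known parameters, then independent
multiplicative log-normal noise of a requested coefficient of variation
on each of the 10 entries. It reproduces the *structure* of a
flow-cytometry fold-change panel (means per condition, multiplicative
error) but none of the biology it abstracts away — no cell-to-cell
heterogeneity, transfection-dose variation, gating effects or
between-replicate correlation — so passing recovery tests demonstrate
optimiser and model-identifiability soundness, not robustness to real
experimental structure.

## Known limitations

* Deterministic ODEs only: no intrinsic noise (SSA), no spatial effects.
* Transcriptional resource competition is not modelled explicitly;
  burden on transcription folds into the transcription rate constants.
* The degradation model tracks mRNA species only (no protein readout);
  the translation model assumes an unlimited degradation machinery. The
  two resource couplings are studied separately, not jointly.
* The competitive-binding form of the free-ribosome pool is a
  quasi-steady-state abstraction; `kappa` values are effective constants,
  not measured dissociation constants.
* `eta_plus` proportional to target-site count ignores cooperativity
  between adjacent sites.
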