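# Methods

This note documents the models, numerical choices and validation scope of
receptorpharm.

## Mass-action binding model

All binding simulations and kinetic estimators assume a single receptor
site binding a single tracer under pseudo-first-order conditions (free
ligand concentration effectively constant):

* association: d[RL]/dt = kon·[L]·(Bmax − [RL]) − koff·[RL], giving
  B(t) = Beq·(1 − e^(−kobs·t)) with kobs = kon·[L] + koff and
  Beq = Bmax·[L]/([L] + K_D);
* dissociation after an excess-competitor chase: B(t) = B(t₀)·e^(−koff·t),
  valid when the chase concentration is ≥100·K_D so rebinding is
  negligible — the generator rejects weaker chase designs, and the test
  suite's two-ligand ODE oracle quantifies the residual rebinding error
  (≈0.15% over 200 min at a 1 µM chase with K_D ≈ 0.03 nM, <0.02% at
  10 µM);
* equilibrium competition: specific binding Bmax·[L]/([L] + C + K_D)
  (homologous) or Bmax·[L]/([L] + K_D·(1 + C/K_i)) (heterologous). Both are
  exact Hill −1 logistics in log10 C, with IC50 = [L] + K_D and
  IC50 = K_i·(1 + [L]/K_D) respectively, which is what makes the
  fixed-slope logistic the correct fitting model.

A guard warns when expected bound tracer exceeds 10% of added counts, the
point where the pseudo-first-order assumption (no tracer depletion)
degrades. No depletion-corrected (cubic) equilibrium solver is provided.

## Synthetic-assay generator

The generator reproduces the four assay designs of the study it targets:

* SPA membrane kinetics: tracer ≈ 0.19–0.21 nM, readings every minute to
  100–120 min (association) or 500 min (dissociation), dissociation
  initiated by a 1 µM unlabeled chase after 60 min preincubation;
* whole-cell competition binding: 13–86 pM tracer, ~25,000 CPM added per
  well (default `added_cpm`), zero-competitor wells defining B0;
* cAMP-style dose–response with a Gaddum competitive shift
  (response = basal + 100·emax_frac·A/(A + EC50·(1 + B/K_B))), emitted on
  the percent-of-reference scale;
* BRET: independent acceptor and donor channels whose expected ratio
  follows the same logistic on the raw ratio scale.

Noise is Gaussian per replicate with a user CV on each expected count,
truncated at zero. γ/SPA counts at these magnitudes are large enough that
Gaussian noise is an adequate model; a Poisson option was deliberately not
made the default. The study does not state its counters' noise magnitude;
`noise_cv = 0.05` is this package's choice of a realistic plate-assay CV.
Nonspecific binding is modeled as a time- and competitor-independent
fraction of added counts (default 0.02, giving the ~5–10% specific-binding
regime the competition assay was designed for) and emitted as a separate
mock-transfected channel. Identical seeds reproduce every number
bit-for-bit; changing the seed changes only the noise, never expectations.

What the generator does **not** emulate: plate spatial effects, receptor
internalization/desensitization, tracer depletion, ligand degradation, or
inter-assay drift. Parameter-recovery results on synthetic data therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to real-data violations of them.

## Dose–response fitting

Three-parameter logistic (bottom, span, midpoint) with the Hill slope fixed
at +1 or −1; free-slope (4PL) and biphasic fits are out of scope. The
midpoint is estimated as pEC50 (log space), which conditions the problem
and yields the SE on the reported scale directly (from the Jacobian-based
covariance of the least-squares fit). Multi-start initialization places the
midpoint on a 0.5-decade grid spanning the observed concentration range
(±1 decade); starts are tried in deterministic order and the lowest SSE
wins, so refits are reproducible. Zero-dose wells enter the residuals at
the zero-concentration limit of the logistic (they inform the basal
plateau) and are never log-transformed. The bottom plateau is bounded at
≥0 by default but left free (`basal_min=None` unbounds it).

A fit is flagged N.A. (no saturation) when the fitted span is below 3× the
residual SD or the midpoint falls outside the tested concentration range
(±0.5 decade); reports propagate the label instead of a number. The same
rule flags N.B. (no binding) for competition curves. Across independent
experiments, potency is summarized as mean pEC50 ± SEM of per-experiment
fits rather than one pooled fit, matching the convention of treating the
experiment as the unit of replication.

## Schild analysis

Dose ratios come from paired logistic fits (same agonist and receptor;
metadata mismatches are rejected). Points with DR ≤ 1 carry no information
about a rightward shift and are excluded with a logged reason code. The
regression is OLS of log10(DR − 1) on log10([B] in M); pA2 is the
x-intercept and is also reported as A2 in nM, since the field frequently
prints "pA2" values in concentration units. With exactly two antagonist
concentrations (a common design) the line is exact and the slope SE and R²
are reported as NaN — undefined, not zero.

## Competition binding

The logistic is fitted to raw bound CPM with a free bottom plateau, which
absorbs the nonspecific floor; B0 (total specific binding) is the fitted
span (top − bottom), preferred over the raw zero-competitor wells for noise
robustness. The assay mode (homologous/heterologous) is declared by the
caller, never inferred; the only internal consistency check is the
IC50 ≥ [L] precondition of K_D = IC50 − [L]. Derived quantities are
computed per experiment and then averaged, so a reported mean K_i will not
in general equal 10^(9 − mean pIC50). The optional conversion of Bmax from
CPM to fmol/10⁵ cells divides by the tracer's specific activity (CPM/fmol)
and the cell count.

## Kinetic fitting and error propagation

Association fits enforce B(0) = 0 (the reaction is initiated by tracer
addition); dissociation fits fix the floor at 0 because nonspecific binding
is already subtracted — a free-floor variant is available
(`free_floor=True`) since assays with incomplete chase can leave a genuine
plateau. Replicates are fitted jointly (pooled) by default; per-replicate
fitting supports SEM-style reporting. Rate initializations span a log grid
(10⁻³–1 min⁻¹ association, 10⁻⁴–10⁻⁰·⁵ dissociation); bounds keep rates and
amplitudes positive. A flat trace or an increasing "dissociation" trace
(compared by early vs late time quartiles, robust to pooled replicates) is
an error, not a silent bad fit.

kon = (kobs − koff)/[L] and K_D = koff/kon, with delta-method SEs treating
kobs, koff and the pipetted [L] as independent:

    SE(kon)² = (SE(kobs)² + SE(koff)²)/L² + ((kobs − koff)·SE(L)/L²)²
    SE(K_D)² = (SE(koff)/kon)² + (koff·SE(kon)/kon²)²

A 10⁵-draw Monte-Carlo check in the test suite confirms the first-order
approximation within 5% at the study's parameter magnitudes (the relative
SEs there are ≤10%, well inside the linear regime).

## Statistics and reporting

Paired comparisons use the classical paired Student's t-test (two-sided).
Zero-variance differences are degenerate: all-zero differences give
t = 0, p = 1; constant nonzero differences give infinite t with p reported
as 0 and a warning. Report tables have deterministic column and row order,
round potencies to the field's conventions (pEC50 to 0.1, EC50/K_i to 2
significant figures) and propagate N.A./N.B. labels as strings.

## Problem sizes used in validation

Simulation-based checks run at the emulated assay designs: kinetics at
[L] = 0.21 nM with 1-min sampling (101-point association, 500-point
dissociation, 4 replicates, 5% CV, 20 seeds); Schild at K_B = 51.9 nM with
antagonist at 100/300/1000 nM; competition on 13-point half-decade series
with zero wells; 200-curve potency-recovery at 5% CV. These sizes make the
whole suite a desk-scale computation (about a minute) while keeping the
Monte-Carlo medians stable.

## Known limitations

No variable-slope or operational-model (Black–Leff) analysis; no two-site
or allosteric binding models; no ligand-depletion correction; no
biexponential kinetics or kinetics-of-competition (Motulsky–Mahan); no
plotting beyond what pandas provides. The Schild slope SE from two-point
designs is undefined by construction — per-experiment regressions are the
way to obtain one, and are supported but not automated.
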