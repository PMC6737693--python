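# Methods

## Model structure and assumptions

The network couples four signaling arms inside an NSCLC cell:

* **EGFR arm.** EGF drives EGFR phosphorylation (Michaelis–Menten in EGFR,
  with the ligand as modifier); pEGFR activates ERK directly and Akt through
  PIP3 production. Dephosphorylation is first order. There is no ERK→SOS
  negative feedback: ERK stays continuously activated under sustained EGF,
  so the feedback loop present in many receptor models is deliberately
  absent here.
* **ER arm.** ERα and ERβ are lumped into one ER species: every
  modeling-relevant perturbation in the underlying experiments silences or
  stimulates both together, and the network treats "ERs" as a single axis.
  E2 induces ER synthesis (positive feedback) and activates ER to ERa by
  mass action. ERa transactivates EGFR — the redundant route that lets ER
  hyperactivation re-drive Akt/ERK even when EGF-driven input is inhibited.
* **Notch arm.** ERa induces Notch1 synthesis; Dll1 catalyzes cleavage of
  Notch1 into NICD, *consuming* the receptor. Because resynthesis
  (k ≈ 0.02–0.3 /h) is slow against cleavage at high Dll1 (≈ 2 /h), a Dll1
  step depletes the standing Notch1 pool and produces the characteristic
  rapid, transient Hes1 pulse; the sustained tail is set by the resynthesis
  flux. NICD induces Hes1; Hes1 represses PTEN synthesis (Hill n = 2),
  which raises PIP3 and slightly elevates pAkt — the Hes1/PTEN/PIP3 route.
* **GSK3β/β-Catenin arm.** pAkt and pERK phosphorylate (inactivate) GSK3β;
  active GSK3β degrades β-Catenin (Michaelis–Menten in β-Catenin). ERa also
  induces β-Catenin synthesis directly — the bypass that makes the High-E2
  β-Catenin rise much larger than the kinase-mediated one.

The mechanism of the ER positive feedback is modeled as E2-induced
synthesis (transcriptional auto-induction); stabilization would be an
alternative reading and is not distinguishable at this level of detail.

States are relative abundances (a.u.), time in hours. Kinase pools
(Akt+pAkt, ERK+pERK, GSK3β+pGSK3β, totals normalized to 1) are closed by
construction; the stoichiometric closure is asserted symbolically and the
integrated drift is checked to < 1e-6 relative.

## Scenarios, baseline and readout

Ligand inputs are boundary species fixed at scenario levels; the two-level
design uses low = 0.01 and high = 1.0 a.u. (the underlying study gives only
a two-level contrast, not magnitudes; these are calibration constants).
Every simulation starts from the resting state obtained by a 200 h All-Low
burn-in. For reporting, the burn-in endpoint is Newton-polished to the
exact fixed point (the slowest turnover, PTEN at k_deg = 0.04 /h, is not
fully settled after 200 h); for parameter estimation the raw burn-in is
used unpolished, because the polish's accept/reject gate is discontinuous
in the parameters and traps gradient-based optimizers. Readout is at
t = 48 h (the treatment window of the drug experiments); panels also report
each output's peak value and peak time over [0, 48] h since it is not
obvious a priori whether endpoint or peak is the more informative summary.

Drug action is competitive-style multiplicative inhibition. Ki_gef = 1 μM
and Ki_ful = 0.1 μM place the experimentally used doses (Gefitinib 20 μM,
Fulvestrant 1 μM) at ≥ 90% inhibition of their targets (factors 1/21 and
1/11), matching the near-complete pathway suppression those doses produce.

## Qualitative constraints and their operationalization

The five-scenario behavior is encoded as six checks against the
pre-equilibrated baseline: C1 All-Low outputs within [0.8, 1.25]×; C2
High-EGF pAkt/pERK ≥ 2× with β-Catenin/Hes1 ≤ 1.2×; C3 High-Dll1 Hes1 peak
before 12 h, decayed below 0.5× peak by 48 h, pAkt in (1, 2)×; C4 High-E2
all four outputs > 1.2×; C5 All-High componentwise maximal; C6
pAkt(High-E2 + Gefitinib 20 μM) > 2 × pAkt(All-Low + Gefitinib 20 μM).
The numeric thresholds are this package's operationalization of the
qualitative statements ("not significantly affected", "slightly elevated",
"reactivate"). C6 uses a 2× margin rather than a bare inequality because
the Notch1→Hes1→PTEN→PIP3 route alone gives a ~1.4× rise even with the
ER→EGFR edge deleted; the margin separates genuine EGFR-transactivation
(40× with the shipped defaults) from that residual redundancy, which is
what the ablation counterfactual must detect.

The shipped default parameters (`src/ernet/data/default_params.json`) were
calibrated by hand until C1–C6 and the three ablation counterfactuals hold
simultaneously; they are data, not code, and alternative sets can be passed
everywhere. No claim is made that they are uniquely identified.

## Synthetic data

**Expression matrices.** Default dimensions 17,489 genes × 1,019 samples on
the log2(norm_count+1) scale, emulating the tumor cohort the DE stage is
designed for. The marker gene is drawn from a continuous distribution
(N(baseline, 1)), so the median split is tie-free by construction; a
tie-injection flag exists to exercise the tie rule. Planted up/down genes
receive symmetric ±effect/2 mean shifts conditional on the marker's median
split (a two-group contrast, not a latent dose); defaults are effect = 2
log2 units with additive Gaussian noise of 0.5 log2 units — noise on the
log scale because that is the scale analyzed. 15% of genes are planted
below the abundance filter (mean < 2); the remainder are null. The truth
sidecar labels each gene marker/up/down/null/low_expressed; the marker row
is excluded when scoring sensitivity/FDP since it is the stratifying
variable itself. Not emulated: count-level noise, library-size artifacts,
batch effects, correlated gene programs — so passing operating
characteristics here show the calling rule works at the stated effect and
noise, not that it is robust to real-data artifacts.

**Time courses.** Densitometry-style measurements are strictly positive and
ratio-scale, so the default noise is multiplicative lognormal with unit
mean and CV = scale (σ² = ln(1+CV²), μ = −σ²/2); additive Gaussian is
available. Replicates default to 3 ("repeated at least three times" is the
only anchor in the source experiments; the error structure is our
convention, not a reported fact). The generating parameters are stored on
the dataset as hidden truth for recovery studies.

## Differential expression

Between-group log2 fold change is the difference of group means on the
log2 matrix, i.e. "fold change > 2" is applied as |log2fc| > 1; whether the
original analysis used ratios of unlogged means instead is not stated. The
moderated statistic shrinks per-gene pooled variances toward a scaled
inverse-chi-square prior fitted by method of moments across genes
(s²|σ² ~ σ²χ²_d/d, σ² ~ s0²d0/χ²_{d0}; matching the first two marginal
moments gives d0 and s0²; a degenerate spread maps to d0 = ∞, full
shrinkage). This is empirical-Bayes moderation in the limma spirit;
bit-exact limma equivalence is not asserted — the acceptance surface is
planted-truth recovery. Welch's t-test is the unmoderated option. No
multiple-testing correction by default (the calling rule is raw p < 0.05
with FC > 2); a Benjamini–Hochberg flag exists but is off. Clustering uses
Euclidean distance with average linkage (the metric is stated by the
analysis being reproduced; the linkage is the default of the tool it used).
Median-split ties go to the low group — the only rule consistent with a
509/510 split of 1019 distinct values.

## Parameter estimation

Neither the objective nor the optimizer of the original estimation step is
stated; we fix log-scale least squares (residual = log(sim+ε) − log(obs+ε),
ε = 1e-6 to tolerate zero observations — appropriate for ratio-scale
densitometry) with multi-start bounded local optimization
(scipy.least_squares, trf) in log10-parameter space, starts drawn
log-uniformly within bounds from a seeded generator. The default free set
is the four rate constants governing the experimentally probed edges —
ER synthesis induction (ki_er_syn), ER→Notch1 (ki_notch_syn), ER→β-Catenin
(ki_bcat_syn) and Dll1 cleavage (k_notch_cleave) — with everything else
held at the shipped defaults to keep the desk-scale fit identifiable.
Fitting simulations run at rtol 1e-6 (vs 1e-8 for reported trajectories).

Recovery studies use one stimulated scenario (E2 and Dll1 high, EGF low —
all four free parameters are active), observations of ER, Notch1, Hes1 and
β-Catenin at 8 time points with 3 replicates, and noise CVs {0, 0.1, 0.2}
over 20 seeds. Bounds for the study span 10× either side of truth with 3
starts per fit (the default 100× span with 20 starts is used for the
single noise-free certification fit); with these settings the noise-free
fits recover all four parameters to machine precision and median errors
grow monotonically with noise (≈ 2.3% at CV 0.1, ≈ 4.6% at CV 0.2).
Parameters whose zero-noise relative error exceeds 50% are reported as
non-identifiable rather than folded into summaries — sloppiness is
surfaced, not hidden. Bayesian posteriors and profile-likelihood intervals
are out of scope.

## Numerical choices

* Integrator: LSODA (stiff-capable), rtol 1e-8 / atol 1e-10 for reported
  trajectories; BDF serves as the independent cross-check (agreement to
  1e-3 required, ~1e-8 observed). Dense output at ≥ 200 points per window.
* Negative round-off states are clamped to 0 inside rate evaluation;
  trajectories below −1e-9 abort with the scenario named.
* Ties in hierarchical clustering are broken by input order (SciPy
  convention), making orderings deterministic for fixed input.
* Pipeline stage seeds derive from one global seed via CRC-mixing of the
  stage name, keeping every derived seed below 2³¹.

## Problem sizes

Tests and the acceptance script run at desk scale: DE operating
characteristics on 2,000-gene × 200-sample matrices over 20 seeds (the
full-size 17,489 × 1,019 default is exercised for the median-split check's
sample dimension only); recovery at 3 noise levels × 20 seeds. These sizes
are the package's own choice of a representative, quickly reproducible
experiment.

## Known limitations

* The supplementary tables holding the original model's exact equations
  and fitted parameter values were not available; the topology is a faithful
  reconstruction from the described mechanism, and the shipped defaults are
  a calibration to the described qualitative behavior, not the authors'
  fit. Quantitative trajectory values are therefore not comparable to the
  original figures; directions, orderings and dynamical signatures are.
* Model outputs are signaling levels; the mapping to proliferation,
  apoptosis or motility phenotypes is assumed verbally in the source and is
  not modeled.
* Deterministic ODEs only — no cell-to-cell variability, no spatial
  effects.
* The DE stage's operating characteristics are certified on synthetic
  matrices with independent genes; correlated programs would change the
  effective false-discovery behavior.
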