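# Methods

## The screen

The pipeline models a drug-repurposing screen around human serum albumin
(HSA), the 585-residue plasma protein that buffers amyloid-β (Aβ) in blood.
Candidate small molecules are filtered for bioavailability and disease
linkage, grouped by where they are predicted to bind on HSA, ranked within
each group, and the representative ligands' effect on HSA–Aβ40 binding is
quantified by surface-plasmon-resonance (SPR) kinetics. Docking, database
retrieval and wet-lab steps are out of scope: binding sites and ligand
tables are inputs (real or synthetic), and sensorgrams are either measured
data supplied by the user or simulated.

## Filtering

Each candidate carries six attributes; the pass conditions are
mass ∈ (100, 900) Da, solubility > 1 µM, BBB penetration > 50 %,
plasma concentration > 0.5 nM, literature references ≥ 2, and not a fatty
acid. Threshold wording ("above", "exceeding", "less than") is read as
strict; "more than 1 reference" as ≥ 2. The survivor *set* is a conjunction
of independent predicates and therefore order-invariant; the per-stage
*counts* follow the fixed order mass → solubility → BBB → plasma →
references → fatty acid. This order is a reporting convention, not a claim
about any particular historical screen. Records with missing attributes
raise a named validation error instead of being dropped silently.

## Site encoding and DTW distance

A predicted binding site is a set of HSA residue numbers (PDB entry 1UOR,
chain A numbering). For clustering it is encoded as the ascending series of
its residue numbers; sites are then compared with dynamic time warping
(DTW): local cost |x − y|, symmetric step pattern (match, insert and delete
each add one local cost term), endpoints anchored, no warping window, no
path-length normalisation. Under this encoding DTW is small when two sites
occupy nearby stretches of the chain, even if their residue counts differ.
Sequence-position proximity is a proxy for spatial proximity — adequate
within one subdomain, blind to contacts that are close in space but distant
in sequence. Alternative encodings (e.g. a binary residue-presence vector
over 1..585) would weight sites differently; the series encoding is the
simplest one consistent with treating sites as number series, and the
distance, linkage and normalisation are all exposed as options.

The DTW dynamic program is verified in the test suite against exhaustive
enumeration of all monotone alignment paths for short series.

## Clustering and ranking

The pairwise DTW matrix is clustered with agglomerative hierarchical
clustering (scipy linkage). Average linkage is the default: it behaves
robustly on non-Euclidean distance matrices and needs no centroid
embedding; single/complete/weighted are accepted. The dendrogram is cut to
exactly *k* flat clusters and cluster ids are relabelled 1..k by
decreasing size (ties by smallest member index) so output is deterministic.

Within a cluster of *n* ligands, the frequency of residue r,
f_aa(r), counts the member ligands whose site contains r (presence, not
multiplicity), and a ligand's rank is R = Σ_r (f_aa(r)/n)·k(r) with k(r)
the presence indicator for the ligand's own site. R is read with k as a
multiplicative indicator; placing k in a denominator would be undefined for
absent residues. Consequences used as test oracles: a singleton cluster's
ligand has R equal to its site cardinality; adding residues to a site never
lowers R; relabelling ligand ids never changes R.

## Occupancy

Two equilibrium models for a single site class with association constant K
(M⁻¹):

* excess-ligand isotherm θ = K·L/(1 + K·L), valid when total ligand far
  exceeds total sites;
* exact mass balance with total sites S = n_sites·[HSA] and Kd = 1/K:
  bound b solves b² − (S + L + Kd)·b + S·L = 0, physical root
  b = ((S + L + Kd) − √((S + L + Kd)² − 4SL))/2, θ = b/S. This reduces to
  the isotherm as L/S → ∞ and is required when a poorly soluble ligand
  (e.g. 15 µM levothyroxine against up to 160 µM of sites) is depleted.

Site classes are treated independently; no competitive or cooperative
binding polynomial is attempted. θ is monotone in K, L (increasing) and in
S (decreasing); mass conservation holds to machine precision. Reporting
rounds to the nearest percent, half away from zero; all computation is done
unrounded. Note that for the levothyroxine condition at the *low* end of
the protein range (2.5 µM HSA) this model gives 50 % occupancy; published
summaries quoting a lower upper bound evidently used a different (unstated)
model, and no attempt is made to match it.

## SPR kinetics

The heterogeneous-ligand model: the chip carries two independent classes of
immobilized Aβ40 sites; flowing HSA (analyte, concentration C) binds each
with rates ka_i, kd_i. Under pseudo-first-order conditions each class obeys
dR_i/dt = ka_i·C·(Rmax_i − R_i) − kd_i·R_i, giving the closed forms

* association (t ≤ t_assoc):
  R_i(t) = Rmax_i·ka_i·C/(ka_i·C + kd_i)·(1 − e^{−(ka_i·C + kd_i)t})
* dissociation: R_i(t) = R_i(t_assoc)·e^{−kd_i (t − t_assoc)}

with total response R₁ + R₂. Mass-transport limitation, conformational
change and rebinding are deliberately not modelled. The closed form is
checked against an independent ODE integration (LSODA, rtol 1e-11) to
1e-6 relative in the tests.

**Fitting.** Each sensorgram is fitted separately by bounded nonlinear
least squares (scipy trust-region reflective) over
(ka1, kd1, ka2, kd2, Rmax1, Rmax2), parameterised in log10 space (rates
bounded 1e-2..1e8 M⁻¹s⁻¹ and 1e-8..1e2 s⁻¹; Rmax 1e-4..1e6 RU).
Biexponential fits are initialisation-sensitive, so every fit multi-starts
from a log-spaced grid (ka ∈ {10², 10⁴} M⁻¹s⁻¹, kd ∈ {10⁻⁵, 10⁻³, 10⁻¹}
s⁻¹ per site, kd1 ≤ kd2 starts only) plus any user-supplied guess; the
lowest-residual solution wins, and starts are skipped once a numerically
perfect fit is found. After each fit sites are relabelled so KD1 ≤ KD2
(site 1 = higher affinity), making the result invariant to label swaps in
the initial guess. Per-concentration estimates are then averaged
arithmetically with standard deviations over concentrations; KD_i is
computed per fit and then averaged, so the averaged KD is an average of
ratios and generally differs from the ratio of the averaged rates. A
global fit with shared rates across concentrations is available
(`global_fit=True`) but is not the default protocol.

**Derived quantities.** ΔG_i = −RT ln(55.3/KD_i) with R = 8.314×10⁻³
kJ mol⁻¹ K⁻¹, T = 298.15 K by default and 55.3 M the molarity of water
(standard state); kcal/mol optional. δΔG_i = RT ln(KD_i^ligand /
KD_i^baseline) against a solvent-matched baseline; negative δΔG means the
ligand favors HSA–Aβ binding. Fold changes are reported as
max/min ≥ 1 with a direction flag, rounded to whole folds (half away from
zero) only at the presentation layer. Baseline correction is pointwise
blank subtraction, with optional linear interpolation onto the sample grid.

## Synthetic data

The generators define the study conditions for all tests:

* **Ligand tables.** Attributes are sampled independently per filter; the
  single-filter pass probability is controlled exactly by drawing a
  Bernoulli pass indicator at the configured fraction and then sampling the
  attribute from its marginal restricted to the pass/fail side of the
  threshold. Marginals: mass uniform on [50, 1200] Da (both tails of the
  mass window populated), solubility and plasma concentration log-uniform,
  BBB uniform on [0, 100] %, references refs_min + Poisson(4) on the pass
  side. Default pass fractions (0.7, 0.8, 0.5, 0.6, 0.4, 0.9 for mass,
  solubility, BBB, plasma, references, non-fatty-acid) mimic a plausible
  attrition profile; the historical survivor count depends on an external
  database snapshot and is not a generator target.
* **Binding sites.** Five archetype anchors default to residues 447, 452,
  117, 145 and 292 — hallmark residues of the five empirically observed
  cluster regions on HSA (subdomains IIA/IIB, IIIA, IB, the IB cleft, IIA).
  An archetype is 8 distinct residues within ±12 of its anchor; each member
  site removes and adds `site_jitter` residues (default 1). With ~50+
  residue anchor separation and jitter ≤ 2, within-cluster DTW distances
  stay strictly below between-cluster ones, so planted labels are exactly
  recoverable (ARI = 1), which is asserted, not assumed. The planted label
  rides along on each site but is never read by the clustering code.
* **Sensorgrams.** Closed-form two-site traces on a uniform grid (defaults:
  300 s association, 2400 s dissociation, dt = 1 s, matching the assay
  protocol; concentrations 2.5–40 µM) plus pointwise Gaussian noise of
  fixed sd (default 1 RU, a realistic instrument noise floor). Zero-noise
  output is bit-identical to the simulator.

What the synthetic data does **not** emulate: real docking energetics or
pose uncertainty, correlated/structured SPR noise (drift, spikes, bulk
refractive-index steps), attribute correlations in real pharmacology
tables, and real cluster imbalance. Passing tests therefore demonstrate
correctness of the algorithms under the stated models, not performance on
real screens.

## Problem sizes and numerical choices

Test and benchmark sizes are chosen so the full suite exercises every path
at comfortable scale: filter tables of 10⁴ records for binomial checks,
40–50 sites for clustering recovery, sensorgrams of ~1350–2700 points, and
a 20-seed noisy-refit study at 1 % of-plateau noise. The noisy-recovery
benchmark uses generating rates (ka1 = 10⁴ M⁻¹s⁻¹, kd1 = 5×10⁻⁴ s⁻¹,
ka2 = 10³, kd2 = 10⁻²) whose dynamics are resolvable within the 300/2400 s
observation window; a dissociation rate of order 2×10⁻⁵ s⁻¹ decays only
~5 % in 2400 s and is fundamentally weakly identified at percent-level
noise, which is a property of the assay design, not of the optimizer.
Optimizer tolerances are xtol = ftol = gtol = 1e-14 with max_nfev = 2000
per start. The agglomerative cut falls back from `maxclust` to an explicit
dendrogram-height cut in the degenerate case of tied merge heights.

## Known limitations

* The series encoding of sites (and hence the clustering) sees sequence
  proximity, not 3-D proximity.
* Per-concentration averaging propagates fit noise into averaged KD as an
  average of ratios; with few concentrations its sd understates
  uncertainty. The global-fit mode is the statistically stricter
  alternative.
* The two-site model is phenomenological; a good fit does not establish two
  physical site classes.
* The depletion model covers one site class at a time; simultaneous
  competition of one ligand pool across classes is not modelled.
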