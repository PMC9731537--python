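# Methods

## The analysis in one paragraph

Clinical diagnoses of Alzheimer's disease (AD) do not always track the
underlying biology: tau pathology and cognitive symptoms can disagree.
This package implements a cluster-based revision of diagnostic labels
for a baseline dementia cohort.  A heterogeneous per-participant table
(sociodemographics, cognitive and functional assessment scores, and
regional tau-PET/MRI uptake values) is embedded with UMAP, partitioned
with k-means, and the cluster dominated by clinically diagnosed AD
cases is identified.  Every CN or MCI case inside that cluster is
promoted to AD — the working hypothesis being that their biomarker
profile, not their symptom-based label, reflects their true disease
state.  The revision is quantified with Cohen's kappa against the
original labels and validated post hoc against biomarkers held out of
the clustering (CSF amyloid-beta in particular).  Finally, an
auto-metric graph neural network (AMGNN) is trained twice — once per
labeling — and the two are compared over repeated splits.

## Synthetic cohort

No participant-level cohort ships with the package; a generator
(`adrelabel.synthetic`) emulates the statistical structure the analysis
needs, so every stage is testable end to end.

**Composition.**  559 participants in five latent clusters whose sizes,
age/education/gender profiles, and per-cluster diagnosis counts follow
the cluster table the analysis is designed to produce: an AD-like
cluster (n=50; 6 CN / 18 MCI / 26 AD observed), a mixed catchall
cluster with intermediate pathology (n=166), male-only and female-only
clusters (n=131 each), and a younger cluster with strong parental
family history (n=81).  Observed class totals are exactly 363 CN /
137 MCI / 59 AD.  The 24 CN/MCI members of the AD-like cluster are
latently AD (the targets the re-labelling rule should recover); 33 AD
labels fall outside that cluster and must be left untouched.  For
non-default sizes the composition is re-apportioned deterministically
by largest-remainder rounding and validated against the class totals.

**Feature model.**  Features are conditionally independent Gaussians
(numeric) or categoricals given cluster and role — the simplest
structure that realizes the orderings the analysis checks:

* *Tau uptake* (`n_tau_marker` = 60 of the 177 imaging features,
  baseline N(1.25, 0.2)): shifted upward by the AD cluster's effect
  size (3.0 SD) scaled per member role — in-cluster AD cases 1.0,
  planted CN/MCI cases 0.9, AD cases outside the cluster 0.35, catchall
  members 0.2 of the AD effect.  The 0.9 discount keeps the AD cluster
  geometrically tight while leaving the re-labelled cases' uptake
  strictly intermediate between non-AD cases and the AD cases that
  remained in the cluster; the 0.35 level keeps outside-AD cases
  elevated yet anchored to their home clusters, as sociodemographically
  driven clusters retain their AD members in real cohorts.
* *Memory scores* (five composites plus ten correlated sub-items of the
  40 CFA features): depressed according to the *observed* diagnosis
  (CN 0, MCI 0.8, AD 1.0 of a 1.5 SD effect).  Cognition follows the
  clinician's label; tau follows the latent cluster.  Their deliberate
  decoupling on the planted cases is the premise of the analysis.
* *Sociodemographics*: gender respects the single-gender constraints
  exactly; APoE4 allele counts (0/1/2, one-hot encoded downstream) are
  enriched in the AD-like cluster; parental family history is near-
  universal in the young cluster.
* *CSF amyloid-beta* (exogenous, never a clustering feature): baseline
  N(1300, 300) minus 660 x an abeta severity (re-labelled cases 1.0,
  observed AD 0.68, catchall 0.4), reproducing the ordering AD cluster
  < catchall < remaining clusters, with the re-labelled cases showing
  more advanced amyloid pathology than the clinically diagnosed AD
  cases.
* *Missingness*: completely at random at rate 0.06 over the feature
  table (identifiers and labels never masked).  The mechanism of the
  emulated cohort's missingness is unknown; MCAR is an assumption.

What the generator does **not** emulate: feature covariance within
blocks (beyond the shared shifts), longitudinal visits, raw images,
site effects, or informative missingness.  Passing tests therefore
demonstrate that the pipeline's logic is correct under a known ground
truth — not that the clustering would behave identically on a real
cohort.

`strong_effect_config()` provides a noiseless, well-separated variant
(no planted noise, larger effects, sharper categorical signatures) used
to check that the embedding/clustering stack can recover all five
latent clusters (adjusted Rand index >= 0.8) when they are genuinely
separable.  Under the default configuration only the AD cluster is
strongly separable — which is all the re-labelling rule needs — and
the gender clusters deliberately blur into the manifold.

## Preprocessing

Order: similarity imputation of the sociodemographic block -> mean/mode
imputation of everything else -> one-hot APoE4 -> shifting of negative
columns by |column minimum| -> min–max normalization.  The similarity
imputer scores rows by a Gower-style mean of per-feature similarities
over shared observed features, keeps the ~10 closest complete rows and
copies from the single closest (ties to the lowest sample id).
Constant columns normalize to all zeros rather than being dropped, so
column counts are stable.  The chain is idempotent on its own output to
1e-12, and shift-then-normalize is numerically identical to
normalization alone (affine invariance) — both asserted in tests.

## Embedding, clustering, feature ranking

UMAP with 30 neighbours (to avoid very local structure), minimum
distance 0 (to densify clusters) and 5 output dimensions, seeded and
single-threaded for bit-reproducibility; k-means with k = 5, greedy
(++-style) seeding, 10 restarts.  Both k and the dimensionality were
selected by inspection in the analysis this pipeline operationalizes;
they are configuration here, not inference.  Features are ranked by
information gain in bits, IG = H(cluster) − H(cluster | feature), with
continuous features discretized by equal-frequency binning into 5 bins
(robust to skew; the discretization is a convention, checked against a
brute-force plug-in entropy oracle on small instances).

## Re-labelling and validation

The AD cluster is the argmax of within-cluster AD proportion (ties to
the lowest index).  The proportion criterion rather than an absolute
majority generalizes to settings where no cluster crosses 50%.  The
rule only ever promotes CN/MCI to AD; AD labels are never demoted,
anywhere.  Agreement is unweighted three-class Cohen's kappa.  The
post-hoc validation groups are: non-AD, CN/MCI-to-AD (the re-labelled
cases), remained AD, and the AD cases outside the AD cluster; group
summaries report n, mean, and SD (n−1 denominator).  Group contrasts
use Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
freedom (two-sided).

## The auto-metric GNN

Episodic (meta-task) training for few-shot node classification:

* **Episode**: 64 nodes — 5 labelled supports per class during training
  (one per class at test: one-shot) plus query nodes.  Training queries
  are drawn with class-balanced quotas; with the cohort's 65/25/10
  imbalance, prior-dominated episodes otherwise collapse the argmax to
  CN.  Test queries partition the held-out split; supports always come
  from the training split, so no held-out sample is ever a support.
* **Auto-metric graph**: edge weight(i,j) = softplus(MLP(|g_i − g_j|))
  over the sociodemographic graph features (gender, age, education,
  parental family history), self-edges included, rows normalized to sum
  to 1.  Each of the two GNN layers owns one such two-layer similarity
  network — four transform layers in total.  At initialization the
  metric is monotonically decreasing in every feature difference
  (non-negative first layer, non-positive second), so identical
  participants start maximally connected; training reshapes it freely.
* **Node update**: H' = ReLU(H W_self + A H W_nbr + b).  The self
  transform is essential: without it two rounds of row-normalized
  averaging smooth away per-node information and the classifier cannot
  beat class priors.  Node inputs concatenate the full 226-dimensional
  preprocessed feature vector with the support's one-hot label (queries
  get a uniform placeholder).  The second layer maps to 3 class logits;
  scores are softmax-normalized.
* **Training**: 300 iterations, one episode and one Adam step (lr 1e-3)
  per iteration, cross-entropy on query nodes.  All parameters live in
  a compact reverse-mode autodiff core (`adrelabel.autodiff`) whose
  gradients are finite-difference-checked in the tests.
* **Evaluation**: macro one-vs-all AUC (Mann–Whitney with half-credit
  ties, averaged over classes present in the test labels) and balanced
  accuracy (mean per-class recall).  Class scores are averaged over 3
  one-shot coverages of the test pool, damping support-draw noise.
* **Paired experiment**: repeat r re-splits the data with seed
  base + r; both labelings are trained and evaluated on identical
  splits; the per-repeat macro AUC pairs feed a two-sided Welch t-test.
  On synthetic data the queries are scored against the latent ground
  truth, which neither arm observes.

## Problem sizes and numerical choices

The shipped tests run the full 559-sample cohort end to end; the paired
experiment uses 10 repeats of 300 iterations in the test suite and 30
repeats in `scripts/acceptance.py` (the full repetition protocol).
Training 300 iterations takes a few seconds on one CPU.  An episode's
loss is undefined if every query class is absent — the sampler
guarantees supports per class and raises otherwise.  Constant columns,
empty tables, zero-iteration training, and single-repeat experiments
are all defined no-op/degenerate paths rather than errors; see the
operation docstrings.

## Known limitations

* The generator's conditional-independence structure understates the
  correlation of real imaging features; absolute AUC levels on
  synthetic data should not be read as expected performance on a real
  cohort.  The *comparison* between labelings is the meaningful output.
* k and the embedding dimensionality are fixed inputs; no model
  selection is attempted.
* The similarity imputer is O(n_missing x n_complete) in distance
  evaluations — fine at cohort scale, not tuned for biobank scale.
* Balanced accuracy on the synthetic cohort (~0.73–0.84) trails the
  AUC because CN/MCI boundaries remain genuinely fuzzy at the default
  effect sizes.
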