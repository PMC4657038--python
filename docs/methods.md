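# Methods

## Compound handling

Structures are parsed with RDKit and standardized by keeping the fragment
with the most heavy atoms (preferring carbon-containing fragments; ties
broken by lexicographic canonical SMILES), applying RDKit's canonical
tautomer, and emitting canonical SMILES. This is idempotent by construction.
Ionization-state and stereoisomer enumeration are deliberately out of scope:
ligand representations arriving in docking tables are treated as opaque ids,
whatever upstream tool produced them.

Fingerprints are RDKit Morgan sparse count fingerprints at radius 2
(ECFP4-equivalent); only the set of hashed environment ids is kept, since
the classifier is binary-feature based. All downstream code treats a
fingerprint as a plain set of integers, which is what allows purely
synthetic libraries (feature sets with no underlying molecule) to flow
through every stage.

The physicochemical profile is MW, H-bond acceptor/donor counts, rotatable
bonds, topological PSA and Crippen logP. The logP is RDKit's
Wildman–Crippen implementation; pipelines built on other toolkits may use
the Ghose–Crippen ALogP variant, which differs slightly in parameterization
but not in the ≤ 5 drug-likeness regime the filter operates in.

Potencies (IC50/Kd/Ki) are p-transformed as −log10 of the molar value; a
`units` column (nM/µM/mM/M) is mandatory in activity tables to avoid silent
unit errors. Compounds with several measurements are collapsed to the
median p-activity. Compounds without any measurement for the target are
labeled presumed-inactive, mirroring how large curated activity databases
are used for model training.

## Laplacian-modified Naïve Bayes

The per-feature weight is the Laplacian-corrected relative frequency

    w(f) = ln[(A_f + 1) / (T_f · p + 1)],

the canonical published form of this classifier family; a feature never
seen in training has A_f = T_f = 0 and weight 0, so out-of-domain features
are neutral rather than harmful. The raw compound score is the sum of
weights over its features.

**EstPGood.** The normalized probability is the two-Gaussian posterior:
Gaussians are fitted by sample mean/SD to the training-set raw scores of
each class (σ floored at 1e−6) and combined with the class prior,
prior·g_A(s) / [prior·g_A(s) + (1−prior)·g_I(s)], evaluated in log space.
The exact functional form used by commercial implementations of this score
is not published; the two-Gaussian posterior is this package's concrete
choice and matches the score's documented behavior (normalized, comparable
across models, monotone in the raw score for well-separated classes).

**Binary calls.** The class threshold is chosen on training scores to
minimize FP + FN over all midpoints between adjacent distinct scores; ties
break toward the lower threshold (more sensitive). With a ~10% active prior
this yields a conservative cutoff; the EstPGood floor in the screening
cascade is the second, softer probability control.

**Cross-validation** is 20 random stratified 50/50 splits by default
(leave-one-out is available for small curated sets), reporting per-run and
mean ROC/EF. The RNG is an explicit seed everywhere; two runs with the same
seed are identical.

## Docking-score fusion

"Top" means minimum at every level because docking scores are
better-is-lower; this is stated prominently since many fusion codes assume
the opposite. MeanTopK over fewer than K values falls back to the mean of
what is available (logged at debug level). Missing protein models for a
compound simply shrink the protein-level candidate set — no imputation.
Aggregation is implemented as three successive pandas group-bys (poses →
representations → proteins) and is validated in the test suite against an
independent dictionary-based reference that materializes each level
explicitly, over random tables and all 18 schemes. Output order is
ascending fused score with compound-id tie-break, so downstream files are
byte-reproducible.

Selection thresholds are mean − k·SD (sample SD) of a fused-score
distribution. In the screening cascade the distribution is that of the
cascade survivors — the docked-compound population — so the −2/−3 SD
cutoffs adapt to each campaign's score scale.

## Evaluation statistics

ROC is computed through the Mann–Whitney identity (average ranks, ties
counted one half), which is exact under ties and equals trapezoidal
integration of the ROC curve on tie-free data; both routes are compared in
tests. EF uses ceil for the subset size and breaks ranking ties by
compound id. Chemotype grouping uses leader (sphere-exclusion) clustering
on Tanimoto similarity — a deterministic stand-in for maximum-common-
substructure clustering, documented as a methodological substitution; with
fingerprint inputs it gives the same "conserved chemotype" granularity at a
fraction of the cost. Per-cluster Pearson R² between consensus docking
score and median p-activity is reported only for clusters of ≥ 3 members
and marked undefined under zero variance.

## Signature population statistics

Pairwise Pearson correlations are computed across genes for every unordered
pair of perturbation z-score signatures (a zero-variance signature is an
error naming the perturbation). Pairs are partitioned by a perturbation →
target annotation into within-target-A, within-target-B, cross-A–B, and
Other; a perturbation annotated with both targets is rejected because the
four populations must partition the pairs. Populations are compared with
Welch's two-sample t-test (unequal variances, Welch–Satterthwaite df),
implemented from the closed-form formulas and checked against an
independent statistical routine to 1e−10. Restriction to one cell
line/dose/time and to quality-flagged signatures is a metadata filter on
the input table, not hard-coded.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure each stage consumes,
at desk scale:

* **Labeled compound sets** — actives carry a block of 25 marker features
  at rate 0.5 vs a 0.05 background (600-feature pool, 100 actives / 900
  inactives by default). The effect size was set by a forward design
  calculation: it gives an expected log-weight-sum separation of ≈ 2.7 SD
  beyond the error-minimizing threshold, i.e. per-model sensitivity ≈ 0.99
  and cross-validated ROC ≈ 0.99 — the regime reported for well-trained
  kinase classifiers on large knowledge bases.
* **Decoys** — per seed active, property-matched within ±25 Da MW and ±1
  HBA/HBD while capping Tanimoto to every active at 0.35, by sampling from
  a mostly disjoint feature pool with bounded retries.
* **Docking tables** — 9 protein models, 1–3 representations per compound,
  1–5 poses each; pose scores N(−9, 1) for planted actives vs N(−5, 1)
  otherwise. The 4σ pose-level separation survives min-aggregation (both
  classes shift down together), giving consensus ROC ≳ 0.99.
* **Signatures** — a shared-factor model: every signature loads on a global
  factor (between-group r = 0.05) and group members on an additional group
  factor (within-group r = 0.4); groups default to 12 + 4 + 50
  perturbations × 200 genes, matching the target-group sizes used in the
  population tests.
* **Screen scenario** — a 2,000-compound library with 40 planted dual
  actives (markers *and* good docking scores), 760 classifier-only actives
  and 1,200 background compounds, plus two independently drawn training
  sets. The classifier-only majority keeps the survivor score distribution
  dominated by non-binders, so the −2 SD threshold sits between the two
  score modes and recovers ≈ 90% of planted duals; the residual loss is
  mostly the realistic ~5% attrition of the property filter.

What passing these conditions does **not** show: real screening libraries
have correlated features (shared scaffolds), activity cliffs, assay noise
and heterogeneous decoys; real docking scores are not Gaussian and their
errors correlate with chemotype; real signatures have heavier tails and
batch structure. The synthetic results validate the machinery and its
statistics, not prospective hit rates.

## Numerical and design choices

* EstPGood is computed in log space; far-tail scores saturate cleanly at
  0/1 instead of overflowing.
* Sample SD (ddof = 1) is used for thresholds and Gaussians; σ floor 1e−6.
* All rankings break score ties by compound id, and all CLI output uses a
  fixed float format, so identical seed + config ⇒ byte-identical files.
* Interactive survivor selection is replaced by a deterministic policy,
  with an optional secondary policy whose survivor union emulates the
  "strict properties / relaxed probability" trade; vendor availability and
  manual review are represented by an allow-list hook, and an optional
  leader-cluster diversity pass (default cutoff 0.6) keeps one hit per
  chemotype.
* Problem sizes used in the validation suite (1,000-compound training
  sets, 2,000-compound libraries, ≤ 200-row fusion oracle tables, 100
  random seeds for oracle equivalence) were chosen as the smallest scales
  at which the planted statistical structure is unambiguous.

## Known limitations

* No docking engine, pose geometry, or grid generation: the fusion stage
  starts from externally produced per-pose score tables.
* No ionization/tautomer/stereoisomer enumeration; representation ids are
  opaque.
* Single-target binary models only; no multi-class or kinome-wide models,
  no feature selection.
* Confidence intervals on ROC/EF are not computed.
* The leader-clustering substitution for MCS clustering changes cluster
  boundaries for series defined by a common core with large variable
  decorations.
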