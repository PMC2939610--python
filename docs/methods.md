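# Methods

## Model

### Bayes-factor association

The unit of testing is the 2×3 case/control-by-genotype count table. The
model is prospective: genotype is treated as known and case status as the
outcome. Under H₀ every individual is a case with probability θ; under H₁
an individual of genotype class *j* ∈ {AA, AB, BB} is a case with its own
probability θⱼ. Each θ gets an independent Uniform(0,1) prior, so both
marginal likelihoods reduce to products of Beta functions and the log Bayes
factor is

    BFLn = Σⱼ ln B(n_jA+1, n_jU+1) − ln B(n_A+1, n_U+1).

The combinatorial constant common to both hypotheses cancels and is never
represented. Everything is computed in log space through the log-gamma
function (`scipy.special.betaln`); forming the Beta function directly would
overflow for cohort-scale counts. The decision rule is strict: BFLn > 0
supports association, BFLn = 0 (every single-genotype or empty table,
exactly, by analytic cancellation) counts as non-support.

The formula is symmetric under case/control exchange and under any
permutation of the genotype columns; both symmetries are property-tested.
Under the *marginal null* — genotype margins fixed, one θ ~ Uniform(0,1)
shared by all classes — E[BF] = 1 exactly. Note the caveat: this
expectation is carried by an astronomically heavy tail (at margins 40/40/40
the exact Var(BF) ≈ 2×10²⁵), so a Monte-Carlo mean of any feasible number
of replicates sits far below 1 with a misleadingly small sample SE. The
test suite therefore verifies the identity by exact enumeration of the
table space, and checks the simulator against the exactly computed null law
(support probability, true-variance SE) rather than against a sample SE.

### QC

Markers pass three rules, checked in order and logged per rejection:

* **call-rate proxy** — total count ≥ 0.95 × cohort size (largest total in
  the batch); genotype counts carry no per-individual missingness, so the
  total stands in for call rate;
* **MAF** — pooled minor-allele frequency ≥ 0.01;
* **HWE** — 1-df χ² goodness-of-fit on *control* genotype counts, reject at
  p < 10⁻⁶; a marker with zero controls skips the rule with a warning.

Defaults follow common GWAS practice and are all configurable.

### Gene mapping

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on read. A SNP maps to the containing gene, else to the
nearest gene on its chromosome within 500 kb, distance measured to the
nearer interval boundary. Nearest-gene ties break to the lexicographically
smallest gene id — deterministic and order-independent. SNPs farther than
500 kb from every gene are discarded. A gene enters the test set if it
received ≥ 1 significant SNP and shares ≥ 1 base with a disease locus;
overlap rather than containment is used because locus boundaries are
coarse. One gene per SNP; known disease genes (the SVM positive class) are
removed from the test set since they need no prediction.

### Feature vectors

Dims 1–20: amino-acid composition over the 20 standard residues in fixed
alphabetical one-letter order; non-standard letters are excluded from both
numerator and denominator and tallied in a warning. Dims 21–26: crystal
unit-cell lengths a,b,c (Å, positive) and angles α,β,γ (degrees, in
(0,180)). Dims 27–28: helical and β-sheet fractions. Dims 21–28 together
are the "secondary" subset used for the reduced classifier — the name is
kept although 21–26 are unit-cell parameters, not secondary structure.
Helix/sheet values above 1.5 on input are interpreted as percentages and
divided by 100 (logged), avoiding silent unit bugs. Genes without crystal
records keep NaN entries plus a missing mask; the default policy imputes
the training-set mean at standardization time, a strict mode can drop them.
When one gene has several sequence records the first wins (logged).

### SVM screen

Classifier: C-support-vector machine with RBF kernel (scikit-learn's libsvm
binding), C = 1, γ = 1/n_features. These are library-conventional defaults,
recorded in the run report; the study this design follows did not state
hyperparameters. Features are z-standardized per training set (mean/sd from
the training rows only, missing values imputed with the training mean;
zero-variance dims map to 0) — mixing fractions, Ångströms and degrees in
an RBF kernel without scaling would let the large-unit dims dominate.

Each randomization draws all positives plus an equal-size uniform
without-replacement sample of negatives (seed = master + i). Performance is
pooled n-fold CV: one seeded shuffle, n splits, confusion counts summed
over held-out folds, then Qp = TP/(TP+FN), Qn = TN/(TN+FP),
Qa = (TP+TN)/total. Pooling (not per-fold averaging) was chosen so Qa is
exact at any fold size; the identity Qa = weighted mix of Qp and Qn is
asserted on every run. A training split with one class triggers one
reshuffle, then an error.

Ensemble prediction trains one classifier per randomization and labels
every test gene; the final candidates are genes positive in at least
`keep_fraction` of randomizations. `keep_fraction = 1.0` (the default) is
the strict intersection; the vote fraction and the mean signed decision
margin (disease-likeness) are reported per gene regardless. The
intersection is monotone non-increasing in the number of randomizations —
strictness is a budget choice, and a per-gene drop probability of ε becomes
1−(1−ε)^R over R randomizations. This is visible in the end-to-end fixture:
genes voted positive 99% of the time are dropped by the strict rule.

### Functional screen

For each namespace (PIRSF, GO, KEGG; read from GMT files) a category with
*k* of the *K* disease genes among its *n* members in a universe of *N* is
scored with the one-sided hypergeometric tail P(X ≥ k). Enriched =
p ≤ 0.05 and k ≥ 2; no multiple-testing correction by default because the
screen is deliberately inclusive (Benjamini–Hochberg available). The
universe defaults to all genes in the catalog. A candidate keeps
f_ns = 1 iff annotated to ≥ 1 enriched category of namespace ns, and
f = f_PIRSF ∨ f_GO ∨ f_KEGG decides retention. Genes with no annotation
anywhere get f = 0: absence of evidence of shared function is treated as
failure to demonstrate similarity. GO ancestor propagation is out of scope;
terms are matched as given.

### GWAS baseline

The 2×3 table is reduced to allelic counts (2 per homozygote, 1 per het) —
the standard 2×2 reduction; the 2×3 exact test is out of scope. Two-sided
Fisher exact p-values (scipy) are screened at α/n_tests, or at a literal
user-supplied threshold for mirroring an externally fixed study-wide
cutoff. The overlap report (sizes, intersection, Jaccard) quantifies the
divergence between the strict baseline and the inclusive multidimensional
screen.

## Synthetic fixtures

The generators emulate the inputs, not the biology:

* **Genotype counts** — prospective sampling: HWE genotype draws
  (p², 2p(1−p), (1−p)²) for n individuals (or fixed per-genotype margins),
  then Bernoulli(θ_genotype) case status. Causal SNPs get distinct
  (θ₀,θ₁,θ₂); null SNPs share the genotype-averaged θ; marginal-null mode
  draws one θ ~ U(0,1) per SNP (the E[BF] = 1 design). Counts are generated
  per genotype class by binomial draws, which is distributionally identical
  to per-individual simulation.
* **Toy genome** — non-overlapping genes slot-packed into the leading 80%
  of each chromosome (the tail stays gene-free so >500 kb "far" SNPs
  exist); SNPs placed inside genes (round-robin, guaranteeing coverage),
  near them, or far, in set proportions; one padded locus per designated
  gene, clipped so no undesignated gene is touched. Truth records the
  brute-force SNP→gene assignment.
* **Protein features** — class-conditional Gaussians over the 28 dims; the
  requested separation is the Mahalanobis distance between class means,
  spread evenly over the signal dims (alternating sign within composition
  so the simplex sum is preserved), then mapped back onto the constraints
  (simplex, angle and fraction ranges). Sequences realizing a composition
  are built by largest-remainder rounding at length 500 and shuffled, so
  recomputing composition from sequence loses < 1/500 per residue.
* **Annotations** — a few designated disease categories receive each
  disease gene (and each designated co-clustered gene) with probability
  `clustering_strength`; every gene gets Poisson(2) background categories.
  Strength 0 removes the signal entirely.

The end-to-end fixture defaults — 2,000 SNPs, 200 genes, 20 causal genes
covered by loci (plus 10 decoy loci), 30 known disease genes, 2,000
individuals, per-genotype case probabilities (0.35, 0.50, 0.65), feature
separation 4, clustering strength 0.9 — are desk-scale study conditions
chosen so every screen has genuine work to do: the Bayesian screen admits
~5–7% false-positive SNPs, decoy-locus genes reach the test set, and the
SVM/functional screens must remove them. Pipeline runs for tests and the
acceptance script use 200 SVM randomizations; production-scale values
(10,000 randomizations, genome-scale SNP counts) are plain configuration.

What passing tests do **not** show about real data: no linkage
disequilibrium between SNPs (each SNP is independent), no population
stratification or covariates, protein features are unimodal Gaussians
rather than real structure distributions, sequences are random residue
bags, and annotation catalogs have none of GO's hierarchical redundancy.
Recovery rates on the fixture therefore bound nothing about any real
cohort; they verify the machinery, including its failure modes (e.g. the
strict-intersection recall cost).

## Numerical choices

* All Beta/log-gamma computation in log space; exactness against a
  rational-arithmetic oracle is asserted to 10⁻⁹ across an exhaustive sweep
  of small tables.
* HWE χ² skips expected-zero classes (their observed counts are
  necessarily zero).
* Score ordering ties break by SNP id; nearest-gene ties by gene id; every
  output list is sorted — two identically seeded runs produce byte-identical
  reports (asserted).
* Per-randomization seeds are master + counter; `numpy.random.default_rng`
  throughout.
* Degenerate inputs: the all-zero genotype table is legal (BFLn = 0); a
  zero Fisher margin gives p = 1; an empty test set yields an empty
  ensemble; an empty locus list yields an empty genetic screen with a
  warning.

## Known limitations

* One gene per SNP; multi-gene assignment and LD-aware mapping are not
  implemented.
* The HWE test is the plain 1-df χ², not an exact test; at very small
  control counts its p-values are approximate.
* The SVM stage refits the scaler per randomization, so with extremely
  small positive pools the standardization itself adds training variance.
* The hypergeometric screen treats namespaces independently; no correction
  is applied across namespaces.
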