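# Methods

## Model and assumptions

`pacscore` treats annotation assessment as binary classification of each
gene's functional annotation into *correct* (A_c) versus *incorrect*
(A_inc), given the functional similarity the gene shows to its chromosomal
neighborhood. The biological assumption is the well-established clustering
of function along bacterial chromosomes: a correctly annotated gene tends
to resemble its neighbors — operon mates above all — while a wrongly
annotated gene resembles them no more than chance.

Term-level similarity is the Jaccard index of is-a ancestor sets
(excluding the namespace root, which carries no information); gene-level
similarity (GFS) is the maximum over all cross pairs of the two genes'
term sets, computed separately per GO namespace. Each gene's evidence is
the vector of GFS values to the six neighbors at offsets −3…+3 in the
gene order of its replicon, per namespace: up to 18 observations. The
posterior (PAC) combines them by Bayes' rule under conditional
independence, with both class priors fixed at 0.5. Observations that do
not exist (either gene unannotated in a namespace) are skipped from both
class likelihoods — equivalent to assuming missingness is uninformative
about correctness.

The incorrect-annotation class is defined operationally by a
randomization null: every annotated gene receives the complete
per-namespace term sets of a protein drawn uniformly (with replacement
across genes) from a background pool. Randomization deliberately preserves
*which* genes are annotated and only destroys *what* the annotation is.

Class-conditional likelihoods are empirical: GFS values are discretized
into equal-width bins over [0, 1] and per-cell bin frequencies are
Laplace-smoothed,

    Pr(bin | cell, A) = (count + α) / (N + αK),

with one cell per (offset, namespace) — the position-specific structure
mirrors the neighborhood indexing — estimated once from the genome under
its given annotation (taken as correct) and once under the randomized
annotation. Binned frequencies are the minimal-assumption estimator for a
mixed discrete/continuous quantity like GFS, whose mass concentrates at 0
and 1; smoothing keeps every likelihood positive so no single observation
can force PAC to exactly 0 or 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 3 | neighbors per side (gene counts, not base pairs) |
| `prior_correct` | 0.5 | class prior Pr(A_c) |
| `term_frequency_cutoff` | 0.05 | background frequency above which a GO term is discarded |
| `n_bins` | 10 | equal-width GFS likelihood bins over [0, 1] |
| `pseudocount` | 1.0 | Laplace smoothing α per bin |
| `mode` | `plain` | `plain`, `operon`, `strand` or `dependent` |
| topology | `circular` | per replicon; linear replicons truncate the window at ends |

Abundant-term filtering removes terms whose frequency among GO-annotated
background proteins exceeds the cutoff (strictly greater), both from
direct annotation sets and from ancestor sets during similarity scoring.
The second removal is a deliberate design choice: an abundant ancestor of
a retained rare term would otherwise re-introduce exactly the spurious
overlap the filter targets. Filtering only the direct sets remains
available by passing an empty exclusion set to the similarity scorer.

The genome AQS is the fraction of eligible genes (≥ 1 available GFS) in
the PAC histogram bin [0.95, 1]; the histogram uses 20 bins of width
0.05 with the last bin closed, so the headline bin is exactly one bin.

## Model variants

* **Operon model** — GFS observations to neighbors outside the gene's
  operon are treated as missing, so only co-operonic evidence counts.
  Genes in singleton operons (or without an operon call) become
  ineligible; the restriction trades coverage for specificity.
* **Strand model** — each (offset, namespace) cell splits into same- and
  opposite-strand sub-tables, i.e. the GFS likelihood is conditioned on
  strand agreement. The strand flag itself has identical distribution
  under both classes (geometry does not change with annotation), so
  conditioning captures all usable strand information.
* **Dependent model** — per direction the likelihood factorizes as a
  first-order chain, Pr(O±1|A)·Pr(O±2|O±1,A)·Pr(O±3|O±2,A), with each
  conditional a row-stochastic K×K table estimated like the marginals.
  When a conditioning observation is missing, the conditioned observation
  falls back to its marginal table — the closest consistent completion,
  and with conditionals equal to marginals the model reduces exactly to
  the independent one.

Likelihood tables serialize to versioned JSON, so conditional
probabilities fitted on a data-rich genome can score a sparsely annotated
one (`fit(likelihoods=...)`); a strand-mode table set refuses to score
plain profiles and vice versa.

## Shuffle experiment

Sensitivity to a controlled error load: Nr pairs of GO-annotated genes
are drawn without replacement within an experiment, their complete
annotation sets swapped, and the genome re-scored with the likelihood
model held fixed at its unshuffled estimate (the experiment probes
scoring sensitivity, not estimation). No check prevents swapping similar
or identical annotations. Repeats use child seeds `seed + repeat index`,
recorded in the output for replay. Nr = 0 short-circuits to the
unshuffled scoring (zero SD by construction).

## Synthetic studies

The generator emulates the single statistical property the method reads
from real data. Per namespace it grows a random rooted is-a DAG (default
60 terms; each new term attaches below 1–2 earlier terms). A circular
gene order (default 2000 genes) is partitioned into operons with
geometric sizes (mean 3), one strand per operon. Each (operon, namespace)
pair gets a uniformly drawn non-root "theme" term; an annotated gene
(probability 0.7 per namespace, 1 + Poisson(1) terms) draws each term
from the theme's sub-DAG with probability ρ·(1 − noise) (defaults ρ = 0.8,
noise = 0.1) and uniformly from the namespace otherwise. All randomness
descends from one seed through named substreams (ontology / genome /
annotation).

What the generator does **not** emulate: realistic GO topology (term
counts, depth, fan-in), realistic per-gene term multiplicity, intergenic
distances, partially correct annotations, or between-operon functional
gradients along the chromosome. Passing tests on synthetic data therefore
demonstrate the machinery's correctness and the method's qualitative
behavior (separation, operon sharpening, shuffle degradation), not
quantitative performance on any real genome.

## Numerical choices

* PAC products run in log space with a single exponentiation after
  subtracting the max — 18 small factors underflow naive arithmetic.
* Bin assignment snaps values within 1e-9 of a bin edge upward: in binary
  floating point 0.95 × 20 evaluates to 18.999…, which would silently
  drop an exact 0.95 out of the closed top bin.
* A replicon shorter than 2·window+1 drops colliding window offsets
  rather than revisiting a neighbor (or reaching the gene itself).
* Empty likelihood cells are uniform under smoothing and an error when
  α = 0; a genome with no eligible genes has AQS NaN, and empty
  calibration bins report NaN (empty, not zero).
* Estimation is order-invariant; all stochastic steps take explicit seeds.

## Problem sizes

The test suite and the reproduction script run the default 2000-gene
study (module-level tests use 400–600 genes); the shuffle experiment uses
20 repeats over Nr ∈ {0, 10, 25, 50, 100}. These sizes give stable
statistics (per-cell likelihood sample sizes in the thousands) while the
whole suite completes in well under a minute of compute.

## Known limitations

* The independence assumption is knowingly violated: the six window
  observations share the focal gene's own term set, the three namespaces
  share the operon geometry, and operon themes correlate neighbors. The
  result is mild overconfidence — an S-shaped reliability curve with
  per-bin deviations of up to ~0.16 from the diagonal at the default
  synthetic conditions (positive in low bins, negative in upper-middle
  bins) while the decisive [0.95, 1] bin stays within ~0.03. The
  dependent model exists to absorb first-order neighbor correlation but
  does not address within-gene sharing.
* Likelihoods are estimated on the same genome they score (matching
  standard practice for this design); cross-genome transfer is the
  supported remedy for sparse genomes.
* Only is-a edges are used; part_of/regulates semantics and
  information-content similarities are out of scope.
* Operon calls are taken as given; the model does not infer operons.
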