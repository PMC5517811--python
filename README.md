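# pacscore

Bayesian assessment of bacterial genome annotation quality from
gene-neighborhood functional similarity.

Functional annotations of sequenced bacterial genomes are produced by
automated pipelines, and there are few tools to ask *how good* a set of
functional assignments is. `pacscore` exploits a robust property of
bacterial chromosomes — functionally related genes cluster physically,
most strongly within operons — to score every gene's annotation by how
consistent it is with the annotations of its chromosomal neighbors. It is
aimed at people who build or compare annotation pipelines and at anyone who
needs a confidence value for individual gene annotations (e.g. to triage
hypothetical-protein assignments).

## The model

For two GO terms with ancestor sets *S₁*, *S₂* (each term plus all of its
is-a ancestors, excluding the namespace root):

    GOsim(GO₁, GO₂) = |S₁ ∩ S₂| / |S₁ ∪ S₂|

For two genes with term sets *A₁*, *A₂* in one namespace (BP, MF or CC),
gene function similarity is the best matching pair:

    GFS(G₁, G₂) = max over GOᵢ ∈ A₁, GOⱼ ∈ A₂ of GOsim(GOᵢ, GOⱼ)

Each gene *G* presents an observation profile *O* = {GFS(G, Gᵢ)} over the
six neighbors at offsets i = −3…+3 and the three GO namespaces (up to 18
observations). Conditional probabilities Pr(Oᵢ | A_c) are estimated from
the genome's given annotation (assumed correct) and Pr(Oᵢ | A_inc) from a
randomized annotation (each annotated gene receives the terms of a protein
drawn uniformly from a background pool), as Laplace-smoothed binned
frequencies per offset and namespace. The probability of annotation
confidence is the naive-Bayes posterior with priors 0.5:

    PAC(G) = Pr(A_c | O) =
        Π Pr(Oᵢ|A_c) · Pr(A_c) / [ Π Pr(Oᵢ|A_c) · Pr(A_c) + Π Pr(Oᵢ|A_inc) · Pr(A_inc) ]

Missing observations (a neighbor unannotated in a namespace) are skipped
from both products. The genome-level **annotation quality score (AQS)** is
the fraction of PAC-eligible genes (≥ 1 available GFS) with PAC in
[0.95, 1]. Abundant, uninformative GO terms (background frequency > 5%)
are filtered out before any similarity is computed. Variants: an **operon
model** (count only same-operon neighbors), a **strand model**
(strand-conditioned likelihoods) and a **dependent model** (first-order
chain factorization per direction instead of full independence).

## Worked example

The package ships a synthetic-study generator that emulates the one
statistical property the method reads from real genomes — operon mates
share function — so everything runs self-contained:

```python
from pacscore import AnnotationConfidenceModel, SimulationConfig, SyntheticStudy

study = SyntheticStudy(SimulationConfig(seed=1))   # 2000 genes, rho=0.8
model = AnnotationConfidenceModel(study.genome, study.annotations, study.graph)
res = model.fit(seed=1)
print(res.summary())
```

```
        Annotation Confidence Model Results
====================================================
Mode:            plain       Genes:          2000
Prior P(A_c):    0.5         Eligible:       1936
Bins:            10          PAC>=0.95:      712
Pseudocount:     1           AQS:            0.368
Cutoff:          0.05        AQS (random):   0.011
Filtered terms:  3           Seed:           1
====================================================
```

1936 of 2000 genes had at least one neighbor similarity available; 712 of
them (AQS 0.368) sit in the high-confidence bin [0.95, 1], against an AQS
of 0.011 for the randomized annotation — the model cleanly separates a
coherent annotation from a random one. Per-gene posteriors are in
`res.pac` (a DataFrame), the reliability curve in `res.calibration()`, and
`res.shuffle_experiment([0, 10, 25, 50, 100])` measures how the
high-confidence count degrades as annotation pairs are swapped.

The same pipeline runs from the shell on OBO + GAF + gene-table files:

```sh
pacscore simulate --seed 1 --out sim/
pacscore score --obo sim/ontology.obo --gaf sim/annotations.gaf \
    --genes sim/genes.tsv --seed 1 --out run/
pacscore build-model ... --out m/   # save likelihoods for cross-genome transfer
```

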