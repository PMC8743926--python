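# Methods

## Model and procedure

The pipeline operationalizes a simple idea: genes whose probes rank in the
top *K* of every required sample across a postnatal developmental window are
"constitutively highly expressed" there, and their mutational-study
annotations — summarized over the Mammalian Phenotype Ontology — describe
what those genes are needed for.

The stages and their contracts:

* **Array QC.** An array is excluded iff `background > 90`,
  `|actin_ratio| > 3` or `|gapdh_ratio| > 1`. The inequalities are strict, so
  boundary arrays are kept; each exclusion records every violated criterion.
  The metrics themselves are consumed, not computed — deriving them from raw
  CEL files (and RMA normalization) is upstream of this package. The QC
  ratios are treated as opaque signed numbers compared by absolute value;
  nothing downstream depends on their scale.
* **Top-K and intersection.** Ranking uses a total order — value descending,
  then probe ID ascending — and takes exactly `min(K, P)` probes, so tied
  values at rank K resolve deterministically. The intersection runs over
  samples flagged `required_for_intersection` in the sample sheet; the flag
  generalizes the exemption of the day-1 arrays in the reference analysis to
  any sample. Mean expression and variance are still computed over *all*
  QC-kept samples, exempt ones included.
* **Probe collapse.** Probes lacking the required MGI Feature Type
  (`protein coding gene`), or absent from the annotation table entirely, are
  dropped (with a logged count — an unmapped probe cannot demonstrate the
  required feature type). For genes hit by several probes the representative
  probe is the one with the highest mean expression over retained samples,
  ties broken by smallest probe ID; conflicting symbols for one MGI ID are a
  hard error. Expression variance uses the unbiased n−1 divisor.
* **Ontology levels.** Root = level 0, top-level phenotype classes = level 1,
  and a "level-4 term" sits four `is_a` steps below the root. The level of a
  multi-parent term is the *minimum* depth over parents — a term counts as
  level-N as soon as any path from the root reaches it in N steps — with a
  `max` convention available for sensitivity checks. Only `is_a` edges are
  honored; other OBO relationship types are ignored. Obsolete terms are
  parsed but excluded from every closure.
* **Propagation and truncation.** Per gene: union over its zygosity-filtered
  records of (direct terms ∪ all their ancestors), restricted to levels
  1–4, minus the descendant closures of `normal phenotype` and
  `no phenotypic analysis`, minus the root. Exclusion runs *after*
  propagation, so a legitimate term still contributes its ancestors when a
  sibling path is excluded. Direct term IDs that do not resolve in the
  supplied ontology are dropped and counted rather than fatal — ontology
  versions drift. Zygosity tokens default to the MGI-style codes `hm`/`ht`
  (case-insensitive) and are configurable; so is the level cutoff
  (`max_level`, default 4: the fourth level is specific enough for phenotype
  summarization while keeping term counts manageable).
* **Percentages.** Integer percent = round-half-away-from-zero of
  `100·k/n`, implemented in integer arithmetic
  (`(200k + n) // 2n`). This convention reproduces all 27 printed
  (count, %) pairs of the published first-level table at the 547-gene total
  and every text-level percentage except two published prose values
  (348/547 printed as 63%, which computes to 64%, and 139/547 printed as
  26%, which computes to 25%); the package reports computed values.
* **Co-annotation and trees.** Pair counts enumerate, per gene, all
  unordered pairs of its terms passing a level filter (default: level-4
  terms only, the most specific retained level — which levels fed the
  original pairwise script is unstated, so this is configurable). Phenotype
  trees keep, under each top-level term, the annotated nodes plus the
  zero-count internal nodes needed to connect them upward; pure zero-count
  leaves are pruned. Exported edges run parent → child.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes:

* **Expression** — several experiments over five postnatal time points
  (days 1, 10, 15, 21, 30; 2–4 replicates, 15 samples, day-1 samples exempt
  from the intersection), a planted set of constitutively-high probes
  (defaults: 2000 probes, 100 planted, Δμ = 4 log2 units, σ = 1), i.i.d.
  Gaussian noise on the log2 scale (RMA output is approximately Gaussian
  there), 1–3 probes per gene so deduplication is exercised, plus
  non-protein-coding and unmapped probe fractions (8% / 2%). A fourth
  "degraded" experiment with out-of-range 3′/5′ ratios exercises QC
  exclusion, mirroring the excluded experiment in the reference data.
* **Ontology** — a single-rooted `is_a` DAG with 29 top-level terms by
  default (27 abnormal classes plus the two excluded subtrees), Poisson
  branching to depth 6, optional second parents drawn from strictly
  shallower terms (guaranteeing acyclicity), one obsolete stanza, and a
  forced chain so level-4 truncation is always exercised.
* **Annotation** — geometric terms-per-gene counts (mean 3: most genes few
  terms, a few genes many), per-gene partition into unannotated (36%),
  normal-only (12%) and abnormal genes matching the study's observed
  tri-state proportions, distinct PubMed-style study IDs with an occasional
  empty study cell, and decoy records carrying disallowed zygosity codes
  whose terms must stay invisible to a correctly filtering pipeline.

Truth manifests (planted probes/genes, term levels, expected post-propagation
sets, expected status and study counts) are computed by plain BFS/recursion
over the generator's own structures, independent of the pipeline's graph
machinery.

Not emulated: raw CEL intensities, probe-level mismatch or spatial
artifacts, realistic inter-gene correlation, batch effects between
experiments, and ontology terms with multiple names or cross-references.
Passing tests therefore demonstrate the *logic* of the pipeline — not that
real hippocampus arrays would yield any particular gene set.

## Seeding and determinism

One master seed; per-component generators derive theirs by fixed offsets
(expression +11, ontology +23, annotation +37, QC +53, housekeeping +71).
Identical spec + seed reproduces every file byte-identically: tables use
fixed float formats and sorted orders, and the run manifest carries no
wall-clock fields (timestamps go to the log), so a rerun of `run-all` on
the same bundle is byte-identical — which the test suite asserts by
hashing.

## Numerical and design choices

* Ties anywhere (rank K, representative probes, output ordering) resolve by
  lexicographic ID so runs are order-independent.
* Output staging: results are written to a `.partial` directory and moved
  into place only on success, so a failed stage leaves no partial output.
* Problem sizes in the test suite and the acceptance script are scaled to a
  few hundred probes and terms; the planted-recovery and oracle-equivalence
  properties they check are size-independent.
* At σ = 0 with K larger than the planted probe count, deterministically
  tie-broken background probes enter the intersection alongside the planted
  ones; exact planted-set recovery holds when K equals the planted count,
  and that is how the zero-noise checks are run.
* Unknown configuration keys are rejected rather than defaulted, so typos
  cannot silently change an analysis.

## Known limitations

* Only `is_a` semantics; no reasoning over other MPO relationship types.
* Housekeeping matching is by exact (whitespace-stripped) gene symbol, as
  symbol lists are what housekeeping databases publish; identifier-level
  matching would require an extra mapping input.
* The heavy-tailed terms-per-gene family is a geometric stand-in chosen for
  its "few terms for most genes, many for a few" shape; the real
  distribution of curated annotations is not modeled beyond that.
* Multi-gene/multi-allele genotypes and conditional constructs are out of
  scope, as is any enrichment statistic — the summaries are raw counts by
  design.
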