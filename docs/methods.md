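# Methods

## The measurement

A pooled-injection transgenesis experiment injects a library of
uniquely barcoded integration plasmids into embryos, crosses the
surviving G0 males, and sequences the barcode amplicon from individual
F1 transgenic progeny. Because each germline integration event fixes
one library barcode into one pole-cell-derived germ cell, the number of
distinct barcodes recovered from a G0 fly's progeny counts the
independent integration events in that embryo. This package implements
that counting pipeline together with the simulator needed to test it
end to end.

## Simulation model (`tagem.synthetic_data`)

**Library.** Barcodes are uniform random 14-mers over {A,C,G,T},
deduplicated by rejection, default pool size 20,000 (the diversity of
the injected plasmid pool; with 4¹⁴ ≈ 2.7×10⁸ possible 14-mers a
20,000-member pool is collision-free by construction and within-embryo
barcode collisions are negligible).

**Germline biology.** Per embryo: survival ~ Bernoulli(`survival_prob`,
default 0.26 — embryo to scoreable adult, chosen so that ~1,713
injections yield ~225 scoreable males at a 0.5 male fraction, the scale
of a large robotic run); sex ~ Bernoulli(0.5); fertility ~
Bernoulli(0.83 ≈ 187/225). Pole-cell count is uniform on [12, 18]. Each
pole cell independently integrates, with probability
`per_cell_integration_prob`, one barcode drawn uniformly *with
replacement* from the pool; duplicates within an embryo collapse to one
unique barcode. The default integration probability is solved
numerically (`integration_prob_for_mean`) so that the mean number of
integrations in transgenic-producing embryos is 3.9 — the
independent-insertions-per-embryo regime the pipeline is designed to
measure (p ≈ 0.256).

Note an intrinsic property of this i.i.d.-per-cell model: at the
probability giving a conditional mean of 3.9 insertions, nearly every
injected germline receives at least one integration, so the fraction of
fertile crosses producing transgenics is higher than the ~53% a real
experiment shows. Real injections vary in delivered volume and
placement, which the model deliberately omits; the transgenic-fraction
statistic therefore enters through the `experiment_metrics` count
tables, not through this simulator.

**Cross design.** Only surviving, fertile, male, integration-bearing
embryos found scoreable lineages. Up to `progeny_sampled_max`
(default 10) F1 samples per lineage each inherit one barcode uniformly
with replacement from the embryo's true set — single-insertion
transmission, siblings may share. Duplicate-control pairs (default 7)
share one template drawn from a random transgenic lineage; blanks
(default 16) have none.

**Reads.** Each read is `pad + forward-primer core + barcode +
trailing flank`, with the pad chosen uniformly among the four
frameshift pads ("", "AG", "TCGA", "GAAGAG"; lengths 0/2/4/6) that
precede the shared 20 nt core `CTTCCAACAACCGGAAGTGA` in the
amplification primer pool, and the flank being the SV40-derived
sequence complementary to the reverse primer. Sequencing noise is
i.i.d. per-base substitution at `per_base_error_rate` (default 0.005,
typical Illumina amplicon error); qualities are constant Q37 because
the calling rule uses base identity only. Indels, chimeras, index
hopping and PCR duplicates are out of scope. Per-sample depth is
negative binomial with mean 1,000 and dispersion 5 (overdispersed, as
plate-based amplicon depths are); sub-threshold blanks instead draw a
uniform depth in [10, 400]. Blanks can alternatively be synthesized in
"mixture" mode — full depth, each read's barcode drawn uniformly from
the library — which exercises the mixed-call path instead of the
read-floor path. Per-sample seeds are spawned from the experiment seed,
so FASTQ output is bit-identical across runs.

## Barcode calling (`tagem.barcode_calling`)

Trimming is a Hamming-only (no indel) search for the primer core at the
four pad offsets, tried in order 0/2/4/6 with first-hit-wins, allowing
≤2 substitutions; the barcode is the 14 bases 3′ of the hit. The
trailing flank is not required for a call (single-anchor trimming);
`require_flank=True` additionally verifies the flank prefix. The
500-read floor applies to *successfully trimmed* reads, since the
analyzed unit is the trimmed barcode set.

The consensus rule is deliberately strict: a sample is called only if
at every position the modal A/C/G/T base exceeds `consensus_threshold`
(default 0.80) of trimmed reads — the comparison is `count >
threshold × n`, so an exactly-80% position is mixed. Ambiguous bases
count in the denominator but can never be modal, and a position where
two bases tie for modal never passes regardless of threshold. The
vectorised plate path (`trim_reads`) is semantically identical to the
per-read `locate_and_trim`, which the tests verify by round-trip.

## Lineage analysis (`tagem.lineage_analysis`)

Per-lineage unique counts use called samples only; mixed and
insufficient-read samples are ignored. The global total deduplicates
across lineages (two embryos can, rarely, integrate the same library
barcode; such collisions are reported). Mean insertions per embryo is
taken over transgenic-producing lineages only.

Because only ~10 progeny are sampled per lineage, the observed unique
count saturates below the true integration count. The estimator
inverts E[U] = K·(1 − (1 − 1/K)ⁿ) by bracketed root-finding (the
relation is strictly increasing in K); U = n has no finite solution and
returns ∞, in which case the summary falls back to the observed count
as a documented lower bound. n is the number of *called* samples in the
lineage, so depth dropouts are accounted for.

Rarefaction subsamples reads without replacement and counts raw
distinct trimmed barcodes; an optional `collapse_1mm` flag folds
barcodes within one mismatch of a more abundant barcode first (crude
denoising, off by default because the core measurement counts, not
denoises).

## Efficiency metrics and detection evaluation

`experiment_metrics.efficiency` implements the six percentage formulas
with their fixed numerator/denominator pairings; reporting rounds
half-up to integer percent (99/187 → 52.94% → 53%) while full precision
is retained. `cumulative_detection_success` is the product of
sequential per-stage rates (two 90% stages → 81%).

`detection_eval` uses the PASCAL-VOC-style conventions: greedy
matching in descending confidence, a prediction claiming the best-IoU
unmatched ground-truth box on its image at IoU ≥ 0.5; recall is
TP/(TP+FN) (the standard definition); AP is the 11-point *interpolated*
average (max precision at recall ≥ r), since the raw 11-point formula
is ambiguous about interpolation. Confidence ties break by input
order, IoU ties by lowest ground-truth index, for determinism. An
exact-rational rank-enumeration oracle in the tests confirms the
floating-point implementation to 1e-12 on random small instances.

## Problem sizes and what the tests show

The acceptance-level checks run a simulated experiment of 2,400
injections (≈250 transgenic lineages, 10 progeny each at ~1,000× depth
and 0.5% error: parameter recovery of the mean insertions per embryo to
within 15%) and an exhaustive-sampling run of 600 injections with 150
progeny per lineage at zero error (per-lineage counts exactly equal to
truth). These sizes give comfortable statistical margins while keeping
the whole suite around half a minute on one core.

Passing tests show the pipeline correctly recovers what this generative
model produces. Real data differ in ways the model omits: non-uniform
barcode abundance in the injected pool, PCR and index-hopping
artifacts, indel sequencing errors (the trimmer is substitution-only),
cross-well contamination, and per-embryo variation in injection
quality. The strict consensus rule is designed to fail toward "mixed"
under most such violations rather than miscall, but no simulation-based
test can certify behaviour under error modes the simulator does not
model.

## Known limitations

* The saturation estimator assumes equal transmission of all
  insertions within a lineage; transmission bias would bias K̂ downward.
* `estimate_true_integrations` is a moment estimator; no confidence
  interval is provided.
* The trimmer tolerates substitutions only; reads with indels in the
  primer core are rejected (they fall out of the trimmed set rather
  than corrupting calls).
* Detection evaluation covers evaluation arithmetic only; it does not
  train or run any detector.
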