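# tagem

Analysis toolkit for **barcode-based germline transgenesis experiments**
in *Drosophila melanogaster*: multiplexed injections of a pooled plasmid
library in which every plasmid carries a unique 14 bp DNA barcode
(a TaG-EM barcode), so that each independent germline integration event
can later be identified by amplicon sequencing of F1 progeny.

It is written for labs running (robotic or manual) pooled-injection
transgenesis who need to turn demultiplexed per-fly FASTQ files into
the experiment's headline numbers — how many distinct integration
events each injected embryo produced, how many unique transgenic lines
the experiment yielded, and whether the plate-level controls behaved —
plus the surrounding bookkeeping: injection-efficiency metrics and
bounding-box detection evaluation for the machine-vision stages of an
injection robot.

## The model and the statistics

During early embryogenesis ~12–18 pole cells found the germline, and
each is an independent target for transgene integration. Injecting a
pool of *L* ≫ 1 uniquely barcoded plasmids makes integration events
countable: the number of **distinct barcodes** among a G0 fly's F1
progeny is the number of independent germline integrations in that
embryo.

* **Consensus barcode calling.** For each sample, reads are trimmed by
  locating the forward-primer core at the four frameshift-pad offsets
  (0/2/4/6 bases, Hamming matching, ≤2 mismatches) and taking the 14
  bases 3′ of it. Samples with < 500 trimmed reads are excluded.
  Otherwise the per-position base composition is tallied and the sample
  is *called* with the modal sequence only if at **every** position the
  modal base fraction **strictly exceeds 80 %**; otherwise it is
  *mixed* (a multi-template well or a blank).
* **Lineage counting.** Per lineage, the unique insertions *U* =
  |{distinct called barcodes among its progeny}|; globally, barcodes are
  deduplicated across lineages. The mean is taken over
  transgenic-producing lineages.
* **Saturation correction.** Sampling *n* progeny with replacement from
  *K* equally transmitted insertions observes
  E[U] = K·(1 − (1 − 1/K)ⁿ) distinct barcodes; inverting this monotone
  relation gives the estimate K̂ ≥ U of the true integration count
  (K̂ → ∞ when U = n).
* **Rarefaction.** Library diversity is gauged by the mean number of
  distinct barcodes in repeated subsamples (without replacement) of the
  sequenced pool at increasing depths.
* **Efficiency metrics.** Percentages such as integration efficiency =
  100 · (# transgenic-producing vials) / (# fertile crosses).
* **Detection evaluation.** IoU = |A∩B| / |A∪B| between axis-aligned
  boxes; greedy confidence-ordered matching at IoU ≥ 0.5; 11-point
  interpolated average precision AP = (1/11) Σᵣ max\_{recall ≥ r} P.

A fully-tested simulator (`tagem.synthetic_data`) generates the barcode
library, the germline biology (survival, sex, fertility, pole-cell
integration), the amplicon reads with the construct's real primer
scheme, and detection fixtures, so the entire pipeline is testable with
no external data.

## Worked example

```python
from tagem import GermlineSimConfig, generate_library, efficiency, round_half_up, ExperimentCounts
from tagem.pipeline import run_simulated_experiment

library = generate_library(20000, length=14, seed=1)
config = GermlineSimConfig(library=library, n_embryos=300, seed=1)
truth, calls, table, summary = run_simulated_experiment(config)

print(f"transgenic-producing lineages: {summary.n_transgenic_lineages}")
print(f"total unique insertions:       {summary.total_unique_insertions}")
print(f"mean insertions per embryo:    {summary.mean_insertions_per_embryo:.2f} (observed)")
print(f"                               {summary.estimated_mean_insertions:.2f} (saturation-corrected)")
print(f"histogram of unique counts:    {summary.histogram}")
cr = summary.control_report
print(f"blanks called:                 {cr.n_blanks_called}/{cr.n_blanks}")

counts = ExperimentCounts(n_injected=1713, n_fertile_crosses=187, n_transgenic_vials=99)
pct = efficiency("integration", counts)
print(f"integration efficiency:        {pct:.2f}% -> {round_half_up(pct)}%")
```

prints

```
transgenic-producing lineages: 38
total unique insertions:       130
mean insertions per embryo:    3.45 (observed)
                               4.36 (saturation-corrected)
histogram of unique counts:    {1: 1, 2: 12, 3: 7, 4: 9, 5: 7, 6: 1, 8: 1}
blanks called:                 0/16
integration efficiency:        52.94% -> 53%
```

300 simulated injections yielded 38 scoreable (surviving, fertile,
male, transgenic-producing) lineages carrying 130 distinct insertions
between them. The observed mean of 3.45 distinct barcodes per embryo
under-counts the truth because only 10 progeny are sequenced per
lineage; the saturation correction raises it to 4.36, bracketing the
simulation's configured conditional mean of 3.9. All 16 blank wells
were correctly non-called, and 99 transgenic-producing out of 187
fertile crosses is the 53 % integration efficiency.

The same steps are available from the shell via the `tagem` command
(`simulate-experiment`, `call-barcodes`, `lineage-report`,
`rarefaction`, `metrics`, `gen-detections`, `eval-detections`); run
`tagem --help` for details.

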