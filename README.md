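# satmut

Analysis pipeline for saturation-mutagenesis massively parallel reporter assays
(MPRAs): from tagged mutant libraries and RNA/DNA barcode sequencing to
per-variant expression effects, region-level statistics, motif/k-mer scoring and
benchmarking of annotation scores. A synthetic-data generator with planted
ground truth makes every stage runnable and testable with no external data.

## Pipeline

1. **synthetic_data** — simulate a target element (promoter/enhancer), an
   error-prone-PCR-like tagged library (transition-biased spectrum, rare
   indels), and per-replicate RNA/DNA tag×UMI reads generated from
   `log2(RNA) = log2(DNA) + Σ effects + noise`, with effects planted in
   TFBS-like footprints.
2. **assignment** — learn the tag→variant map from insert reads: affine-gap
   global alignment to the reference element, per-position majority-vote
   consensus, minimum coverage of 3 reads along the whole target, and
   disqualification of tags with insertions or multi-bp deletions.
3. **counting** — filter tag/UMI reads (N bases, off-design lengths, pair
   disagreement), count each tag×UMI pair once, keep only assigned tags, and
   intersect RNA/DNA within each replicate.
4. **effect_model** — multiple linear regression of `log2(RNA)` on
   per-replicate `log2(DNA)` columns, an intercept, and one binary indicator
   per variant, combined across the three transfection replicates; coefficients
   of the indicators are per-variant log2 effects with OLS standard errors,
   p-values and 95% CIs. A minimum of ten tag observations gates downstream
   reporting; condition comparison flags variants with disjoint CIs.
5. **region_stats** — replicate reproducibility (correlation of effect/SE),
   run-length permutation test for positional clustering of significant
   variants (vs 1000 label shuffles, rank-sum with continuity correction),
   and class contrasts (rank-sum + Hodges–Lehmann shift, exact binomial).
6. **annotation_scoring** — deltaSVM scores from k-mer weight tables
   (mean ref-kmer weight − mean alt-kmer weight, missing k-mers = 0), PWM
   scanning with length-normalized scores, pooled percentile thresholds,
   per-position motif counts, PWM score deltas with the 80th-percentile gate,
   and most-frequent-factor selection.
7. **evaluation** — Pearson/Spearman correlation of scores with (absolute or
   signed) effects, and top-N classification with per-element-matched
   resampled near-zero negatives (AUROC/AUPRC over 100 resamples).

## CLI

A single entry point with one subcommand per stage:

```sh
satmut simulate --config cfg.yaml --seed 1 --out-dir sim/
satmut assign   --reference sim/element.fa --reads reads.fq --min-coverage 3 --out a.tsv
satmut count    --assignment a.tsv --rna rna_r1.fq --rna-umi rna_umi.fq \
                --dna dna_r1.fq --dna-umi dna_umi.fq --replicate 1 \
                --tag-length 15 --umi-length 10 --out counts.tsv
satmut fit      --counts counts.tsv --assignment a.tsv --min-tags 10 \
                --mode combined --out effects.tsv
satmut stats    --effects effects.tsv --alpha 1e-5 --shuffles 1000 --seed 7 --out stats.json
satmut score deltasvm --weights w.tsv --effects effects.tsv --reference element.fa --out d.tsv
satmut score motifs   --pfm motifs.jaspar --reference element.fa --out matches.bed
satmut evaluate --effects effects.tsv --scores d.tsv --top-n 200 --resamples 100 \
                --seed 11 --out eval.json
satmut run      --config cfg.yaml --seed 1 --out-dir run/   # end-to-end synthetic
```

All randomness flows from explicit `--seed` options; seeded runs are
bit-reproducible.

## File formats

- **assignment TSV**: `tag`, comma-separated `pos:ref>alt` variant tokens
  (0-based; `-` alt = 1-bp deletion), `n_reads`, disqualification reason or `.`.
- **count TSV**: `replicate`, `tag`, `dna_count`, `rna_count` (distinct UMIs).
- **effects TSV / VCF-like**: 1-based positions; effect, SE, p-value, 95% CI,
  tag support. **BED** output is 0-based half-open.
- **k-mer weights**: `kmer<TAB>weight`; **PFMs**: JASPAR text format.
- Gzip input is handled transparently.

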