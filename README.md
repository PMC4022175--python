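# cnaprep

Copy-number preprocessing for tumour high-throughput-sequencing data:

- **summarize** — windowed read counting from SAM with flag-based
  classification of paired-end reads (proper / improper / discarded) and
  per-window mean mapping quality; annotation with GC content,
  mappability and common-CNV overlap.
- **filters** — five independent window filters: improper-read
  proportion (PEM), mean mapping quality, GC-aware automatic trimming
  driven by a Wald–Wolfowitz runs test that distinguishes scattered
  outliers from adjacent copy-number blocks, common-CNV overlap and
  mappability; combined mask plus a Venn-cell overlap report.
- **normalize** — single-pass local-regression GC correction and a
  two-pass, segment-wise correction that stays unbiased when GC content
  and copy number are correlated (segment, screen, center by segment
  median, refit per segment, combine by aligned pointwise median);
  matched-normal normalization (ratio or two-pass with the normal as
  covariate); a robust signal-to-noise metric.
- **segment_call** — exact penalized least-squares changepoint
  segmentation (PELT) and threshold-based integer copy-number calling
  with an optional data-driven threshold suggestion.
- **synthetic** — simulator for read-count profiles with known truth
  (piecewise-constant copy number, smooth GC effect, tunable
  GC–copy-number Spearman correlation, negative-binomial noise, planted
  outliers) and toy SAM generation.
- **plots** — GC-effect density map with fitted curves and a genome-wide
  profile view with segment means and call thresholds (optional
  matplotlib).
- **pipeline / CLI** — step planning from the input inventory, flat
  config files, deterministic end-to-end runs with worker-count-invariant
  outputs.

## Test

```
python -m pytest tests/
```

`tests/test_acceptance.py` holds the release criteria (several minutes);
the rest of the suite runs in well under a minute.

## CLI

```
cnaprep summarize --sam tumor.sam --window-size 200000 --out tumor.tsv \
    --annot annot.tsv --cnv common_cnvs.bed
cnaprep filter --profile tumor.tsv --pem-max 0.5 --mapq-min 30 --trim \
    --out filtered.tsv --report filter_report.json
cnaprep normalize --profile filtered.tsv --method seqnorm \
    --out normalized.tsv --curve-out gc_curve.tsv
cnaprep segment --profile normalized.tsv --out tumor.seg
cnaprep call --seg tumor.seg --thresholds 0.25,0.75,1.25,1.75 --out calls.seg
cnaprep simulate profile --seed 1 --out sim
cnaprep run --config pipeline.cfg
```

Annotation tables are tab-delimited `chrom start end gc mappability`
(1-based inclusive); CNV regions are standard BED. BAM input is not
decoded — convert externally (`samtools view -h`).

Suggested starting thresholds for the PEM and mapping-quality filters are
0.5 and 30; they are never applied silently.

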