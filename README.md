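# tivscan

Detection of signal-induced **transcript isoform variation (TIV)** from
exon-level probe-set signal time courses, plus quantification of
scratch-assay (wound-healing) screens.

The pipeline takes gene models, a probe-set annotation table, and a
normalized log2 signal matrix with per-sample detection p-values over a
replicated stimulation time course, and produces:

1. **QC / exon refinement** — probe sets are labeled against the gene model
   (constitutive intron / putative exon / ambiguous), filtered by
   detection ("present") calls, and putative exons are kept only if their
   signal exceeds the empirical constitutive-intron background
   distribution (default 95th percentile) in all replicates of at least
   one time point.
2. **Noise model** — replicate SD is estimated per (probe set, time point),
   binned by mean intensity, summarized by a bias-corrected median and
   constrained to be monotone non-increasing in intensity (isotonic
   regression).
3. **Fold changes & DE calls** — log2 fold change per probe set vs the
   pre-stimulus time point; gene-level fold change is the median over the
   gene's true-exonic probe sets (>= 3 contributing probe sets). Genes are
   differentially expressed if BH-FDR q < 5% AND |linear FC| >= 1.5 at
   >= 1 time point.
4. **TIV events** — per probe set and time point, the deviation from the
   gene-level fold change is tested (z from the propagated noise model,
   BH-FDR pooled over all tests); events are runs of >= 2 adjacent
   significant time points with a consistent sign; runs of >= 3 are
   flagged "switch-like". Events are classified
   (alternative first/last exon, cassette exon, alternative 5'/3' splice
   site, intron retention) by majority vote over the deviating probe
   sets' region classes derived from the gene model.
5. **Scratch assay & screen** — image tiles are merged, the cell-free gap
   is segmented (crop 15%, Gaussian smooth, Otsu, morphological closing,
   per-row longest central background run), the average migration
   distance (AMD) is derived from gap widths relative to t = 0, and
   per-oligo screen statistics (relative AMD vs negative controls, Welch
   t, BH-FDR) feed an isoform-specific hit rule.

A fully deterministic synthetic-data generator (`tivscan.synthetic`)
emulates every input — gene models engineered per event class, signal
time courses with injected DE/TIV and intensity-dependent noise, scratch
image series with known closure speed, and screen plates with known oligo
effects — and emits the matching ground truth for validation.

## CLI

```bash
tivscan simulate arrays  --seed 1 --out sim/            # synthetic inputs + truth
tivscan qc     --signals sim/signals.tsv --detp sim/detp.tsv \
               --samples sim/samples.tsv --models sim/gene_models.json \
               --annot sim/probesets.tsv
tivscan noise  --signals sim/signals.tsv --detp sim/detp.tsv --samples sim/samples.tsv
tivscan detect --signals sim/signals.tsv --detp sim/detp.tsv \
               --samples sim/samples.tsv --models sim/gene_models.json \
               --annot sim/probesets.tsv --alpha 0.05 --fc-min 1.5 --min-adjacent 2
tivscan simulate scratch --seed 1 --out tiles/
tivscan scratch --tiles-dir tiles/ --out traces.tsv
tivscan simulate screen --seed 1 --out screen/
tivscan screen --amd screen/well_amd.tsv --platemap screen/platemap.csv
```

File formats: gene models as simplified JSON or GTF; probe-set annotation
TSV (`ps_id, gene_id, chrom, start, end, strand, tier`); signal/detection
matrices as TSV (rows = probe sets, columns = samples); sample sheet TSV
(`sample_id, time_minutes, replicate`); tiles as TIFF/PNG named
`<well>_<row>_<col>_<time>`; plate map CSV. Coordinates are 0-based,
half-open.

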