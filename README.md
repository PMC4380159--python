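# spikemix

Spike-in linearity benchmarking of RNA-seq library-preparation protocols.

## The problem

Low-input and "single-cell" RNA-seq protocols pre-amplify cDNA before
library construction. If that amplification distorts genes unevenly, a
doubling of a transcript's concentration may no longer double its measured
abundance — and any analysis that interprets fold-changes quantitatively
(spatial expression patterns, dose-response curves, mixture deconvolution)
inherits the distortion. `spikemix` implements the analysis used to ask:
*how linearly does a protocol report known concentration changes, and how
far is it from an ideal protocol limited only by counting noise?*

The experimental design it analyzes mixes total RNA from two species — a
"spike" species (e.g. *D. virilis*) into a background species (e.g.
*D. melanogaster*) — at known fractions Q_j (0, 1, 5, 10, 20%). Every
spike-species gene is then a spike-in whose true relative concentration
across libraries is known, and together they cover the full ~10^5-fold
dynamic range of real transcript abundances.

## The model

With A_ij the read count of gene *i* in library *j* (after subsampling all
libraries to equal depth), each gene is rescaled onto the Q axis by the
weighted no-intercept normalization

    Â_ij = A_ij ÷ ( Σ_j Q_j A_ij / Σ_j Q_j² )

so that a perfectly linear gene satisfies Â_ij = Q_j regardless of its
absolute expression. Spike genes with ≥ 20 fragments in the highest-Q
library are kept, and for each a linear fit Â_ij = m_i·Q_j + b_i and the
Pearson correlation r_i are computed. Per protocol the analysis reports
the distributions of m, b and r (ideal: m = 1, b = 0, r = 1), one-sample
t-tests of m̄ against 1 and b̄ against 0, Welch t-tests between protocols
on r, and the interquartile range of the slopes.

Two reference analyses complete the picture:

* **Multinomial null.** An ideal protocol's only noise source is read
  sampling. From a reference library's per-gene probabilities, libraries
  at lower spike fractions are built by scaling spike-gene probabilities
  down and spreading the freed mass evenly over background genes; one
  multinomial draw per level replays the experiment with counting noise
  only. Replicated ensembles give null distributions of mean r and slope
  IQR, and the observed protocol is ranked within them.
* **Intrinsic/extrinsic noise.** Two runs of the experiment give paired
  slopes (m1_i, m2_i) per gene. η_int = std(m1 − m2) measures variation
  independent between runs; η_ext = std(m1 + m2) measures shared
  variation. Runs reusing one pre-amplified cDNA batch should show lower
  η_int than runs with separate pre-amplifications.

A synthetic-data generator (log-uniform expression over a configurable
dynamic range, multinomial sampling, optional per-batch amplification
bias, optional overdispersion) stands in for sequencing data, so the whole
pipeline is testable end to end.

## Worked example

Generate a four-protocol comparison (one low-bias deep protocol, three
low-input protocols with increasing amplification bias, all measuring the
same 0/5/10/20% ladder), then run the full analysis:

```sh
python analysis/01_generate_data.py
python analysis/02_linearity.py
```

which prints (protocol summaries, after subsampling to the lowest common
depth of 2,500,000 reads):

```
          n_genes  mean_slope  sd_slope  mean_intercept  sd_intercept  mean_r    sd_r  iqr_slope
protocol
ct            867      0.9948    0.0948          0.0008        0.0142  0.9688  0.0466     0.1286
ss            867      0.9945    0.0901          0.0008        0.0135  0.9705  0.0409     0.1167
tots          856      0.9784    0.1248          0.0032        0.0187  0.9447  0.0777     0.1590
trus          872      1.0007    0.0424         -0.0001        0.0064  0.9934  0.0125     0.0420

trus shows the tightest linear response (mean r 0.993).
ct vs ss mean correlation: Welch t = -0.82, p = 0.414 (n = 867, 867)
```

Every protocol recovers mean slope ≈ 1 and mean intercept ≈ 0 — all are
*linear on average* — but the per-gene scatter (sd of slopes, mean r)
cleanly separates the low-bias protocol from the biased ones, and the two
equally-biased protocols are statistically indistinguishable on mean r.

`analysis/03_ideal_null.py` ranks the best protocol against 200
counting-noise-only replicates (its mean r sits inside the null
distribution; its slope IQR above it — the residual signature of its small
preparation bias), and `analysis/04_noise_decomposition.py` pairs runs
sharing a pre-amplification batch:

```
same_preamp (ss25 vs ss5):  eta_int = 0.044, eta_ext = 0.103, n = 877
different_preamp (ss vs ss25): eta_int = 0.078, eta_ext = 0.082, n = 866
```

— intrinsic noise is lower when the batch is shared, i.e. a reproducible
part of the slope variation is introduced at pre-amplification.

`analysis/05_yield_pooling.py` covers the bookkeeping side: femtomole
yields from concentration/size measurements and equimolar pooling volumes.

The same stages are available as subcommands of the `spikemix` CLI
(`generate`, `subsample`, `normalize`, `fit`, `summarize`, `simulate`,
`noise`, `yield`, `run`); `spikemix run --design design.csv --out report/`
executes the whole pipeline on any design table and htseq-count files.

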