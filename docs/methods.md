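# Methods

## Scope and units

All coordinates are 0-based half-open on the plus strand; a CpG is
anchored at the position of its C on the plus strand. Minus-strand
reads are reverse-complemented at ingest so every later stage works in
one frame. The atomic object is a read: its base sequence, the offsets
of its covered CpGs, and a binary methylation state per CpG.

## Generative model of the simulator

The simulator emulates the regime the method targets: a panel of
candidate regions, tissue cohorts, and urine samples that are mixtures
of a small tumor-read fraction in a noncancer background.

* **Reference.** `n_regions` regions (default 200) of `region_length`
  bp (240) on one synthetic chromosome, each carrying `cpgs_per_region`
  CpGs (12) placed near-evenly with jitter; the sequence contains `CG`
  exactly at the recorded offsets, so CpG bookkeeping is exact by
  construction. `n_informative` regions (20) differ between origins —
  by default tumor-hypomethylated with p_meth 0.1 vs 0.9 (a methylation
  difference of 0.8); the remaining regions sit at a background level of
  0.8 in both origins, matching the high baseline methylation of bulk
  genomic DNA.
* **Reads.** A read of `read_length` bp (100) starts uniformly inside a
  region. Its methylation propensity is μ ~ Beta(p·κ, (1−p)·κ) with p
  the origin's region mean and κ = `concordance_kappa` (15); covered
  CpGs are then independent Bernoulli(μ). This Beta-Bernoulli
  hierarchy is the simplest model with the empirically motivated
  property that methylation states are concordant within a fragment:
  smaller κ gives more bimodal per-read α at the same region mean. κ=15
  keeps background reads clearly methylated (P(α ≤ 0.2) ≈ 1–2%) while
  leaving visible read-level dispersion. Degenerate p ∈ {0, 1} is exact
  (μ = p). A uniform state-flip rate is available as a stand-in for
  bisulfite non-conversion noise (default 0). Per-region read counts
  are Poisson(depth_X × reads_per_region_per_X), with 2 reads per region
  per 1X-equivalent.
* **Cohorts.** Tissue samples are pure-origin at 10X-equivalent
  (a desk-scale stand-in for deep tissue sequencing); urine samples at
  20X-equivalent are two-origin mixtures: each read is tumor-derived
  with probability θ. The default cohort is 10 tumor + 10 normal
  tissues, 25 noncancer urines (θ = 0), and 5 case urines per θ in
  {0.02, 0.05, 0.1, 0.2, 0.3}. True θ and per-read origins are retained
  for parameter-recovery tests. A validation cohort is drawn over the
  *same* region panel under an independent seed.

What the simulator does **not** model: sequencing error, fragment-length
variation, strand asymmetries, background (off-panel) genome, CpG-island
structure, and any realistic composition of urine background DNA — the
two-origin mixture is an assumption, not a measured property. Passing
tests therefore demonstrate the correctness and statistical behavior of
the pipeline under its own model, not clinical performance on real
cohorts.

## Region statistics and DMR calling

Reads with fewer than `min_cpgs_per_read` = 3 CpGs are excluded (not
zero-filled) from α-based statistics; `mean_meth` weights every CpG call
equally over all reads. A (region, sample) cell with fewer than
`min_reads_per_region` = 5 qualifying reads is missing, and a missing
sample is dropped from that region's test only.

Differences are tested per region with a two-sided Wilcoxon rank-sum
test across per-sample statistics (exact p where scipy supports it; a
region where every value ties is assigned p = 1 directly, since the
tie-corrected normal approximation is undefined there). BH correction
runs across tested regions; a call requires q ≤ 0.05 **and**
|Δ| ≥ 0.2. The effect-size gate exists because with enough samples
arbitrarily small proportion shifts become significant; 0.2 is the
smallest difference we consider biologically interesting for a
proportion statistic on [0, 1]. Matched tissue pairs are treated as
independent groups so one unpaired code path serves tissue and urine
contrasts alike; this sacrifices a little power on paired designs
(documented limitation).

Cancer-specific calls must be called with the same direction in both
the tumor-vs-normal-tissue and tumor-vs-noncancer-urine contrasts; the
merged call conservatively keeps the smaller-magnitude Δ and the larger
q. Ranking for the marker panel is by |Δ| descending with ties broken
by q then coordinate; `top_n` defaults to 20, which keeps the selected
fraction of the 200-region panel comparable to selecting ~2000 markers
from a genome-scale universe. Sample clustering uses Ward linkage on
Euclidean distance (the conventional default when no linkage is
specified) over the top fraction of regions by |Δ|, with region-mean
imputation of missing cells.

## Read encoding and classifier

Encoding: L × 5, L = 66 bp (trim 3′, right-pad with zeros); channels
1–4 one-hot A/C/G/T (N = all zeros), channel 5 is +1 at the C of a
methylated CpG, −1 at an unmethylated one, 0 elsewhere. CpGs whose G
falls outside the window are dropped so the channel is always consistent
with the visible sequence.

The classifier is a compact 1-D convolutional network written directly
in numpy with analytic gradients and Adam: conv (32 filters, width 8)
→ ReLU → max-pool (2) → flatten → dense (16, ReLU) → sigmoid. The
contract is sequence-local feature extraction followed by
position-aware aggregation into a probabilistic output; the flatten +
dense aggregation keeps positional information through
position-specific weights while keeping the implementation small,
dependency-free and exactly reproducible. Gradients are verified
against finite differences in the test suite. Training uses binary
cross-entropy, batch 64, learning rate 1e-3, 12 epochs, a 20% read-level
held-out split, and majority-class downsampling for balance; one seed
fixes initialization, the split, shuffling and balancing, so training is
bit-reproducible single-threaded (the only caveat would be
multi-threaded BLAS reductions, which these small matrices do not
trigger in practice).

Positive training reads are restricted to the aberrant-α side of their
marker region (hypo regions: α ≤ α_lo) because even tumor tissue is a
mixture — only the aberrant subpopulation carries the tumor pattern.
Model artifacts store the hyperparameters and a checksum of the marker
region set, so scoring against the wrong panel fails loudly.

## Sample score and evaluation

S = #{d > τ}/n with τ = 0.5; a mean-probability variant (S = mean d) is
available behind a flag, the thresholded fraction being the default as
the most literal "ratio of tumor-called reads". S is missing below
`min_reads_for_score` = 20 scored reads — beneath that the binomial
noise on S swamps the θ range of interest. ROC analysis uses the
trapezoidal AUC (equal to the tie-corrected Mann–Whitney statistic);
the Youden cutoff is the *lowest* threshold attaining max(sens + spec
− 1), which maximizes sensitivity among ties, and validation cohorts are
always evaluated at the cutoff frozen from the training cohort — the
only leakage-free protocol. Downsampling robustness subsamples each
sample's per-read score vector without replacement (equivalent to
subsampling reads, since S depends on a read only through d) and reports
pairwise-complete Pearson correlations between depth fractions.

## Problem sizes and numerical choices

Default study conditions (chosen once as a realistic desk-scale analog
and used by the test suite and the acceptance script): 200 regions / 20
informative, 10 + 10 tissue samples at 10X, 25 + 25 urine samples at
20X over the θ grid above, marker panel of 20, ~6,500-read balanced
training set, 12 epochs. A full end-to-end run takes under two minutes
on one CPU. The downsampling analysis uses a dedicated 40-sample cohort
at 52X (≈ 20,800 reads per sample) so that 10% subsamples still carry
~2,000 scored reads. Ties in ranking break deterministically (q, then
coordinate); all randomness flows from one master seed through
per-stage SHA-256-derived seeds, so any stage can be rerun independently
and reproducibly.

## Known limitations

* The mixture model for urine background DNA is an assumption; real
  noncancer urine is heterogeneous in ways the simulator does not
  capture.
* Statistical thresholds (α_lo/α_hi, min-CpG and min-read gates, q and
  Δ gates, τ) are documented package defaults, each exposed in
  configuration; they are sensible for the simulated regime but should
  be re-examined on real data.
* Paired tissue designs are tested unpaired (power loss, no bias).
* The classifier is intentionally small; with a sequence motif present
  the sequence channel is learnable, but no claim is made that this
  architecture is optimal for genome-scale panels.
* mDMR calling from Bismark-style cytosine reports covers mean-level
  statistics only; read-level statistics require per-read input.
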