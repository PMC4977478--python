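# Methods

This note documents the models, parameter choices and limitations behind
`enhancernet`: what is computed, under which assumptions, and what the
synthetic benchmarks do and do not demonstrate.

## Signal representation

ChIP-seq reads for each histone mark are assigned to fixed-width genomic
bins (default 100 bp; each read increments the bin containing its 5′-most
coordinate, midpoint assignment is available) and converted to RPKM:

    rpkm = count / (bin_width / 1000) / (total_mapped / 10^6)

which for 100 bp bins is `count × 10^7 / total_mapped`. Replicates are
RPKM-normalized independently and averaged element-wise. An optional
input-control correction subtracts a control track's RPKM per bin, floored
at zero; it is off by default because the right operation (ratio vs
subtraction vs library matching) is context-dependent.

A candidate locus at bin *c* is described, per mark, by the window of bins
`[c − 10, c + 10)` — spatial offsets −10..+9, spanning −1 kb..+1 kb. A 2 kb
window covers an even number of 100 bp bins, so it cannot be symmetric
around one center bin; the chosen convention is recorded per column in
`FeatureMatrix.column_map` and is therefore auditable everywhere
downstream. Windows running off a chromosome end are zero-padded and the
affected rows flagged. Feature vectors are mark-major: all offsets of mark
1, then mark 2, etc., giving `M × 20` features (480/220/180 for panels of
24/11/9 marks).

Coordinates are 0-based half-open (BED). All distances between functional
elements are summit-to-summit; summits default to interval midpoints, with
a configurable BED column for explicit summit offsets. Distances across
chromosomes are infinite, so proximity rules never match across
chromosomes. Strand is ignored.

## Training and test sets

Positives: p300 co-activator peaks that overlap a DHS (any-bp overlap;
summit containment available) and lie strictly more than 1 kb from every
TSS summit. Negatives: TSS that overlap a DHS, plus random 100 bp bins
whose centers are more than 1 kb from every DHS and TSS summit, drawn
uniformly over the genome with rejection (an error reports the achieved
count if the eligible space is exhausted after 1000× oversampling). The
positive:negative ratio is 1:10 by default and configurable; negatives are
subsampled with a seeded draw that preserves the TSS:background proportion
of the pool by largest-remainder allocation. Test sets use all distal,
DHS-overlapping p300/CBP/TFBS peaks (deduplicated by summit bin) as
positives and TSS as negatives; classes absent for a cell type are simply
empty inputs.

## The classifier

A fully connected feedforward network maps the feature vector to one raw
score. Hidden units use softplus, `ln(1 + e^x)` (computed as
`logaddexp(0, x)`); the output unit is softplus by default and may be set
linear. Training minimizes mean squared error between the raw score and
the 1/0 label by shuffled mini-batch SGD (batch 100), with inverted-scaling
dropout (rate 0.5) applied to hidden layers only — fresh Bernoulli masks
per batch, survivors scaled by 1/(1−p), nothing at prediction time.
Default architecture: hidden layers 600-500-400; 5 epochs. Remaining open
choices are fixed as: fan-in-scaled uniform initialization U(±√(3/fan-in)),
zero hidden biases, learning rate 0.01, no momentum, all exposed in
`TrainConfig`.

Two engineering details stabilize this loss:

* the output bias is initialized so the initial score equals the label base
  rate (softplus-inverse of ȳ). Without it, the first updates can drive
  the softplus output unit far negative, its gradient (a sigmoid) vanishes,
  and the network is dead on arrival;
* `train_best` trains several independently seeded restarts and keeps the
  lowest final *training* MSE. A collapsed run is unambiguous in training
  error alone (it sits at the label variance), so no evaluation data is
  involved in the selection.

Classification applies a strict `score > threshold` rule; ties are
non-enhancer. The scikit-learn wrapper `EnhancerMLP` adds optional feature
standardization (z-scoring with train-set moments, default on): RPKM scales
vary enormously with library size, and standardization makes SGD behave
identically across scales (the wrapper is exactly scale-invariant under
per-column affine rescaling of inputs).

## Evaluation

True-positive markers (TPMs) are DHS, p300, CBP and TFBS summits more than
1 kb from every TSS summit. A prediction is validated iff a TPM summit lies
within 2.5 kb (inclusive) on the same chromosome; everything else —
including "unknown" sites with real signal but no DHS — counts as an
error. The validation rate is validated/predicted; with zero predictions
it is reported as undefined (`None`/NaN), never 0 or 1. Threshold sweeps
report (threshold, n_predictions, rate) over strictly descending
thresholds; matched-count comparisons pick the threshold yielding a target
prediction count so different models are compared at the same operating
point.

The class-distribution overlap statistic is histogram intersection:
both samples are binned on a shared equal-width grid over the pooled range
(100 bins by default, configurable and reported), and the overlap is
Σ_b min(p_a(b), p_b(b)). It is 1 for identical samples, 0 for disjoint
supports, and ≈0.5 for unit-width uniforms shifted by half their width.
`neighborhood_average_overlap` applies the same statistic to per-site
window means.

## Synthetic epigenome

The generator plants sites uniformly at random with a minimum spacing
(rejection-free spacing construction; an error if the genome is too small),
then draws per-bin read counts per mark from
Poisson(background + Σ_sites amp·exp(−d²/2σ²)) and materializes reads as
bin-width intervals. DHS peaks are co-placed at enhancer-class sites *and*
at TSS — promoters are open chromatin, and without promoter DHS the
"TSS overlapping DHS" negative-selection rule would be vacuous. Everything
derives from one seed.

The frozen benchmark conditions (`enhancernet.benchmark`) are a 5 Mb
two-chromosome genome with 300 enhancers (p300), 250 TSS and 600 distal
unknown sites at ≥3 kb spacing (unknown sites therefore never sit inside a
TPM's 2.5 kb radius), background 1 read/bin, 12 marks of which 4 are
informative:

| mark | enhancer (amp, σ) | TSS (amp, σ) | unknown (amp, σ) |
|------|------------------|--------------|------------------|
| H3K4me1 | 3.0, 400 bp | 1.0, 250 bp | 4.8, 100 bp |
| H3K27ac | 2.5, 300 bp | 2.5, 200 bp | 3.0, 100 bp |
| H3K4me2 | 2.0, 300 bp | 3.0, 200 bp | 2.4, 100 bp |
| H3K9ac  | 1.5, 300 bp | 2.5, 200 bp | 1.8, 100 bp |

The design encodes class identity the way real chromatin does:
combinatorially and spatially, not in any single bin. H3K4me1 is
enhancer-specific and broad; the acetylation/H3K4me2 profiles are shared
with promoters but narrower and promoter-leaning there; unknown sites are
sharp spikes carrying ~40% of an enhancer's window mass, so neither a
peak-bin value nor a few-bin sum separates them. Two heterogeneity terms —
per-(site, mark) Gamma amplitude scaling (CV 0.75) and N(0, 300 bp) jitter
of each bump's center — emulate variable signatures and nucleosome
positioning. These are what make the benchmark informative about feature
reduction: with homogeneous, unimodal, fixed-position bumps a handful of
bins carries all the information and the top-k degradation the method is
designed to expose simply does not exist. The remaining 8 marks are flat
Poisson background, so "class-independent noise" is literal.

Desk-scale training config for the benchmark: hidden layers 96-64-48
(scaled to 240 features), learning rate 0.1, 120 epochs — chosen so the
training MSE converges at ~3,300 training rows; the genome-scale defaults
(600-500-400, 5 epochs) retain far more SGD updates per epoch. Best-of-3
restarts as above.

Benchmark operating points: the headline validation rate is read at the
top 1% of genome bins (500 predictions of ~50,000 bins); the top-k sweep
compares models at a matched 1,000-prediction operating point, averaged
over three consecutive benchmark seeds with 3 restarts per reduced model
(single runs of the reduced models are restart-noisy, as importance
rankings are seed-sensitive). The no-signal control sets every amplitude
to zero and compares its matched-count rate against the TPM base rate — the
validation rate of *all* bins — which is ~0.28 under these conditions.

## Interpretability

Importance starts at 1 on the output neuron and propagates backward:
S_i = Σ_{j∈N_i} |w_ij|·S_j. Biases are excluded; scores are non-negative
by construction; flipping any weight's sign changes nothing; multiplying
one layer by c > 0 multiplies every input score by c (so rankings, which
are scale-invariant, are the meaningful output — absolute values are not
comparable across models). The per-feature score equals the sum over all
input→output paths of the product of absolute weights along the path,
which the test suite verifies against brute-force path enumeration to
1e-10 relative error. Per-mark importance is the plain sum of the mark's
20 feature scores. Rankings sort descending with ties broken by ascending
feature index; top-k reduction keeps the top-k columns in their original
order and retrains with the same hidden architecture as the full model.
Importance is computed from a single trained model by default; a multi-seed
mean helper exists because single-run rankings vary between restarts.

## What the benchmarks show — and what they do not

Passing the synthetic benchmarks shows the pipeline's machinery is correct
and its qualitative behavior matches the intended regime: informative
marks are recovered by weight analysis, validation rates are high when
signal is present and collapse to base rate when it is not, and reduced
models degrade once the feature budget falls below what the signal's
spatial and combinatorial structure requires. It does not show
genome-scale performance on real epigenomes: real ChIP-seq has correlated
background, batch effects between replicates, fragment-length artifacts,
mappability holes and far more heterogeneous site classes than the
generator's three; library sizes are ~100× larger; and real validation
uses hundreds of thousands of annotated markers. Numbers from the 5 Mb
benchmark are analogues of, not estimates of, genome-scale rates.

Other known limitations: squared-error training of a softplus output is
collapse-prone (mitigated, not eliminated, by bias initialization and
restart selection); the importance equation ignores biases and activation
saturation, so it is a connectivity measure rather than a sensitivity
measure; background bins for training are drawn by summit distance only,
so flanks of annotated sites are in neither class and their scores are
extrapolation; BAM input is out of scope (convert to BED first).
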