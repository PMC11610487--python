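# Methods

## Study design and data model

The package targets the standard free-running circadian RNA-seq design: one
pooled sample collected every 4 h for 48 h (12 samples, CT1–CT45) under
constant darkness (DD) and, independently, under constant light (LL), with
abundance reported in FPKM-like units. There are no biological replicates;
within-condition inference therefore leans entirely on the temporal
structure. `TimeDesign` enforces even spacing and that the sampling
interval divides the 24 h test period into an integer number k of phase
groups (k = 6 by default, two observations per group after folding the two
cycles). Transcripts with any missing value are excluded before analysis
(hard exclusion, no imputation); normalization is DESeq-style
median-of-ratios, estimated by default jointly across all 24 samples of
both conditions (a per-condition switch exists, since grouping conventions
differ between studies).

## Rhythm detection

**Umbrella rank test.** A rhythm folded at period T visits k phase groups;
an umbrella shape (peak group p, trough group t) induces a cyclic ordering
that rises from t to p and falls back. The statistic sums Mann–Whitney-type
concordances along both arms:

    S = Σ_{(u,v): u before v on the rising arm}  #{ y_i < y_j : i∈u, j∈v }
      + Σ_{(u,v): u before v on the falling arm} #{ y_i > y_j : i∈u, j∈v }

Pooling both arms lets unequal rise/fall lengths — sawtooth-like waveforms —
score as highly as symmetric ones. The reported p-value is the minimum
per-shape p times the number of shapes (k·(k−1) = 30; Bonferroni, the
conservative choice since shapes overlap), capped at 1; the reported phase
is the winning shape's peak-group center modulo 24 h.

*Exact null.* Under within-series exchangeability the null of S is obtained
without approximation. Conditioning on the rank *sets* of the trough group
T and peak group P, every cross term involving T or P is fixed:

    S = C(T, P) + JT_rising-interior + JT_falling-interior,
    C = 2·U(T,P) + u(T, rest) + u(rest, P),

and the two interior Jonckheere–Terpstra statistics are independent and
distribution-free given the split. The exact null is therefore
hist(C) ⊛ JT(r−1 groups) ⊛ JT(f−1 groups), where each JT null is Harding's
convolution of sequential Mann–Whitney nulls (Gaussian-binomial
coefficients). C's histogram is enumerated over the C(n,g)·C(n−g,g)
endpoint choices (2,970 for the default design) — milliseconds, cached per
design. The construction is verified in the test suite against full
enumeration (k = 3) and against ≥10⁵-permutation Monte Carlo (k = 6).

**Kendall-tau test.** Concordance of the series with cosine references of
the test period, one per candidate acrophase on the sampling grid (6
phases). With acrophases aligned to sampled times, the reference values tie
in blocks of sizes (2,4,4,2) over the 12 samples; the concordance count is
then exactly a JT statistic over the blocks, with the same convolution
null. Bonferroni over the 6 phases.

**Ties and degeneracies.** Tied values receive 0.5 concordance credit; the
convolution nulls assume tie-free data, so any series containing ties falls
back to a seeded 20,000-permutation Monte-Carlo null (the fallback seed is
fixed, so results are reproducible). Constant series are assigned p = 1 by
convention. Both tests are invariant under strictly monotone transforms.

**FDR.** Benjamini–Hochberg step-up, implemented directly
(q_(i) = min_{j≥i} m·p_(j)/j, capped at 1) and cross-checked against
statsmodels. Strict/broad rhythmic calls use q < 0.1 and q < 0.2; the
cross-method agreement statistic is the fraction of umbrella calls
(q < 0.1) that the tau test also calls at q < 0.6.

## Waveform characterization

Amplitude follows the median-normalization convention: fold =
max/min of the series divided by its median (undefined, and flagged, when
the median is not positive), and median-normalized amplitude =
(max−min)/2 ÷ median, both from the 12 sampled points without
interpolation — so a sampled fold slightly undershoots the continuous
peak/trough ratio. "Reliably quantified" means ≥ 5 abundance units at
every time point.

Period estimation fits the single-harmonic cosinor
y ~ β₀ + β₁cos(2πt/P) + β₂sin(2πt/P) by least squares at every period of
the 20–28 h grid in 0.2 h steps; amplitude = √(β₁²+β₂²), acrophase from
atan2, significance from the F-test of the harmonic pair against the
intercept-only model with (2, n−3) df. The best period minimizes RSS; RSS
ties (within 10⁻¹² relative tolerance) resolve toward 24 h, then toward
the smaller period. In the pipeline the fit runs on log abundances, since
the generative signal (and biology) is multiplicative. The DD-vs-LL period
comparison includes only transcripts passing the double rule — rhythmic at
q < 0.1 *and* cosinor-fit q < 0.1 in both conditions — and uses the
two-sided Wilcoxon rank-sum test (exact enumeration when both n ≤ 10, else
the tie-corrected normal approximation).

## Clustering

Profiles are z-scored per transcript (n−1 convention; constant transcripts
excluded and logged) so clusters capture shape. Fuzzy c-means with
Euclidean distance and fuzzifier m = 1.25 (crisp but soft enough to damp
noise) uses the classic updates u_ij ∝ d_ij^{−2/(m−1)} (membership 1 at a
coincident centroid) and centroids Σu^m x / Σu^m; centroids initialize from
c distinct profiles sampled under the run seed, with 3 restarts keeping the
best objective. The objective Σ u^m d² is recorded per iteration and is
non-increasing. c is fixed at 30 for study-replication mode; `select_c`
provides a diagnostic — the largest c before the minimum pairwise centroid
distance collapses below half its value at the smallest candidate
(redundant centroids signal more clusters than profile families). On
structureless data this collapse emerges once the transcript count is large
relative to c; with few transcripts the curve can drift upward instead, so
the diagnostic is advisory, not a gate. Hard clusters (argmax membership,
ties to the lowest index) are tested for rhythm enrichment with the
hypergeometric upper tail P(X ≥ k), BH-corrected over the c tests of a
condition.

## Enrichment

GO over-representation uses the hypergeometric upper tail with the analyzed
annotated gene set as the default population; terms with fewer than 2
population genes are skipped as noise-prone, terms with zero study hits are
not tested, and BH runs across tested terms. Annotations are used exactly
as supplied (no ancestor propagation). Term profiles across condition
columns (untested cells set to 1) are compared with distance
d(a,b) = Σ_cols |p_a − p_b| and clustered agglomeratively with complete
linkage (configurable); the leaf order is returned for presentation. The
cross-species test maps a foreign rhythmic gene list through a possibly
many-to-many ortholog table, deduplicates, restricts to the universe, and
scores the overlap with the native rhythmic set by the hypergeometric upper
tail.

## Differential expression

With one sample per time point, DE is a fold-change call on per-condition
medians over the 12 time points (robust to isolated aberrant time points):
fold = median_DD / median_LL, strata DDu (fold > 1.5), DDh (1 ≤ fold ≤ 1.5),
LLh, LLu symmetrically; zero-median features are flagged and excluded. The
procedure is exactly antisymmetric under swapping the conditions. When gene
ids are present, member transcripts are summed per gene first.

## Synthetic-data generator

Each transcript draws a log-normal baseline (meanlog 3.0, sdlog 1.5 —
median ≈ 20 abundance units, a realistically wide dynamic range).
A transcript is rhythmic with probability 0.06. Rhythmic transcripts get:

- a peak/trough fold from the mixture 0.8·U(1.3, 2] + 0.2·U(2, 4], so
  P(fold ≤ 2) = 0.8 by construction; the 1.3 floor (≈30% peak-to-trough
  modulation) is the smallest oscillation treated as biologically
  meaningful;
- a peak phase from an equal mixture of wrapped normals at CT2 and CT14
  (sd 1.5 h) — the bimodal subjective-morning/subjective-night pattern;
- condition periods 25.4 h (DD) and 24.0 h (LL): the defaults are the
  *transcriptional* free-running periods (25.4/24.0) rather than the
  behavioral ones (25.8/22.4), because the generator emulates transcript
  series and the transcript-level period medians are the quantity the
  period analysis measures; behavioral values can be set in the config;
- with probability 0.87 a cross-condition phase shift drawn from
  N(0, 1.5 h) clipped to ±4 h ("shared" phase), otherwise a clear
  displacement of 6–12 h — so the ±4 h phase-agreement fraction among
  rhythmic transcripts equals the configured 0.87 up to binomial error;
- with probability 0.15 a sawtooth waveform whose rise occupies 20–35% or
  65–80% of the cycle (steep rise or steep fall), otherwise a cosine.

The waveform is exponentiated — value = baseline · fold^(s(t)/2) with
s ∈ [−1, 1] — giving an exact peak/trough ratio and positivity.
Multiplicative log-normal noise with CV 0.15 (a free parameter of the
generator; there is no published per-transcript noise magnitude for this
design, and 0.15 is a plausible technical+pooling CV for deeply sequenced
pooled samples) is drawn independently per condition, time point and
transcript. DD and LL are independent experiments sharing the transcript's
biology (baseline, fold, waveform class). `planted_de` scales chosen
transcripts by a constant fold in one condition for DE benchmarking.

What the generator does *not* emulate: count-level (negative-binomial)
noise, library-size artifacts, batch or light-box effects, transcript
length biases, correlated noise across transcripts, and partial overlap of
the rhythmic sets between conditions (all rhythmic transcripts oscillate in
both conditions, only their phase alignment varies). Passing recovery tests
on this generator therefore demonstrates correctness of the statistical
machinery under the stated signal model, not robustness to every artifact
of real libraries.

## Statistical power at the default conditions

A deliberate property of the defaults, worth stating plainly: with 12
samples, mostly sub-2-fold amplitudes and noise CV 0.15, transcriptome-wide
detection at q < 0.1 has low sensitivity. The best attainable umbrella
p-value at n = 12 is ≈2.8×10⁻⁴ for a symmetric shape after the ×30 shape
correction, and at fold 2 the typical p is ~10⁻²–10⁻³, so the BH cascade
over 10,000 transcripts with ~6% true signal settles at a handful of
discoveries (measured sensitivity ~0.03–0.10 pooled across conditions,
with empirical FDR well below 0.1 and phase errors of detected transcripts
almost always ≤ 4 h). A parametric oracle given the true period reaches
only ~0.5 sensitivity under the same conditions, so this is an information
limit of the design at these amplitudes, not an implementation artifact;
the null-calibration and permutation-agreement benchmarks confirm the
p-values themselves are exact. Detection studies wanting high sensitivity
should raise amplitudes or lower noise in the generator config.

## Problem sizes and seeds

The shipped analyses use 10,000 transcripts for the main study, 10,000
series for null calibration, 50 series × 10⁵ permutations for the
exact-vs-Monte-Carlo cross-check, a 180-transcript all-rhythmic panel
(~85 surviving the double inclusion rule, matching the scale of the
original period comparison) for the period analysis, 200 profiles for the
clustering benchmark and 4,000 transcripts with 100 planted fold-2 genes
for DE recovery — sizes chosen to make each Monte-Carlo tolerance
meaningful on a single CPU. Every stochastic component draws from
`numpy.random.default_rng` seeded from the run seed; the tie-fallback
permutation seed is a fixed constant so batch composition cannot change
per-series results.
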