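# Methods

This note documents the models and numerical choices behind `oscillome`,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Fourier features

The forward transform is the unnormalized, negative-exponent DFT
(`numpy.fft` convention): `X_k = Σ_{n=0}^{N−1} x_n e^{−2πikn/N}`. For a
cosine `A·cos(2πk₀n/N + φ₀)` this gives `A_{k₀} = N·A/2` and
`φ_{k₀} = φ₀`; peak time within a cycle of period P is
`t_peak = (−φ_k mod 2π)·P/(2π)`. The component index `k_osc` equals the
number of phenotypic (dissolved-O₂) cycles spanned by the series — 4 for
the short-period and 3 for the long-period experiment layout the simulator
reproduces — so a series needs `N ≥ 2·k_osc + 2` samples and equal spacing
(checked to 1%).

**Scaled amplitude.** `S_k = A_k / mean{A_j : 1 ≤ j ≤ ⌈N/2⌉−1, j ≠ k}`
(DC and Nyquist excluded from the pool). Dividing by the mean amplitude of
the other components makes the statistic invariant to multiplicative
intensity scaling, which is what lets the pipeline operate on raw,
unnormalized intensities: array-to-array artifacts concentrate in other
frequency components and inflate the denominator rather than the score.
`S = ∞` (pure tone) is represented by a sentinel capped at 100 before
clustering; the cap preserves ordering and keeps EM finite.

**Permutation test.** The time order of the series is permuted uniformly
at random B times (default 1,000) and the add-one estimate
`p = (1 + #{S_perm ≥ S_obs})/(B+1)` is used, so `p ∈ [1/(B+1), 1]`. This
construction (uniform time-order permutations, add-one correction) is this
package's definition of the test. In the matrix routine one shared
permutation set is applied to all genes — valid under the per-gene null
and B full-matrix FFTs instead of genes×B. A consequence worth knowing:
per-array multiplicative artifacts are *shared* across genes, so when an
artifact vector happens to carry power at `k_osc`, non-oscillating genes
leak through the significance filter together (see Clustering below).

**Display normalization.** For plotting only, each array is divided by the
median mean-ratio of a "least-oscillating" reference set (bottom decile of
`S_{k_osc}` with permutation p ≥ 0.5, falling back to the decile alone if
the intersection is empty), and genes are shown as log2 mean-ratios. No
statistic is computed from normalized data.

**Component choice.** Features default to the phenotypic component only
(2-D: `S cos φ, S sin φ` at `k_osc`); the feature extractor accepts any
component list (e.g. `{k_osc, 2k_osc}` to add curvature of the waveform).
With a single planted harmonic, the second-harmonic dimensions carry only
noise and measurably dilute cluster recovery, hence the 2-D default.

## Clustering model

Features are transformed with the signed (Bickel–Doksum) Box-Cox
`f(x) = (sign(x)·|x|^λ − 1)/λ`, λ searched in [0.1, 2]. This is the
standard monotone, continuous extension of Box-Cox to signed data; it
reduces to `x − 1` at λ = 1 and is odd up to the additive constant −2/λ.
Small λ compresses the large dynamic range of scaled amplitudes, turning
the radially elongated "wedge" clusters of the polar feature plane into
compact blobs — empirically this is what makes phase cohorts separable,
and why λ is optimized rather than fixed.

The mixture is multivariate *t* with shared, fixed ν = 4 (heavy tails
de-emphasize the semiquantitative amplitude information; optional
estimation is deliberately omitted). EM uses the standard latent-scale
construction (`u = (ν+p)/(ν+δ)`); λ is updated inside EM by a bounded 1-D
profile search in which the component locations and scales are profiled in
closed form given the current responsibilities and latent scales — a
generalized EM step, so the observed-data log-likelihood (including the
Jacobian `(λ−1)Σ log|x|`) is non-decreasing, which the tests assert.
Convergence: relative log-likelihood change < 1e-5 (the reference
implementation's printed tolerance); singular scale matrices are
ridge-regularized with a warning. Initialization is a seed-controlled
random partition with best-of-R restarts (default R = 8–10): explicit
seeds replace the input-order dependence of sequential initializers.

**Model size.** `BIC = 2·loglik − d·log n` with
`d = (K−1) + Kp + Kp(p+1)/2 (+1 if λ is free)`; the argmax over a K range
is taken. In the synthetic pipeline the range extends one below and two
above the planted cohort count: background genes that leak through the
periodicity filter (shared array artifacts, see above) form a coherent
extra cluster, and giving BIC room to add a component for them prevents
two genuine cohorts from being merged.

**Phase sorting and consensus.** Per cluster, the circular phase density
(von Mises kernel, κ = 25 ≈ 11.5° SD, 1° grid) is maximized; a global
rotation puts the anchor cluster's peak just above 0° and clusters are
relabeled in increasing peak order. Two experiments' clusterings are
merged over their shared gene universe: each contingency cell gets a
cumulative hypergeometric p, and a declarative label map assigns consensus
names to significant cells (default threshold 1e-3), background classes to
the rest, and `r` to genes absent from either experiment. The shipped map
(`data/consensus_labels.yaml`) encodes the A/AB/B/B.C/C/B.D/D + fallback
scheme; `auto_label_map` derives a map from mutually-best significant
cells for synthetic runs. Codifying the map replaces the manual,
inspection-guided step of the original analysis with a declarative,
reproducible artifact.

## Enrichment statistics

Categorical: exact upper-tail hypergeometric `P(X ≥ k)` with enrichment
`E = (k/m)/(n/N)`; `E > 1 ⇔ k/m > n/N` exactly. Categories are flat
term→gene sets; ontology terms are *not* propagated to parents. Raw
p-values are reported (display cutoff default 1e-4); Benjamini–Hochberg is
an opt-in flag.

Numerical: two-sided Mann-Whitney-Wilcoxon with mid-rank ties; `U` counts
cluster-over-rest pairs (ties ½), `r = 2U/(mn) − 1`; exact p (shift
algorithm via scipy) when `m + n ≤ 50` without ties, tie-corrected normal
approximation otherwise; all-tied input returns r = 0, p = 1 by
convention. `u_frac = U/(mn)` is emitted alongside r because both scales
appear in published tables; r is the display default since its [−1, 1]
range matches a diverging palette. For approximately normal data (e.g.
nucleotide frequencies) Welch's *t* with Satterthwaite dof is used; the
sign of *t* gives the direction. A scale-relative tolerance
(1e-12·max|x|) guards the zero-variance degenerate cases.

Compendium meta-analysis: per (cohort, experiment), `r` of the cohort's
values vs. all other genes' values in that experiment, with pairwise
exclusion of missing values; experiments with < 2 distinct values are
null. Experiments are clustered SOTA-style: a binary tree of centroids
grown by splitting the cell with the largest mean within-cell distance,
children trained by sequential winner-take-most updates (winner learning
rate 0.1, sibling 0.01) until K cells exist; columns are ordered by the
decreasing mean of the anchor cohort's r within each experiment cluster.
Bit parity with the original SOTA implementation is out of scope.

## TSS-aligned tracks

Coordinates are 1-based genomic; TSS-relative columns use TSS = +1 with no
position 0, transcription towards increasing positions (minus-strand genes
flipped); promoter-relative coordinates use start-codon A = +1.

**SDP.** Bins tile the aligned range half-open; per bin each gene's values
are averaged into one observation (position autocorrelation within a gene
is never pseudo-replicated), and cluster genes are tested against all
others (rank-sum by default, Welch optional). Each row carries the bin
mean, the direction statistic, p, and a symbol-size class in [0, 1]
(1 at p ≤ 1e-5, 0 at p ≥ 0.05, log₁₀-interpolated — the source's cutoffs
are not printed, these are this package's defaults). Default bin widths:
10 bp for fine tracks, 32 bp for 32-bp-resolution tracks. Plotting is
deliberately left to the user; the tidy table is the canonical output.

**Sliding content.** Centered 71-nt windows; GC = {G, C}, purine = {A, G};
non-ACGT symbols count in the denominator, never the numerator; the
window/2 edge positions are missing. Sequence profiles are tested
per position without prior binning, at every 10th position by default,
with Welch's *t*.

**Consensus TSS.** Evidence sites (weight 1 unless supplied — the sources'
weighting is not defined, so unweighted is the default) are sorted by
position and greedily grouped: a site joins the open group while it lies
within 73 nt (≈ half a nucleosome) of the group's *running* weighted
center; the anchored-window alternative is unspecified in the source, and
running-center greedy is this package's definition. Each group's weighted
mean position is rounded toward the start codon; among candidates in
[−400, −1] the one closest to the start codon is the TSS. Output is
independent of input row order.

## Motif scanning

PWM scores are plain sums of the published per-position weights (no
log-odds re-derivation); a hit needs ≥ 80% of the maximum achievable
score (configurable). Windows containing non-ACGT symbols are skipped;
IUPAC motifs match degenerate sets exactly and never match sequence N.
Both strands are scanned by default (the source is silent on strandedness);
TATA ranges are conventionally scanned sense-only. Range conventions:
default 500 nt upstream of START or downstream of STOP; `TATA.350` =
[−350, −1]; `TATA.500` = [−500, −351]; suffix `.3p` = downstream of STOP.
Presence is binary per (gene, motif, range) and feeds the hypergeometric
layer. Experimental binding-site tables are ingested as precomputed
presence tables, not re-derived.

## Synthetic data

Oscillating genes follow
`base_g · (1 + a·cos(2π·k_osc·n/N + φ_cohort + jitter_g)) · scale_n + ε`,
background genes omit the cosine. Defaults: two experiments of 4×10 and
3×12 samples (periods 0.7 h and 5 h), seven cohorts of 10% each at phases
evenly spread over the cycle (~51° apart), 30% background, relative
amplitude 0.4, additive t₅ noise with SD 5% of the base intensity
(amplitude/noise ≈ 8), log-normal array scaling with SD 0.1, wrapped-normal
phase jitter SD 10°, base intensities log-uniform over
[100, 10,000] (two decades, microarray-like). These defaults are the study
conditions; the generator is deterministic given its seed.

The toy genome plants: a degenerate TATA motif in 50% of one cohort's
promoters vs 5% elsewhere; an occupancy dip of 1 SD over [−150, −50] for
one cohort; a category overlapping one cohort at a stated rate; compendium
blocks where one cohort is up and another down in half the experiments
(and flipped in a quarter), producing anti-correlated rank-sum profiles.

**What passing tests do and do not show.** The generator reproduces the
statistical *structure* the analysis assumes — phase-coherent cohorts,
heavy tails, multiplicative array artifacts, unnormalizable raw
intensities — but not probe-level microarray physics, intensity summarization,
cross-hybridization, period drift within an experiment, or the biological
coupling between cohort membership and promoter architecture. Recovery of
planted truth therefore validates the machinery, not the biological
conclusions drawn from real arrays; replication checks against the
published per-gene tables run only when those files are supplied
(`oscillome replicate`).

## Known limitations

- The mixture model omits the uniform outlier component some reference
  implementations carry; outliers are absorbed by the heavy tails instead.
- The exact permutation scheme and DFT component selection of the original
  analysis are not public in detail; this package's definitions (above)
  are used and flagged as such.
- Consensus definition in the original work involved visual inspection;
  the declarative label map reproduces its logic but not its judgment, so
  published cluster contents are a replication input, not a test oracle.
- Unevenly sampled series (Lomb-Scargle territory) and de novo motif
  discovery are out of scope.
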