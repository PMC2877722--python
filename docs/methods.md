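# Methods

## Model and statistics

All analysis is based on within-sample ranks. A network *m* with genes
`g_1..g_G` measured on a sample yields the binary pair-encoding
`b(i,j) = 1[x_i < x_j]` over the `P = G(G−1)/2` pairs `(i, j)`, `i < j`, in
lexicographic order over the network's sorted gene list (sorting makes
templates reproducible regardless of how the gene set file orders its
genes). Ties (`x_i = x_j`) encode as 0 — the indicator is a strict
"less-than" — and the same rule is used in template estimation and
scoring, so tied data cannot make the two disagree.

The rank template for phenotype *k* sets bit `(i,j)` to 1 iff the fraction
of phenotype-*k* training samples with `x_i < x_j` exceeds 0.5; a fraction
of exactly 0.5 gives 0. The rank matching score `R`, conservation index
`μ_R` (phenotype mean of `R`), difference score `Δ = R_A − R_B`, template
Hamming distance, and classification rate `η` (mean of sensitivity and
specificity of the `Δ > 0 → A` rule, with `Δ = 0 → B`) all follow from
the encodings. They are computed as exact integer agreement counts divided
once at the end, so no floating-point accumulation error enters; the
majority template provably maximises in-sample `μ_R` over all binary
vectors and guarantees `μ_R ≥ 0.5` (each bit agrees with at least half the
samples), properties the test suite checks exhaustively for `P ≤ 12`.

Because encodings depend only on within-sample orderings of the network's
own genes, every statistic is invariant to strictly increasing per-sample
transforms (hence to normalisation) and to all genes outside the network.

## Significance

Both permutation tests shuffle the phenotype labels while preserving class
sizes and re-estimate all templates within each permuted labelling:
`θ(m) = |μ_R(m,A) − μ_R(m,B)|` for deregulation (default B = 1,000
permutations) and `η(m)` for variable expression (default B = 10,000).
P-values use add-one smoothing, `p = (1 + #{null ≥ observed}) / (B + 1)`:
never zero, at most 1, and uniform on its support under exchangeability so
that with `B = 199`, `Pr(p ≤ 0.05)` is exactly 10/200 = 0.05 — the value
used by the calibration tests.

The engine is vectorised: with the `(N, P)` encoding matrix `E` and a
`(B, N)` class-membership matrix `Z`, permuted class pair-frequencies are
`Z·E` row-scaled, and agreement counts come from the identity
`Σ_p 1[e_p = t_p] = 2 e·t − Σe − Σt + P`, i.e. one more matrix product.
This makes exhaustive enumeration (all `C(N, n_A)` assignments) affordable
at small N, which the tests use as an exact oracle against the Monte-Carlo
p-values.

The FDR is the permutation plug-in estimator: at threshold `c`,
`[mean over permutations of #{null ≥ c}] / max(1, #{observed ≥ c})`,
capped at 1. It is made monotone non-increasing in the statistic q-value
style: each observed value receives the minimum raw estimate over all
thresholds at or below it (every such rejection region contains the
observation). The procedural alternative — propagating a cumulative
minimum downward from the largest statistic — would hand the top
statistic's (often zero) FDR to every weaker one and break monotonicity in
the required direction, so it was rejected.

The deregulation-count sign test treats each significantly deregulated
network (p < α, default 0.05) as a coin flip for which phenotype holds it
more tightly; exact `μ_R` ties are excluded. The default tail convention is
the *strict* upper tail `Pr(X > k_less)` with `X ~ Binomial(k_less +
k_more, 1/2)`, which reproduces published tables of this statistic exactly
(e.g. a 13/1 split gives `2^−14 = 6.10×10⁻⁵`, and 26/0 gives exactly 0);
the conventional inclusive tail `Pr(X ≥ k_less)` is available via a flag.
Global regulation is summarised by the per-phenotype mean of `μ_R` over
networks, compared by one-way ANOVA treating networks as independent
observations within each phenotype group — an approximation (networks
sharing genes are not independent) reported as such in the output header.

## Classification protocol

The DIRAC classifier selects the network with the largest apparent `η` on
training data. Ties break deterministically: larger template Hamming
distance (the more variably expressed network), then lexicographically
smaller name. Leave-one-out cross-validation repeats *all* training
decisions — template estimation, network selection, gene filtering, pair
search — inside each of the N splits; held-out predictions are pooled
first and sensitivity/specificity computed once over all N predictions,
which is the only aggregation that yields a single average of sensitivity
and specificity. The no-leakage property (overwriting the held-out
sample's values changes nothing about that split's model) is tested
directly.

Comparators are size-matched to the best DIRAC network's gene count `G`:
the TSP classifier searches all pairs of the top-`G` genes by two-sided
Wilcoxon rank-sum p-value (exact enumeration when both class sizes are
≤ 20, tie-corrected normal approximation otherwise; p-value ties break by
the larger deviation of the rank-sum statistic from its null mean, then by
name), scoring pairs by `|Pr(X_i<X_j|A) − Pr(X_i<X_j|B)|` with ties broken
by the larger between-class rank-difference margin, then the
lexicographically smaller pair. The SVM comparator is a Gaussian-kernel
SVM with default regularisation on the same filtered genes, standardised
with training-set statistics only; since its kernel width and
regularisation are not tuned, its results are qualitative.

## Synthetic data

The generator emulates a two-phenotype study under a Gaussian location
model: gene `g` has base mean `μ_g` (default equally spaced with unit gap
δ, largest first) plus iid `N(0, σ²)` noise. Every pair probability is
then closed-form, `Pr(X_i < X_j) = Φ((μ_j − μ_i)/(σ√2))`, giving the
analytic conservation expectation `E[μ_R] = mean over pairs of
max(p, 1−p)` that the parameter-recovery tests target (±0.02 at 500
training / 500 held-out samples). Discriminative networks are planted by
permuting phenotype B's base means with a permutation of exactly
`n_reversed_pairs` inversions (built from its Lehmer code), so at low
noise the two phenotype templates differ on exactly that many pairs; the
full `G(G−1)/2` inversions give complete template reversal.

Defaults describe the planted-signal condition used throughout the
acceptance properties: 20 networks of 10 genes, 3 discriminative, 30 + 30
samples, δ = 1, σ = δ/2, 20 of 45 pairs reversed. At these settings the
reversal is strong (adjacent-pair flip probability `Φ(−√2) ≈ 0.08`), so
the discriminative networks are cleanly recoverable while null networks
stay null — a regime chosen to separate correctness failures from
power failures.

What the generator does *not* emulate: probe-level and platform noise,
heavy-tailed or heteroscedastic marginals (though a log-normal option
exists precisely because rank statistics cannot distinguish it from the
Gaussian), and gene–gene correlation beyond the rank structure induced by
the fixed means. Passing tests therefore demonstrate the statistics,
inference machinery and protocols are correct under a known rank model —
not that any particular biological dataset will show tight conservation.

## Numerical and interface choices

- Probe→gene collapsing on input defaults to `max_mean` (keep the
  brightest probe), with `mean` and `first` available; rows with missing
  values are dropped and logged, since rank statistics need complete
  profiles. Gene matching against set definitions is case-insensitive
  after whitespace stripping, with optional alias→canonical synonym
  remapping (chains collapsed so the map is idempotent).
- Networks need ≥ 2 measured genes (one pair) to be scored; smaller ones
  are excluded and logged, with declared-to-measured coverage recorded.
- Permutation tests are bit-reproducible for a fixed seed; the membership
  matrix is drawn once and shared across networks, which also means every
  network's null is computed under the same permutations (as a pooled null
  requires).
- Test-suite problem sizes (e.g. B = 199–4,000 permutations, 50 planted
  seeds, 500-sample oracles) are the package's chosen verification scale;
  the API defaults remain 1,000/10,000 permutations.
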