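# Methods

This document describes the statistical model behind each module, the
parameter defaults and their rationale, what the synthetic generators do and
do not emulate, and the package's known limitations.

## Alignment construction (`pdcovar.alignments`)

Each family member contributes one row: its aligned protein sequence
concatenated with its trimmed target site. Protein columns keep the
numbering of the input alignment (or a user-supplied reference numbering via
`protein_labels`); DNA columns carry signed position labels.

**Target-site anchoring.** Sites are anchored on the cut sites: `top_cut` is
the 0-based offset of the first central-4 base and `bottom_cut = top_cut +
4`, so the central 4 bases are the 4-nt 3′ overhang generated between the
two scissile phosphates. `anchor_and_trim(site, flank=9,
central4_start_label=2)` keeps `flank` bases on each side of the central 4
and labels positions contiguously with signed integers that skip 0. With
the defaults the central 4 occupy +2…+5 and a 22-nt trimmed site spans
−8…+14. The first central-4 label is a parameter because position-numbering
conventions differ between studies; +2 follows the convention in which
labels count from the site midpoint rather than from the cut.

**Gap filtering.** `filter_columns` removes protein columns whose gap
fraction strictly exceeds 0.5 (DNA columns are never removed). Gap-rich
loop columns are scored on few members and otherwise dominate the pair pool
with noise.

## Covariation scores (`pdcovar.covariation`)

MI is the plug-in (maximum-likelihood) estimator on raw symbol frequencies,
computed over *pairwise-complete* members only: a member is dropped from a
pair if it is gapped (or `X`) in either column. No pseudocounts, no
sequence weighting, no small-sample bias correction — with ~28 members any
of these would be poorly calibrated, and the downstream APC + permutation
null absorb the shared bias instead.

- `APC(i, j) = MĪ(i) · MĪ(j) / MĪ`, where `MĪ(i)` is the mean MI of
  column `i` against all other scoreable columns and `MĪ` the grand mean.
  `MIp = MI − APC` removes shared phylogenetic/entropy signal.
- `Zpx` standardizes MIp globally over all scoreable pairs (sample sd,
  `ddof=1`). Only this single global standardization is implemented;
  variants that standardize per row/column of the matrix are not provided.

Pairs with fewer than two complete members are unscoreable (`NaN`) and are
excluded from the pool. All three pair classes (protein–protein,
protein–DNA, DNA–DNA) enter the same pool, so a pair's Zpx is relative to
the whole alignment.

Implementation: columns are one-hot encoded (amino acids and nucleotides in
one 24-symbol code; gap cells are all-zero) and joint count tables for all
pairs are obtained by chunked tensor contraction, which makes the full
matrix exact yet fast (a 28 × 86 alignment scores in ~0.2 s).

## Permutation null (`pdcovar.shuffle_null`)

The null hypothesis is "no protein–site pairing signal". Three schemes:

- `assignment` (default): permute whole site rows across members. Both the
  protein block and every site sequence are preserved; only the pairing is
  broken. Protein–protein MI values are invariant, and DNA–DNA values are
  too (rows move together), so only protein–DNA entries are recomputed per
  shuffle — the fast path is exact and is tested against full rescoring.
- `within_site`: permute the bases inside each member's own site
  (destroys positional structure, preserves per-member composition).
- `within_column`: permute each DNA column independently across members
  (preserves column compositions, destroys within-site correlation).

Randomness is counter-based: shuffle `k` of a run with seed `s` uses
`numpy.random.default_rng([s, k])`, so results are independent of execution
order. Significance is the add-one empirical p,
`p = (1 + #{null ≥ observed}) / (n + 1)`, never exactly zero.

## Read handling (`pdcovar.depletion_counts`)

- **Demultiplexing**: exact barcode match at a fixed read offset;
  mismatched barcodes go to `unassigned`. Barcodes must be unique and of
  equal length.
- **Core extraction**: the read must contain upstream flank + core +
  downstream flank at the expected offsets, with at most
  `max_mismatch_per_flank = 1` mismatches in *each* flank. Cores with
  ambiguous bases are rejected. Rejection reasons (`too_short`,
  `flank_mismatch`, `ambiguous_core`) are tallied, and the pipeline report
  satisfies the conservation identities
  `assigned + unassigned = total` and `accepted + rejected = assigned`.
- **Count table**: all `4^core_length` substrates (256 for the 4-base core)
  are zero-filled so downstream compositional analysis sees a fixed
  support.

## Depletion kinetics (`pdcovar.kinetics`)

**CLR.** Counts are transformed per sample:
`clr(c_s) = log2(c_s + 0.5) − mean_s log2(c_s + 0.5)`. Sequencing counts
are compositional (only relative abundance is observable); under
first-order depletion `a_s(t) ∝ a_s(0) · 2^(k_s t)` the expected CLR is
linear in time with slope `k_s − mean(k)`, so fitted slopes are *centered*
rates. A pseudocount of 0.5 keeps zero counts finite; an optional
Monte-Carlo mode averages CLR over Dirichlet resamples of the composition
for users who want posterior smoothing, but the deterministic transform is
the default (reproducible, and adequate at the depths used here).

**Rate fitting.** `k_rel` is the slope of a single pooled OLS over all
replicates × timepoints (replicates are not averaged first; pooling
preserves degrees of freedom for the residual estimate). Reported per
substrate: `k_rel`, `se_slope`, `sigma` (the standard error of the
estimate, i.e. residual SD `sqrt(RSS/(n−2))`), `intercept`, `n_points`.

**Differential substrates.** For enzymes A and B, each substrate's point
`(k_A, k_B)` is compared with an axis-aligned ellipse centered on the
identity-matched mean `((k_A+k_B)/2, (k_A+k_B)/2)` with semi-axes
`n_sd · sigma_A` and `n_sd · sigma_B` (default `n_sd = 2`): flagged iff
`(d/(2·n_sd·σ_A))² + (d/(2·n_sd·σ_B))² > 1` with `d = k_A − k_B`. Side
"A" means enzyme A depletes the substrate faster (more negative rate).
`sigma` rather than `se_slope` defines the ellipse: the slope standard
error shrinks with the number of samples and would flag ~5% of substrates
under *identical* rates, whereas the residual-SD ellipse is conservative
and flags none. The cost is reduced power at low depth — differences must
exceed the CLR noise scale, not the slope uncertainty (see Limitations).

**Preference matrices.** A set of flagged substrates is summarized as a
positions × bases frequency matrix (rows sum to 1), exported as TSV
(suitable for any logo-drawing tool).

**Barcode assay normalization.** For low-throughput validation
timecourses, `barcode_relative_cleavage` fits cleaved-fraction-versus-time
slopes and normalizes them to a reference substrate.

## Synthetic generators (`pdcovar.synthetic`)

Generators are first-class, tested code: every statistical claim about the
pipeline is validated on data with known truth.

**Family generator.** Each column is two-state with the majority
probability chosen so the column's binary entropy equals
`background_entropy` (default 1 bit, i.e. 50/50). Members are drawn
independently per column (star phylogeny). For a planted pair with
coupling `c`, the residue is set deterministically from the member's base
via a fixed injective map (A→K, C→Y, G→R, T→E, recorded in the truth
record) with probability `c`, otherwise drawn from background. An optional
two-clade mode draws clade-specific column biases to test that APC absorbs
shared-ancestry signal. Gaps (protein block only) are i.i.d. at
`gap_rate`. Defaults: 28 members, 64 protein columns, 22-nt sites —
family sizes and site lengths typical of a single meganuclease subfamily;
64 protein columns keep the pair pool large enough (>2,000 pairs) for the
global Z-standardization to be meaningful while scoring in well under a
second. Not emulated: realistic indel evolution, rate heterogeneity,
higher-order epistasis.

**Depletion generator.** Substrate abundance follows
`a_s(t) ∝ a_s(0) · 2^(rate_s · t)` with `rate_s ≤ 0`; reads are drawn
multinomially at the configured depth per sample (or, with
`sampling="expected"`, taken as exact expected counts — useful for
zero-noise closed-form checks). Reads are laid out as
barcode + upstream flank + core + downstream flank, with optional i.i.d.
per-base substitution errors, and written as FASTQ. Defaults — timepoints
(0, 5, 10, 15, 30, 60, 120) min, 5 replicates, depth 10^5, error rate 0,
rates uniform(−0.08, 0) — mirror a typical profiling experiment. Not
emulated: PCR amplification bias, indel sequencing errors, quality-score
structure.

Same config + seed is byte-identical everywhere; all internal seeding is
counter-based (`default_rng([seed, k])`).

## Numerical choices

- MI via one-hot tensor contraction: exact plug-in counts, vectorized; the
  full matrix is mirrored from the upper triangle so it is exactly
  symmetric.
- OLS in closed form (vectorized over substrates), checked against
  `scipy.stats.linregress` in the tests.
- Empirical p-values use the add-one rule.
- All tolerances in tests are absolute and tied to the arithmetic (1e-12
  for exact identities, looser for sampling-based statements).

## Limitations and open decisions

- **No sequence weighting / phylogenetic correction beyond APC.** With 28
  members, tree-aware null models are underdetermined; the `assignment`
  shuffle plus APC is the operative control. The two-clade simulation mode
  exists to quantify residual clade-driven false positives.
- **Single global Zpx.** Row/column-wise standardization variants of Zpx
  are not implemented.
- **Conservative differential calling.** The residual-SD ellipse gives a
  ~0% false-positive rate under identical rates but requires rate
  differences comparable to the CLR noise scale; at depth 10^5 and default
  rates (spread 0.08/min) real differences below ~0.1/min are generally
  not flagged. Deeper sequencing or shorter timecourses (keeping fast
  substrates above the count floor) restore power, as in
  `analysis/04_simulate_depletion.py`.
- **Count floor.** Substrates depleted to ~0 counts contribute flattened
  CLR trajectories; rates for very fast substrates are biased toward zero
  at late timepoints. Choose the fit window so expected counts stay well
  above the pseudocount.
- **Reference-family reproduction requires curated input data** (the
  28-member protein alignment with reference numbering and the target-site
  table) under `data/reference/`; the two corresponding acceptance tests
  fail with an explanatory message until those files are provided.
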