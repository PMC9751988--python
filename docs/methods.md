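# Methods

## The question and the statistic

Correlation filtering of sequence-predicted miRNA/isomiR targets — keep a
predicted pair only if the two expression profiles are significantly
anti-correlated across samples — is ubiquitous, but a negative correlation
can arise without targeting (e.g. opposite-signed regulation of the isomiR
and a gene by a shared transcription factor). `isoita` quantifies
targeting against a sequence-defined negative control: for each 5′-isomiR,
the set of transcripts that contain no seed-binding site at all.

For one isomiR in one sample group, let n_tar be its predicted targets and
m_tar those with Spearman ρ < −0.3 and BH FDR < 0.05 (both strict), and
n_nontar / m_nontar the analogous counts over its non-target set. Then

- ITA = m_tar,
- background ITA = n_tar · m_nontar / n_nontar (the anti-correlated count
  expected if targets behaved like background),
- adjusted ITA = m_tar − n_tar · m_nontar / n_nontar.

Adjusted ITA is linear in both m's; it equals m_tar when the background is
quiet and crosses zero exactly when the anti-correlated fractions
coincide. It can be negative for a genuinely functional isomiR: if the
single true target is a hub TF, the isomiR anti-correlates with the TF's
downstream genes by transitivity, inflating m_nontar — this requires
n_tar > 1 for the product term to exceed m_tar = 1, since with a single
predicted target adjusted ITA = 1 − m_nontar/n_nontar ≥ 0.

Activity significance uses the one-sided Fisher's exact test on
[[m_tar, n_tar − m_tar], [m_nontar, n_nontar − m_nontar]] with alternative
"anti-correlation is more frequent among targets", i.e. the upper
hypergeometric tail P(X ≥ m_tar) at fixed margins. One-sidedness in this
direction is the only choice consistent with using the test to *detect*
activity. Fisher p-values are BH-adjusted across isomiRs within each
(group, stratum) family; an isomiR is *active* at Fisher FDR < 0.05.

## Seed model

Seeds are isomiR positions 2–7 (extended 2–8) counted on the isomiR's own
5′ end, i.e. after the 5′ shift encoded in the `name|shift` identity.
Site windows are 8-nt mRNA substrings, read 5′→3′, whose 3′-most
nucleotide opposes miRNA position 1; coordinates are 0-based half-open and
a site is keyed by its 5′-most position, taking the region (5′-UTR / CDS /
3′-UTR) of that start position when it spans a boundary.

Classification follows the canonical motif hierarchy — 8mer (2–8
Watson–Crick + A opposite position 1), 7mer-m8, 7mer-A1, 6mer — with fixed
precedence, plus a relaxed `other` class: seed 2–7 paired with unlimited
G:U wobbles (both G:U and U:G orientations) and at most one irregularity,
which may be a mismatch (evaluated in register on the six opposing
nucleotides), one bulged mRNA nucleotide (the 7-nt segment `window[0:7]`
opposite seed 2–7 with one deletion), or one bulged seed nucleotide (the
5-nt core `window[2:7]` against a 5-nt seed). This is a deliberately
minimal geometry confined to window classification; a full pattern/energy
engine of the RNA22 kind is out of scope.

Non-target sets are computed per isomiR as the complement of all
transcripts carrying any *admissible 6-mer*: the set of mRNA 6-mers fully
pairing with the 6-nt seed under WC + unlimited wobbles (set size
2^(#G + #U in the seed)). The scan runs over the full transcript sequence
(all regions) through a 6-mer hash index. Because an admissible 6-mer at a
transcript edge has no complete 8-nt window, a transcript can carry an
admissible core yet no classifiable site; it is still excluded from the
non-target set — the conservative choice for a negative control. Inside
the ITA computation, any transcript appearing among an isomiR's predicted
targets is additionally removed from its non-target set (an `other` site
with a mismatch need not contain an admissible 6-mer), so no transcript
occupies both rows of the 2×2 table.

## Expression processing

Size factors use the median-of-ratios estimator: reference features are
those with strictly positive counts in every sample; each sample's factor
is the median count/geometric-mean ratio over the reference. When no
reference feature exists the computation fails loudly rather than falling
back to a pseudo-reference. FPM scales size-factor-divided counts to
per-million of the mean normalized library size; FPKM further divides by
transcript length in kb. Correlations are computed on log2(x + 1) of the
normalized values. Normalization is performed once over all samples
jointly (cancer and normal together) before group splitting; a
`per_group_normalization` switch is available.

3′-end isomiR variants share a seed, so rows keyed
`name|shift|variant` are summed into 5′-isomiRs, preserving totals
exactly. IsomiRs are then ranked by median normalized expression
(ties broken lexicographically — the rank rule needs a deterministic
tie-break and the id is the only canonical key) and the shortest prefix
covering 99 % of the total median is retained. Transcripts with zero
counts in strictly more than half the samples are discarded; exactly half
is retained (literal reading of "more than half").

## Correlation engine

Pairwise Spearman uses mid-ranks with the two-sided large-sample t
approximation (appropriate at the intended group sizes of ≥100 samples;
the exactness tests target ρ, not p). The all-pairs path ranks each row
once and takes matrix products of centred rank vectors; it matches
`scipy.stats.spearmanr` pair-by-pair to 1e-12. Constant expression
vectors have undefined rank correlation and are excluded from both
numerator and denominator counts with a logged tally. The BH family for
correlation p-values is all target *and* non-target pairs of a group
jointly — the threshold must mean the same thing in both rows of the
contingency table.

## Synthetic data

The generator produces every pipeline input as a pure function of a
`SimulationConfig` (seed included). Defaults define the reference
experiment: 800 transcripts (150–500 nt, regions at 15 %/70 % of length),
20 isomiRs of which 10 are active with 30 planted 8mer sites each in the
3′-UTR, 20 designated scrubbed non-targets per isomiR, 10 silent
transcripts, two groups of 200 samples.

Expression is log-normal: isomiR log2 values are N(μ_i, 1) with
μ_i ~ U(8, 10) — emulating the post-selection regime in which only highly
expressed isomiRs (the 99 %-coverage set) are analysed, and ensuring the
coverage rule retains every simulated isomiR so selection does not
interact with recovery experiments. Transcript log2 values are baseline
(U(1, 9); silent −3) plus N(0, 0.5) noise; planted targets add
β·(isomiR − μ_i) with β = −1, giving a planted-pair log-scale correlation
of β/√(β² + σ²) ≈ −0.89, comfortably below the −0.3 threshold at n = 200.
Counts are round(2^value), so zeros arise naturally at low baselines and
exercise the transcript filter. IsomiR counts are split into two 3′
variants by per-cell multinomial draws with fixed per-isomiR proportions,
exercising 5′ aggregation.

With `confounded_fraction` γ > 0, each of `n_confounded` otherwise
inactive isomiRs gains a latent standard-normal confounder Z (a hub-TF
stand-in): the isomiR's expression adds +slope·Z while a γ-fraction of all
non-planted transcripts adds −slope·Z. Both the isomiR's chance predicted
targets and its non-targets are confounded at the same rate, so raw ITA
rises (the failure mode of unadjusted correlation filtering) while
adjusted ITA and the Fisher test stay null — the scenario the background
adjustment exists for.

The internal sequence predictor that fills the RNA22-like and
TargetScan-like fixture tables locates candidate windows through the
admissible-6-mer index and classifies them; by default it emits only the
four classical types. In uniform random sequence the relaxed `other`
motif matches a large fraction of transcripts by chance, which would make
every predicted-target set mostly background — real tools prune such
sites with energy and pattern filters not modelled here. Consequently
`other`-relying sites (and any site whose window is truncated by a
transcript end) are absent from synthetic prediction tables, though fully
supported on input. What passing synthetic tests shows is therefore that
the statistic recovers planted monotone repression against realistic
chance-site background; it does not validate prediction quality on real
sequences, 3′-isomiR heterogeneity, library-composition artefacts, or
subtype biology.

## Numerical and design choices

- Strict inequalities at both thresholds (ρ < −0.3, FDR < 0.05), matching
  the statistic's definition.
- Fisher p via the hypergeometric survival function; exact agreement with
  integer tail summation is enforced to 1e-12 for all margins ≤ 30.
- BH via the standard step-up; permutation-equivariant and validated
  against the O(m²) definition.
- A pair with several sites (types/regions) enters every corresponding
  stratum; pair-level summaries label a pair with its highest-precedence
  seed type.
- Pipeline rows with n_tar = 0 or n_nontar = 0 in a stratum are skipped
  with a warning (no background is estimable); groups below
  `min_group_size` (default 100) are skipped likewise.
- DNA-alphabet inputs are transcribed to RNA and upper-cased at parse
  time; any other character is an error.
- There is no unseeded randomness in the analysis path, and set iterations
  feeding output files are sorted, so identical inputs give byte-identical
  outputs across processes.

## Problem sizes in tests

The test suite runs the classifier against an exhaustive 4^8-window oracle
for three isomiRs, the non-target scanner against a per-position pairing
oracle on 50 replicates of 20 isomiRs × 200 transcripts, Fisher against
exact tail sums on all ~2.4·10^5 small tables, and the full pipeline on
desk-scale simulations (90–800 transcripts, 40–200 samples per group) —
sizes chosen so each oracle remains feasible to compute directly while the
statistical checks (recovery, null calibration, confounder neutrality)
operate in the regime the estimator is designed for.
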