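# Methods

## Codon-delimited alignment

Coding sequences are validated on input: upper-cased, `U→T`, strictly
A/C/G/T (IUPAC ambiguity codes are rejected rather than propagated, because
every downstream counting and likelihood step assumes unambiguous codons),
length divisible by 3, one terminal stop stripped, internal stops fatal.
The genetic code defaults to the standard nuclear table (NCBI table 1) and
is selectable.

Proteins are aligned with global affine-gap Needleman–Wunsch (BLOSUM62,
gap open −10, gap extend −1 by default; a gap run of length L costs
`open + (L−1)·extend`). More than two sequences are aligned progressively:
optimal pairwise alignments give Poisson-corrected distances
(d = −ln(1−p), p capped at 0.95 so the correction stays finite), a
neighbor-joining guide tree orders profile–profile merges, and sum-of-pairs
scoring with deterministic leftmost/lowest-index tie-breaking makes output
reproducible. The protein alignment is then mapped back onto the CDS:
residue column i becomes nucleotide columns 3i..3i+2, a gap residue becomes
`---`. Two invariants hold by construction and are enforced in tests:
no aligned triple is ever a partial codon, and degapping any row recovers
the input CDS exactly. Supplied pre-aligned protein guides bypass the
aligner; a translation mismatch between guide and CDS is an error (the tool
never silently "repairs" the guide).

## Pairwise dN/dS

NG86 counting: per codon, the synonymous fraction of each position is the
share of non-stop single-nucleotide changes that preserve the amino acid
(mutations to stops are excluded and the fraction renormalized, keeping
s + n = 3). Differences between codons are averaged over all orderings of
single-nucleotide steps; orderings through stop codons are dropped, and in
the degenerate case where every ordering hits a stop, all differing
positions are counted as nonsynonymous with a logged warning. Sites are
averaged over the two sequences; proportions p_S = S_d/S and p_N = N_d/N are
corrected with d = −(3/4)·ln(1 − 4p/3). ω is reported as `NA` when it is
0/0 or the correction is out of domain (p ≥ 3/4), and as `Inf` when
dS = 0 with dN > 0 — the two cases stay distinct through CSV and plots
(undefined windows render as gaps, not zeros).

The YN00-style method estimates κ first from fourfold-degenerate and
nondegenerate codon positions (positions classified in both sequences)
using the K80 correction — κ = α/β with
α = −½ln(1−2P−Q) + ¼ln(1−2Q), β = −¼ln(1−2Q) — combined by site-count
weighting, falling back to κ = 2.0 with a warning when the pair carries no
signal. Sites and mutation pathways are then weighted by κ (transitions)
and by F3x4 target-codon frequencies computed from the two sequences being
compared, and the weighted counts are iterated to a fixed point (tolerance
1e-8, ≤100 iterations) with the same correction form. Exact numeric
agreement with other implementations of the approximate method is not a
goal; the NG86 column is the default for window tracks.

Window scans operate in codon units (a "window of 100" is 100 codons,
matching an amino-acid x-axis), with 1-based inclusive coordinates and the
window midpoint as plotting coordinate. When the last full window does not
reach the end, a right-anchored full-width terminal window is appended
(rather than a truncated one) so per-window variance stays comparable; it
can be disabled. Windows in which a pair has no comparable codons are
flagged and skipped, not fatal. Window scans are exploratory; the site-model
LRTs are the confirmatory analysis, and the scan logs that caveat.

## Trees

Newick in/out (any tree with unique leaf labels; missing branch lengths
default to 0.1 substitutions/site with a warning, and are re-estimated by
the likelihood machinery anyway). Written trees order children by smallest
contained leaf label, so write→parse→write is byte-stable. Neighbor joining
is the classical Q-matrix agglomeration, consistent on additive matrices;
negative branch-length estimates are clamped to zero. Multifurcations are
accepted by the parser but rejected by the likelihood engine (binary
required, trifurcating root allowed — the natural representation of an
unrooted binary tree).

## Site models

GY94: a reversible 61-state generator with single-nucleotide changes rated
by κ (transition), ω (nonsynonymous) and target codon frequency π_j.
Mixtures share one κ and one set of branch lengths; the per-class
generators are scaled jointly so the mixture-average rate is one expected
substitution per codon site — branch lengths are therefore in expected
substitutions per codon under the whole mixture. Codon frequencies are
F3x4 from the alignment (default) or uniform, fixed rather than
ML-optimized; F3x4 floors positional nucleotide frequencies at 1e-4 so no
sense codon gets zero weight. Transition matrices come from the symmetric
(π-similarity) eigendecomposition of the generator; likelihoods from
Felsenstein pruning over unique site patterns, with gap codons as missing
data (conditional likelihood one in every state).

Beta models discretize beta(p, q) into K = 10 equal-probability classes at
the class-median quantiles. Optimization is L-BFGS-B on transformed
parameters (log for κ, ω, beta shapes and branch lengths; logit /
stick-breaking for class probabilities; 1+exp for ω_s ≥ 1), multi-start
(default 3 starts, perturbations seeded from the fit seed), convergence
tolerance 1e-6 on lnL. Branch lengths are estimated by ML under M0 and then
fixed for M1a/M2a/M7/M8 — an order-of-magnitude speedup; per-model
re-optimization is available via `optimize_branch_lengths="per-model"`.

LRTs use χ² with df = 2 for M1a-vs-M2a and M7-vs-M8 (difference in model
free parameters, branch lengths shared). No boundary (mixture-of-χ²)
correction is applied, the common practice; this makes the tests mildly
conservative, which the null-calibration test reflects. Per-site inference
is naive empirical Bayes: class posteriors ∝ p_k·L_site(ω_k) at the ML
estimates, giving posterior mean and SD of ω per site; a site is flagged
positive when posterior mass on ω > 1 classes exceeds 0.5 ("strong" above
0.95). NEB ignores parameter uncertainty — with few taxa its error bars
are optimistic compared to a full empirical-Bayes treatment; this is the
package's documented substitute for uncertainty-integrated site posteriors.

## Simulator and what it does (not) show

`simulate_alignment` draws root codons from π and evolves each site with
the exact per-branch transition matrix of its ω class (matrix exponential,
not Gillespie), emitting per-site true ω labels. It emulates: site-wise
selection heterogeneity, transition bias, codon-frequency bias. It does
not emulate: indels (gapped fixtures are made by deleting codons after
simulation), rate variation beyond ω classes, recombination, sequencing
error, or alignment uncertainty — so passing recovery tests demonstrates
correctness of the estimators under the model, not robustness to real-data
misspecification.

Study conditions used by the tests and the acceptance script, chosen once
as Caenorhabditis-like divergence: a 4-taxon tree
`(a:0.25,b:0.25,(c:0.25,d:0.25):0.1)` (total ≈ 1.1 substitutions per codon),
κ = 2, uniform codon frequencies; 500 codons for model fits (10 replicate
seeds for recovery and LRT calibration batteries), 150 codons for the
two-segment window scan (ω = 0.05 / ω = 3), 2-taxon trees of total length
0.6 for pairwise counting checks. Problem sizes for the brute-force oracle
comparisons (alignment pairs to length 6, trees to 4 taxa and 5 codons for
state enumeration) are the largest at which exhaustive enumeration is
practical on a desktop.

## Known limitations

- NEB, not BEB: site posteriors condition on point estimates.
- One κ and fixed frequencies across classes; no MG94, branch or
  branch-site models.
- The YN00-style column is a faithful implementation of the approximate
  method's structure, not a bit-level reproduction of any particular
  external program.
- NJ only for tree building (no parsimony/ML search); user trees must be
  binary for the likelihood stage.
- Sliding-window statistics carry no significance assessment; use the LRTs.
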