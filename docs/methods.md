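# Methods

This note documents the models implemented in `mirhost`, the assumptions
behind them, the tunable parameters, and the design choices made where the
design was genuinely open.

## Biological model and assumptions

The package rests on two co-expression assumptions. First, a mature miRNA
whose precursor overlaps a protein-coding gene is transcribed with that
host, so its (unobserved) expression is positively correlated with the host
transcript's expression; maturation and post-transcriptional regulation of
the miRNA are deliberately neglected. Second, an active miRNA degrades its
target mRNAs, so target expression is anti-correlated with the miRNA's.
Chaining the two, host genes and targets of one miRNA are mutually
anti-correlated, and an mRNA-only dataset contains enough signal to infer
both differential miRNA activity and candidate targets. The approach covers
intragenic miRNAs only: a miRNA with no host gene on the array is invisible
to it.

All expression matrices are log2 expression indexes, the scale RMA-style
pre-processing produces. Fold change is the signed log2 difference of group
means, with the group listed first in the design table (conventionally the
control) as baseline; for >2-group ANOVA the fold change is the spread of
the extreme pair of group means and its sign carries no direction. Design
tables with several factor columns are collapsed into one crossed factor
and tested by one-way ANOVA. The default row test is Welch's *t*
(Student's *t* and ANOVA selectable); rows with zero variance everywhere
and equal means receive p = 1 / FC = 0 (p = 0 when the means differ), so
downstream shapes stay stable.

## Permutation-derived significance cutoff

Rather than a fixed alpha, the p-value threshold is the smallest p-value
observed when the row test is re-run on data with shuffled sample-to-group
labels. The shuffle preserves group sizes (a plain label permutation). One
permutation is the default; with `n_perm > 1` the global minimum over all
permutations is used, which makes the cutoff monotone non-increasing in the
number of permutations. Under a pure null with m independent rows the
cutoff is the minimum of m uniform variates, Beta(1, m), with expectation
1/(m+1) — the calibration the acceptance suite checks. The permutation seed
is recorded in the run manifest.

## Predictor I: scaling function

Per mature miRNA, pseudo-expression is the mean of host expression times a
weight vector, w_i = |FC_i| (1 − p_i) k_sense k_overlap k_evidence. The k
coefficients are fixed constants (sense 1.2 / antisense 0.8; intron 2 /
exon, 3'UTR, 5'UTR 0.8; experimental 1.2 / predicted 0.8) encoding that
spliced-out intronic sequence on the coding strand with experimental
annotation support is the most plausible precursor source. The mean of
elementwise products is used literally — it is *not* normalized by the
weight sum, which can overstate fold changes of highly expressed hosts; a
normalized weighted mean is available (`normalized=True`) but off by
default. Both mature forms (miR and miR*) of one precursor receive the same
pseudo-row, as the mapping carries both and the model cannot distinguish
them. Duplicate edges for one (miRNA, probeset) pair are collapsed
preferring experimental evidence, then intronic overlap, then the lowest
start coordinate, because real mapping tables contain many near-duplicate
annotation rows per pair.

## Predictor II: linear model

Measured miRNA expression (from a paired training dataset) is modelled as a
linear function of host-transcript expression `e`, |FC|, (1 − p) and a
miRNA-identity factor. The formula operator `*` is read as main effects
plus all interaction terms; because every covariate interacts with the
identity factor, the global least-squares problem is block-diagonal and is
solved as independent per-miRNA regressions — a tested equivalence, not an
approximation. Three variants exist: the full form with the categorical
overlap/strand/evidence attributes (`eq8`), the default without them
(`eq9`), and expression-only (`eq10`). Aliased design columns (common when
covariates are constant within a miRNA block) are dropped by QR with column
pivoting before solving; coefficient standard errors come from the usual
OLS covariance on the retained columns.

Rows are shuffled with the run seed and split 2/3 train / 1/3 test. Each
host transcript predicts separately, the per-miRNA prediction is the median
across transcripts, and the reported prediction power is the Pearson
correlation between median-aggregated predictions and observations on the
held-out third. miRNAs with fewer than two training rows are excluded with
a warning. By default the mapping is pre-filtered to sense-strand intronic
edges before building design rows, the variant the attribute analysis
identifies as carrying the signal; the evidence attribute is dropped by
default (`eq9`). Higher-order predictors (GLMs, neural networks, genetic
algorithms) are intentionally out of scope.

One identifiability caveat: with several hosts per miRNA and no noise, the
per-transcript intercept offsets cannot be absorbed by covariates that are
constant within the block, so noiseless multi-host data are not perfectly
interpolated; the noiseless-recovery guarantees in the test suite therefore
use the single-host geometry, where the slope on `e` is exactly the
generating coefficient.

## Consensus, correlation and target filtering

Each predictor's pseudo-matrix passes through the same row test and
permutation cutoff; direction (up/down) comes from the sign of the pseudo
fold change. The consensus is the set union with per-miRNA provenance
(scaling / linear / both); an empty union terminates the pipeline with a
distinct exit status (3) since no further analysis is possible. For
correlation, every consensus pseudo-row is correlated against every
significant mRNA row — Pearson by default, Spearman with average ranks on
ties, or Kendall τ-b — in row chunks so memory stays proportional to the
output. Zero-variance rows give missing entries that can never pass the
filter. `get_ht` keeps entries at or below a negative cutoff, −0.8 by
default for a conservative target list (−0.6 for broader screens), sorted
by correlation. Interactions are aggregated from (probeset, mature-form)
pairs to (gene, miRNA) records; the support score is the number of
anti-correlated entries backing the pair, and the direction label
(repression gained / lifted / inconsistent) combines the miRNA and gene
fold-change signs.

## Enrichment

Over-representation is the hypergeometric upper tail P(X ≥ k) for overlap k
between the target gene list and each gene set, with both intersected with
the universe first. The default universe is every gene represented on the
input matrix after annotation translation, and it is user-overridable.
GO/KEGG/disease-ontology content is consumed as ordinary GMT files; no
ontology-graph propagation is performed. Raw p-values are the primary
statistic; Benjamini–Hochberg adjusted values are reported alongside as
modern hygiene — they do not change rankings. The one-sided Fisher exact
test on a 2×2 table is provided for comparing two prediction sets and is
exactly the same hypergeometric tail (cross-checked in the tests).

## Binding-energy validation

Candidate 3'UTRs are scanned with a 25 nt window and 5 nt step; trailing
partial windows are dropped, so a UTR of length L yields
⌊(L − 25)/5⌋ + 1 windows. For genes with several isoforms the longest
3'UTR is used (ties broken by smallest transcript id) and genes whose
longest 3'UTR is under 100 nt are discarded. Each window is joined to the
mature miRNA by an 8-base unpairable 'X' linker and scored by the minimum
free energy of the joined molecule; the lowest-energy window is the
putative binding site, the leftmost window winning ties.

The default backend is a nearest-neighbour *hybridization* dynamic program:
Watson–Crick and GU wobble pairs, published Watson–Crick stacking free
energies with approximate wobble stacks (−1.0 / −0.5 kcal/mol), tabulated
bulge and internal-loop penalties (up to 4 unpaired bases per strand
between consecutive pairs), duplex initiation +4.09 and terminal AU/GU
+0.45 kcal/mol. Intra-strand pairs are forbidden, which makes the linker
contract (linker positions never pair) hold for any placeholder identity.
This is a documented approximation to a full folding engine: it ignores
intramolecular structure and uses coarse loop terms, so absolute energies
are approximate, but rankings agree with RNAduplex (Spearman ρ ≳ 0.87 on
random pairs in the cross-backend test), which is what the distribution
comparisons consume. An adapter (`backend="rnaduplex"` or any callable) is
provided for exact parity with an external engine. A fixed −20 kcal/mol
site cutoff is deliberately *not* applied; whole minimum-energy
distributions are compared instead, because a hard cutoff discards most
genuine targets.

Two randomized controls accompany every matched set: permuting the gene
assignment vector over the same sequences (derangement not enforced) and
substituting the 3'UTRs with other genes' sequences drawn without
replacement from a pool (uniform-random synthetic sequences of matching
length once the pool is exhausted). Matched vs control distributions are
compared by Welch's two-sample *t*-test with Welch–Satterthwaite degrees of
freedom; the two controls are expected to be indistinguishable, and because
a single permutation can re-create a matched pair by chance, that null
comparison is judged on the median p-value over a few seeds rather than a
single draw.

## Synthetic data

The generators are pure functions of their parameters and seed. Mapping
tables draw edge attributes at the observed genomic proportions (92%
intronic, 5% exonic, 2% / 1% UTRs; 83% sense strand; evidence split 50/50
as a neutral choice). Paired datasets use two balanced groups: host rows
are baseline + per-miRNA group effect (±1 log2 unit by default, i.e. a
two-fold shift, for half the miRNAs) + Gaussian noise (σ = 0.1 log2 units
by default); miRNA rows are a_j + b_j · mean(hosts_j) + noise with
a_j ~ U(0,2), b_j ~ U(0.8,1.2); target rows are c − miRNA + noise whose
variance is set analytically so the planted population anti-correlation
equals `target_strength` (default 0.95); remaining rows are independent
decoys. With zero noise the dataset is fully deterministic and planted
target correlations are exactly −1. Optional spurious mapping edges to
decoy genes (`decoy_edges_per_mirna`) emulate many-to-many mapping
ambiguity. The default geometry — 30 samples, 20 miRNAs, 500 genes — runs
the full pipeline in seconds; the linear-model recovery checks use 100
samples, 20 miRNAs and σ = 0.2.

What the generator does *not* emulate: probe-level effects, correlated
biological modules beyond the planted ones, non-Gaussian heavy-tailed
noise, unbalanced designs, or miRNAs that regulate hundreds of targets.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure under idealized conditions, not
field performance on real arrays. One consequence worth knowing: when
several planted miRNAs share the group-effect axis, hosts of one miRNA are
genuinely anti-correlated with another miRNA's row, so target-recovery
checks that count only planted pairs as true disable the group effect
(`diff_fraction=0`) to isolate the planted relations.

## Numerical choices and degenerate inputs

Quantile normalization assigns rank means by stable sort position (exactly
idempotent); single-column matrices are rejected. Correlation values are
clipped to [−1, 1] against float drift. The permutation shuffle re-draws if
a shuffle degenerates to one group. Empty significant sets and empty
interaction lists are returned with warnings rather than raised — the
pipeline decides termination. Reports are plain CSV plus a static HTML
index; QC visualizations are emitted as data tables (p-value histogram,
volcano coordinates, PCA sample scores from an SVD of the centered
significant matrix) so no plotting backend is required.

## Known limitations

Only intragenic miRNAs are predictable; direction labels depend on fold
changes from a two-group contrast and are not meaningful for >2-group
designs; the linear predictor needs a paired training dataset and does not
transfer attributes it never saw in training; the internal energy backend's
absolute energies should not be compared against literature values fitted
with full folding models; and the coordinate-based mapping builder assumes
transcript models with explicit exon/UTR intervals and classifies an
overlap spanning annotation boundaries by the fixed priority
3'UTR > 5'UTR > exon > intron.
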