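# Methods

This note documents the models, conventions and numerical choices behind
`motifcmp`, and what the synthetic benchmarks do and do not establish.

## Motif representation

A motif is a position frequency matrix (PFM): a `width x 4` matrix of
non-negative base counts over the fixed DNA alphabet A, C, G, T, tagged
with the tool that produced it and a per-motif significance (P-value,
E-value, a tool-native score, or none). Counts are kept real-valued:
MEME-minimal files store letter probabilities plus `nsites`, and the
product `prob * nsites` is not rounded, so a write/read round trip
preserves matrices to numerical precision. When a format carries no site
count, `nsites` defaults to 20 — a conventional order of magnitude for
de novo motifs, needed so merging can weight parents by the evidence
behind them. Probabilities (PWMs) are derived with an additive
pseudocount `p` (default 0.25):

    P[j,b] = (C[j,b] + p) / (sum_b' C[j,b'] + 4p)

Significance filtering keeps motifs whose P- or E-value is at or below
the cutoff (default 0.05 for both, inclusive boundary); motifs carrying
a tool-native score or no significance are treated as pre-filtered by
the producing tool and always admitted. Weeder-style native score files
are not parsed — the score semantics vary by tool version — so such
results are supplied as MEME-minimal or JASPAR matrices tagged
`tool_score`.

## Similarity and alignment

Two PWMs are compared by exhaustive ungapped alignment: every relative
offset on both strands with at least `min(4, width_A, width_B)`
overlapping columns is scored, and the best superposition is returned.
The per-column metric is

    sim(x, y) = 1 - ||x - y||^2 / 2,

which is 1 iff the columns are identical and 0 iff they are point
masses on different bases (the squared distance between two stochastic
vectors is at most 2). The superposition score is the mean column
similarity over the overlap, reported on a 0-100% scale. This metric
was chosen over Pearson column correlation because correlation is
undefined on uniform (zero-variance) columns and does not map linearly
onto a percentage cutoff; the metric is pluggable (`align(...,
metric=...)`) should a different column comparison be wanted.

The minimum-overlap floor exists because a one-column overlap between
unrelated motifs is frequently perfect by chance; four columns is the
narrowest window that is still motif-like. No length penalty is applied
beyond the floor: a short perfect sub-alignment of a long motif pair
scores higher than a long mediocre one. A practical consequence — worth
knowing when setting thresholds — is that two motifs sharing only a
strong 4-column core can exceed 75% even when the rest disagrees.

Ties between equally scoring superpositions are broken by larger
overlap, then forward strand, then smaller absolute offset, then the
negative offset; this makes every report byte-reproducible. The score
is symmetric in its arguments and invariant under reverse
complementation of either motif.

## Ensemble comparison

Given significant motif lists from two or more tools and a similarity
cutoff (default 75%), a motif is **global (common)** when every other
tool's best-scoring motif against it reaches the cutoff; the group
records that best counterpart per tool (a star around the anchor, not a
clique — consistent with "best match per motif" semantics and linear in
the number of tools). A majority mode (counterparts in at least half
the tools) is available but off by default. Groups with identical
member sets are collapsed. **Local** motifs are those that are neither
anchors nor members of any group, per tool, in their original rank
order; by construction the groups and locals partition each tool's
significant list, and raising the cutoff can only shrink the set of
groups.

The **best common motif** is selected by popular vote first — the group
supported by the most tools — and then by the highest mean similarity
of the non-anchor members to the anchor (the anchor's own trivial 100%
is excluded; for groups of equal support the member counts are equal,
so this choice cannot change an ordering). Remaining ties fall back to
the anchor id, for determinism.

## Merging

Two motifs are fused at their best alignment: the second motif's counts
are reverse-complemented if the best alignment is on the reverse
strand, the union span of the aligned windows becomes the merged width,
and counts are summed column-wise (so motifs backed by more sites
dominate; overlap columns conserve the parents' total mass). The fusion
is accepted only when the merged motif re-aligns to **both** parents at
or above the threshold. Collection-level merging is greedy
best-pair-first: the highest-scoring eligible pair is attempted,
accepted fusions replace the pair, rejected pairs are marked ineligible
and not retried. This ordering makes the result independent of input
file order; not retrying rejected pairs bounds the work. Note that at
the default 75% threshold the guard is permissive: even the 50/50 blend
of two disjoint point-mass motifs sits at exactly 75% (pseudocount 0)
or 79.3% (default pseudocount) from each parent, because flanking
columns contributed by a single parent match that parent exactly.
Thresholds of 80-90% are appropriate when only near-duplicates should
fuse.

## Clustering and trees

Pairwise best-alignment scores are converted to distances
`d = 1 - s/100`, giving a symmetric matrix with zero diagonal. Trees
are built by agglomerative clustering (SciPy linkage; average linkage
by default — the common choice for similarity-derived distances, and
monotone, so merge heights never invert; complete and single linkage
are options). Two trees are conventionally produced per comparison run:
one over the global-group anchors and one over the full multi-tool
collection. Newick output uses the ultrametric half-height convention:
clusters merging at height *h* join at elevation *h/2*, so leaves sit
at depth *h/2* below that node and the patristic distance between two
leaves equals their cophenetic merge height. Labels containing
whitespace or Newick metacharacters are single-quoted.

## Binding-site evaluation

Six statistics summarise agreement between predicted and known sites.
At the nucleotide level every position is classified against the
position-wise union of each site set (strand ignored — implanted-site
truth is positional): sensitivity `nSn = TP/(TP+FN)`, positive
predictive value `nPPV = TP/(TP+FP)`, specificity `nSp = TN/(TN+FP)`,
and the correlation coefficient

    nCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

which is exactly the Matthews correlation of the per-position binary
labels. At the site level a known site counts as found when a predicted
site on the same sequence overlaps at least 25% of its length (minimum
1 bp, boundary inclusive; the fraction is configurable), and symmetric
for predictions: `sSn` and `sPPV` are the corresponding hit fractions.
A statistic with a zero denominator is reported as undefined rather
than coerced to 0, and undefined values are skipped when averaging over
datasets — the same convention used when a tool reports no motif at all
for some dataset. Coordinates are 0-based half-open (BED) internally;
1-based inclusive TSV input is accepted behind a flag.

## Synthetic benchmarks

The generator reproduces the statistical structure of the classic
implanted-site assessment datasets: random background sequences with
one or more PWM-sampled binding sites implanted per sequence at known,
non-overlapping positions (overlapping implants would corrupt the
ground truth). Sites *replace* background bases, preserving sequence
length; each site's strand is uniform, with minus-strand sites
implanted as reverse complements. Sixteen named dataset shapes are
bundled (2-18 sequences of 500-2000 bp, "generic" or "markov" type).

Backgrounds: "generic" datasets — which originally drew real promoter
sequence — use a uniform i.i.d. background by default, since no genome
data is bundled; `fit_markov` can fit a chain of any order (pseudocount
1 on transition counts) to a user-supplied corpus for more realistic
composition. "markov" datasets use an order-3 chain; because the
original chains were fitted to species background, the bundled stand-in
is a seeded random chain with Dirichlet(5) conditionals — mildly biased
in the way genomic composition is, but synthetic. The implanted PWM
defaults to a seeded random 8-column matrix with informative
(Dirichlet(0.3)) columns, standing in for curated transcription-factor
models that are likewise not bundled.

What passing tests show: the generator is exactly reproducible from its
seed; truth-against-truth evaluation is perfect for every shape;
implanted-column base frequencies and planted Markov conditionals are
recovered within 3-sigma binomial/multinomial bounds at the stated
sample sizes (500 implants; ~10^5 background bases). What they do not
show: anything about real promoter composition, repeat structure,
nucleosome positioning or the true site density of ChIP data — real
motif-finder accuracy on these synthetic datasets will differ from
accuracy on the original benchmarks.

## Problem sizes and determinism

The verification suite runs at deliberately modest scale — hundreds of
random PWM pairs for oracle comparisons, 500 merge attempts, all 16
dataset shapes for closure checks, ~10^5 bases for distributional
recovery — sizes at which the binomial bounds above are already tight.
All randomness flows through a single seeded NumPy generator;
`scripts/acceptance.py --seed N` reproduces every reported number
exactly. Alignment scores are computed with sequential floating-point
accumulation in a fixed order, so independently written enumerators can
(and in the tests do) match them bit-for-bit.

## Known limitations

- The column metric is a stated, documented choice; published motif
  comparison tools use various metrics (Pearson, KL, E-value models)
  and will rank borderline pairs differently.
- No statistical significance is attached to cross-tool agreement or to
  database matches (no TOMTOM-style null model).
- Gapped motif alignment, information-content column weighting and
  protein/RNA alphabets are out of scope.
- The merge guard at permissive thresholds accepts blends of fairly
  dissimilar motifs (see Merging above).
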