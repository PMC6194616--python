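# motifcmp

Cross-tool comparison of de novo DNA motif discovery results.

Different motif finders (MEME, ChIPMunk, Weeder, XXmotif, ...) routinely
report different motifs for the same input sequences, because their
algorithms and significance models differ. `motifcmp` is for anyone who
runs several finders on the same dataset and needs to know what they
agree on: it compares the significant motifs across tools and reports

- **global (common) significant motifs** — motifs for which every other
  tool has a counterpart above a similarity cutoff,
- **local significant motifs** — motifs only one tool finds,
- the **best matches** for every motif in the multi-tool collection (or
  in a JASPAR reference database),
- a **best common motif** chosen by majority vote across tools and then
  by similarity rank,
- similarity-gated **merging** of redundant motifs and hierarchical
  **motif trees**,
- the six standard **accuracy statistics** for predicted binding sites
  against known sites, and
- a **benchmark simulator** that implants PWM-sampled sites into random
  (uniform or order-3 Markov) backgrounds with exact ground truth.

## The core computation

Motifs are position frequency matrices (counts `C` over A,C,G,T),
converted to position weight matrices with a pseudocount `p`:

    P[j,b] = (C[j,b] + p) / (Σ_b' C[j,b'] + 4p)

Two PWMs are compared by exhaustive ungapped alignment over all offsets
and both strands (minimum overlap `min(4, widths)`), scoring each
superposition by the mean per-column similarity

    sim(x, y) = 1 − ||x − y||² / 2     ∈ [0, 1]

over the overlap, reported as a 0–100% score. A motif is *global* when
each other tool's best match against it reaches the cutoff (default
≥75%); motifs in no group are *local* to their tool. Merging fuses two
motifs by summing counts over their aligned union span and accepts the
fusion only if it stays within the threshold of **both** parents. Motif
trees are average-linkage clusterings of the distance `1 − s/100`.
Binding-site predictions are scored at the nucleotide level (nSn, nPPV,
nSp and the Matthews correlation nCC) and at the site level (sSn, sPPV
under a ≥25%-overlap rule). See `docs/methods.md` for details and
conventions.

## Worked example

Compare MEME and ChIPMunk results (MEME minimal format; each file is
tagged `TOOL:FORMAT:PATH`), asking also for motif trees:

```sh
motifcmp compare -i MEME:meme:meme.txt -i ChIPMunk:meme:chipmunk.txt \
    --trees -o out
```

With two files that share one motif and carry one tool-specific motif
each, this prints:

```
Motif comparison report
similarity cutoff: 75.0%

Global (common) significant motifs: 1
  group 1: anchor chipmunk_1 [ChIPMunk], support 2 tools
    ChIPMunk: chipmunk_1 (100.0%) GGAGTTAA
    MEME: meme_1 (100.0%) GGAGTTAA

Local significant motifs (tool-specific):
  ChIPMunk: chipmunk_2
  MEME: meme_2

Best common motif: chipmunk_1 [ChIPMunk], support 2, mean member similarity 100.0%
```

The one shared motif (consensus GGAGTTAA) forms a global group with a
100% counterpart in each tool and is elected best common motif; the two
tool-specific motifs are reported as local. `out/` then contains the
TSV tables (`global_motifs.tsv`, `local_motifs.tsv`,
`best_matches.tsv`), the group anchors as a MEME-minimal file, the
distance matrices and Newick trees, and a `manifest.json` recording
inputs, thresholds and per-tool motif counts. For example, the
full-collection tree

```
('MEME:meme_2':0.172,('ChIPMunk:chipmunk_2':0.144,
 ('MEME:meme_1':0,'ChIPMunk:chipmunk_1':0):0.144):0.027);
```

joins the two copies of the shared motif at height 0 and attaches the
dissimilar motifs on longer branches.

Other subcommands: `motifcmp merge` (redundancy reduction),
`motifcmp tree`, `motifcmp match-db` (JASPAR database verification),
`motifcmp evaluate` (the six statistics from truth/prediction BED files
plus FASTA), and `motifcmp simulate` (benchmark generation;
`motifcmp simulate --list` shows the 16 bundled dataset shapes, e.g.
`hm08m`: 15 Markov-background sequences of 500 bp). `motifcmp simulate
--name yst02g --seed 7 -o sim` writes FASTA, truth BED and a JSON
sidecar; evaluating the truth against itself returns 1.0 for all six
statistics.

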