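# Methods

This note documents the models, estimators and design decisions behind
`rbfcoevo`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Gene catalogue and presence calling

The analysis is anchored on a curated catalogue of 154 genes: 100
ribosome biogenesis factors (RBFs) in six functional categories
(GTPases, maturation factors, ribonucleases, helicases, modification
enzymes, chaperones, plus a small "other" group of hibernation/stringent
factors) and 54 ribosomal proteins (RPs, 21 small-subunit + 33
large-subunit genes in standard *E. coli* nomenclature). The packaged
default (`data/catalog.tsv`) is a best-effort reconstruction from
published gene lists: the 100/54 composition is exact, KEGG orthology
(KO) identifiers are filled where unambiguous, and membership of some
modification enzymes is plausible rather than certain. Users with their
own curation supply a TSV with the same four columns.

A gene is called **present** in a genome when *any* of its identifiers
(gene symbol or any KO id) appears in the genome's annotation set. This
maximizes recall for KO-based annotation pipelines and degrades
gracefully to symbol matching when a catalogue row carries no KO ids.
Fragmented or partial genes are not distinguished: presence is
annotation presence.

## Conservation ratios and their classification

The conservation ratio of gene *j* in group *g* is the exact rational
count `present / n_genomes` (so `ratio * n` is always an integer).
The three-way classification uses the band convention *nearly absent*
(`r < 0.10`), *less conserved* (`0.10 ≤ r ≤ 0.90`, closed at both ends)
and *highly conserved* (`r > 0.90`). Putting the boundary values inside
the middle band is a deliberate convention (a ratio of exactly 10% or
90% reads naturally as "ranging from 10% to 90%"); both thresholds are
parameters. Cross-group comparison tables flag the transition of
interest — highly conserved in the reference group, less conserved in
the focal group — which is how lineage-specific RBF erosion is detected.

Ordination is plain PCA of the centered binary matrix
(scikit-learn), reporting scores, loadings, explained-variance fractions
and the top-loading genes per component. A constant matrix is rejected
rather than silently returning a degenerate rotation.

## Mutual-information dependency network

For genes A and B the dependency is the plug-in mutual information

    MI(A,B) = H(A) + H(B) − H(A,B)

over the empirical presence/absence distributions, with `0·log 0 = 0`
and no pseudocounts — the estimator is exactly the textbook formula
applied to the observed 2×2 cell frequencies. Tiny negative values from
floating-point cancellation are clipped at zero (anything below −1e−12
is treated as a bug, not noise). MI is symmetric and bounded by
`min(H(A), H(B))`; the pairwise screen over *k* genes evaluates exactly
`k(k−1)/2` unordered pairs — 11,781 for the default 154-gene catalogue.

**Log base.** Published MI thresholds are meaningless without the
logarithm base, and the base behind the analyses this package emulates
is not recorded. The default is the natural log with base 2 exposed
everywhere (`MI_bits = MI_nat / ln 2`); all outputs record the base
used.

**Thresholding** keeps edges with `MI ≥ τ` (closed bound, default
τ = 0.1). Genes constant across the genome set have MI 0 with every
partner; they are retained as flagged isolated nodes rather than
dropped. Node statistics are degree and cumulative incident edge
weight. The **hub** is defined as the unique top node by cumulative
weight that also attains the maximum degree: degree ties are expected by
construction (the partners of a star hub inherit mutual edges through
the hub, giving them the same degree at low thresholds), so weight
breaks them, and a weight tie yields no hub rather than an arbitrary
winner. By default the network is computed within one genome group
(group selection is a parameter), matching the within-clade design of
the analysis this package supports.

No significance testing is attached to individual MI values; the test
suite uses planted-truth and permutation-style nulls instead.

## Fitch parsimony gain/loss reconstruction

Binary characters are mapped onto a rooted tree with Fitch small
parsimony: the bottom-up pass computes candidate state sets (score = the
number of union operations), the top-down pass resolves one
most-parsimonious assignment. Tie-breaks are declared, not incidental:

* an ambiguous internal node takes its parent's resolved state
  (pushing changes rootward, ACCTRAN-flavoured);
* an ambiguous root resolves toward **presence** — the focal biogenesis
  factors are argued to predate the radiation of the clades analysed,
  so the prior leans to the ancestral gene being there;
* every ambiguous node is flagged in the output.

The resolved assignment realizes exactly `score` changes (asserted
internally); events are reported per branch as gain (0→1) or loss
(1→0). Exhaustive enumeration over all internal labelings on small
trees, and an independent R/phangorn cross-check, serve as test oracles.
Parsimony is a lower bound on the true event count; the simulation tests
quantify when it is exact (sparse-event regime).

## Triplet co-evolution encoding

The joint state of (*der*, *rplA*, H78) is packed into 3 bits with *der*
as the most significant bit — state 7 = all present, state 6 = H78 lost,
etc. — matching the axis order used throughout the package. Genomes
without an H78 call are excluded and counted. Class-level summaries
report the proportion of each state within each taxonomic class (rows
sum to 1). Ancestral triplet states come from three independent Fitch
runs (one per bit); the trajectory graph then records every
parent→child state change along the tree, annotated with the clade
(classes below the changing branch), and a clade-restricted view
extracts the transition sequence into and within a named clade set.
Pairwise MI between the three bit columns quantifies which pair
co-evolves most tightly.

## rRNA helix metrics

Helix coordinates live in a CRW-style table: per helix, the 5′ and 3′
strand segments in 1-based inclusive reference numbering. A designated
reference row in the alignment is walked once to map reference positions
to alignment columns; helix coordinates beyond the reference's ungapped
length raise an error naming the helix. A sequence's **helix length** is
its non-gap base count across both segments (gap symbols `.`, `-`, `~`).
Lowercase residues (insert states in covariance-model alignments) count
toward length but are excluded from the **stem estimate**
`min(5′ aligned bases, 3′ aligned bases)` — insert columns are not
aligned to the consensus structure, and in these genomes frequently
correspond to intronic insertions absent from the mature rRNA. The stem
estimate is a deterministic sequence-level stand-in for the paired stem
length of the consensus structure; no re-folding is attempted.

**Shortening** is called per (class, helix) when the class median length
is at least `min_reduction` (default 1) bases below the seed length,
where seed lengths come from designated seed/reference rows. **H78
classification** is absent (stem < 2), short stem (2–3 bp), mid stem
(6–8 bp) or full (≥ seed stem − 1); stems falling between bands (4–5 bp,
or between 8 and the full bound) get the nearest label and an
`ambiguous` flag, so the classification is total. Presence calls for
the triplet analysis are simply `class != absent`.

The packaged default helix table has the correct per-molecule helix
counts (50 for 16S, 5 for 5S, 100 for 23S) with synthetic sequential
arm/loop geometry (10/4/10 for 16S and 23S, 6/4/6 for 5S) inside
realistic molecule lengths (1542/120/2904 nt). It is a geometry
stand-in, clearly not real CRW coordinates; real-mode users supply their
own table.

## Synthetic data generator

The generator produces every input format the pipeline reads, with
planted structure returned as truth labels.

**Matrices.** Each genome's gene bits are independent Bernoulli draws at
per-gene retention probabilities (class overrides applied first, e.g.
knockouts at 0.02 rather than exactly 0, to mimic annotation noise).
Planted dependencies use a **copy-mixture**: with probability *s* (the
coupling strength) the dependent gene copies the driver's bit, otherwise
it draws independently. The model is analytically tractable — marginals
and MI are closed-form — which is what the calibration and the
monotonicity tests (higher strength ⇒ higher MI) rely on.

**The `paper_like_cpr` preset** encodes the study conditions: 505
genomes over eight taxonomic classes (the three largest with 85–118
genomes), class-specific knockouts of *der* (4 classes), *obgE* (1),
*era* (6), *rbfA* (5), *rplA*/*rplI* (1 each) and clade-wide loss of
bL30, five planted co-varying pairs (strength 0.95, including the
groEL–groES chaperonin pair), and *der* coupled to five partner genes at
strength 0.85. Retention tiers were calibrated analytically from the
copy-mixture model, before any empirical tuning, so that (i) the median
RBF count per genome is ≈25, (ii) overall *der*/*obgE* conservation is
≈0.38/0.60, and (iii) within retaining classes *der* is near-fixed
(0.995) — the last so that the planted class contrast sits several
binomial standard deviations away from the 10%/90% classification bounds
at every class size, keeping the qualitative pattern detectable rather
than threshold-straddling. Smaller presets isolate single questions:
`planted_pairs` (five pairs on an independent background),
`hub_der` (a six-partner hub), `fig4_triplet` (per-class modal triplet
patterns at fidelity 0.95) and `helix_fig4b` (H78 deleted in three
classes, trimmed to 3 bp and 6 bp stems in two others).

**Trees** are random rooted binary topologies with exponential branch
lengths; classes are generated as separate subtrees joined on a random
backbone, so class monophyly holds by construction (mirroring the
class-level structure of the real phylogeny). **Histories** are
two-state Markov walks along branches with state-dependent gain/loss
probabilities, returning the true event list as a parsimony oracle.
**Alignments** copy an ungapped random reference and plant deletions as
gaps at the loop-proximal ends of helix arms, so expected lengths and
stems are exact arithmetic.

All generators are deterministic under a fixed seed (verified
byte-identically in tests).

What the generator does **not** emulate: sequence-level evolution,
annotation error beyond the symmetric retention noise, genome
completeness artifacts, horizontal transfer, or correlated loss beyond
the planted couplings. Passing tests therefore demonstrate that the
estimators and reconstructions recover planted structure under the
declared statistical model — not that real data satisfy that model.

## Numerical and scale choices

* MI clipping tolerance 1e−12; proportions checked to 1e−12.
* The brute-force oracles run exhaustively where cheap: all 2×2 tables
  with n ≤ 12 (1,819 tables) and all internal labelings of trees with
  ≤ 10 leaves (200 random trees), sizes at which exhaustive enumeration
  is exact and fast.
* Simulation-based checks (planted-network recovery, hub recovery,
  preset patterns) run at the full 505-genome preset scale with fixed
  seeds; the acceptance script re-runs them at the caller's seed.

## Known limitations

* Catalogue membership beyond the explicitly named genes is
  reconstruction, not curation; swap in a curated TSV for real analyses.
* Presence calls ignore gene fragmentation and completeness.
* The H78 stem estimate cannot see compensatory pairing changes; it is
  a length proxy, which is exactly what the class-level comparisons use.
* Fitch parsimony reports one most-parsimonious history; alternative
  resolutions exist whenever nodes are flagged ambiguous, and
  likelihood-based reconstruction is out of scope.
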