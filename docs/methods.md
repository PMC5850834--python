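# Methods

## Pipeline model

`ogmap` annotates query proteins by orthology rather than plain homology.
The database is a set of orthologous groups (OGs): clade-scoped gene
families, each carrying a rooted gene tree over its member proteins and
per-member functional annotations. Annotation of one query proceeds in four
stages.

**1. Seed search.** The query is matched to its closest database protein
(the seed ortholog) either *directly* against all proteins, or *coarse then
fine*: first against whole groups (group score = max member bit-score, a
desk-scale stand-in for a profile-HMM match), then re-ranking only the best
group's members. The built-in scorer is Smith–Waterman local alignment
(BLOSUM62, affine gaps, open 11 applied to the first gap residue and extend
1 thereafter), mapped to bit-scores via the Karlin–Altschul transform
$(\lambda S - \ln K)/\ln 2$ with the standard ungapped constants
$\lambda = 0.267$, $K = 0.041$. E-values use effective search space
= query length × total database residues (direct mode) or × group residues
(fine phase); this is a documented convention, not a fit. The built-in
scorer reports the full query extent as the alignment span; exact
coordinates are available when hits come from external engines instead
(HMMER3 `--domtblout` or BLAST/DIAMOND tabular format-6 parsers). Ties
break by lower E-value, then lexicographically smallest protein id, making
seed selection a total order independent of input order. Default filters:
E-value ≤ 1e-3, bit-score ≥ 20; excluded taxa are expanded to their whole
subtree; self-hits can be removed to prevent circular annotation.

**2. Gene-tree orthology.** Internal nodes of the OG's gene tree are
labeled by species overlap: with child species sets $S_1, S_2$, a node is
a duplication iff the Jaccard index $|S_1 \cap S_2|/|S_1 \cup S_2|$
strictly exceeds the threshold (default 0, the strictest parameter-free
reading: any shared species implies duplication). Multifurcations are
duplications if any child pair overlaps. Raising the threshold can only
turn duplications into speciations (monotonicity). Input trees must be
rooted; unrooted input is rejected rather than silently midpoint-rooted,
because event labels are root-dependent. A leaf of another species is an
ortholog of the seed iff their LCA is a speciation; relation types count
leaves of the two relevant species in the LCA's two child subtrees.
Same-species leaves whose LCA with the seed is a duplication are its
in-paralogs.

**3. Scope resolution.** In `auto` mode the donor OG is taken at the
narrowest clade level that lies on the seed species' lineage and hosts an
OG containing the seed, falling back level by level to the root. This is
the simplest mechanism that restricts transfer to the taxonomically
closest orthologs while guaranteeing a fallback; a `fixed` scope (e.g. the
root level) disables the adjustment, which is what the evaluation setup
uses when comparing against unscoped homology transfer. Orthology is
computed on the gene tree of the OG *at the resolved scope*, so in-paralog
exclusion sees exactly the taxa the transfer will use.

**4. Transfer.** The donor set is the seed, the seed's orthologs, and the
seed's in-paralogs. Including the in-paralogs is deliberate: the query
reached the seed from outside the seed's species, so it is an outgroup to
the seed's local duplication cluster and the seed's same-species
co-descendants are co-orthologs of the query (tagged `one2many`), not
paralogs of it. Donors are filtered to the scope subtree, minus excluded
taxa; the `one2one` policy additionally keeps only one2one orthologs (plus
the seed itself, the query's own best match). GO terms pass an evidence
filter (experimental = {EXP, IDA, IPI, IMP, IGI, IEP}; non-electronic =
everything but IEA; or all), then are closed over is_a and part_of
ancestors — `regulates`-style relations do not propagate, matching
standard GO annotation practice. KEGG transfer is the union over donors;
the COG category is the group-level annotation, so it is reported even for
seed-only results. Gene-name prediction normalizes donor names (case-fold,
strip trailing copy-number digits and separators: `trpB2` → `TRPB`) and
returns the majority name, breaking ties toward the donor taxonomically
closest to the seed, then lexicographically. The normalization rule is this
package's own convention.

These choices guarantee the policy monotonicities the test suite asserts:
one2one transfers ⊆ all-ortholog transfers, experimental ⊆ non-electronic
⊆ all evidence, and narrowing scope never adds donors.

## Evaluation framework

Predictions are scored per (protein, term): **TP** if the term is in the
protein's ancestor-closed experimentally supported set; otherwise **FP** if
it violates a curated taxon constraint for the protein's taxon
(`never_in_taxon` X — violated by any species inside X; `only_in_taxon` X —
violated by any species outside; constraints inherit down the term DAG,
since predicting a child entails the constrained ancestor); otherwise
**uncertain**. The gold sets are ancestor-closed by default (a raw-gold
mode exists) so that predicting an entailed parent of a curated term is not
penalized as uncertain. The strict TP-ratio divides TP by *all* assignments
including uncertain ones; the TP:(TP+FP) proportion ignores uncertain
terms; per-proteome coverage splits into proteins with only-TP, mixed, and
no-TP assignments (the three fractions sum to coverage). Ratios over an
empty denominator are reported as undefined (`None`/NA), never as zero.

$F_{\max}$ is protein-centric, partial mode: at each threshold
$t \in \{0.01, \dots, 1.00\}$ precision is averaged over proteins
predicting at least one term at $t$ (proteins with empty gold may
contribute to precision; proteins predicting nothing do not), recall is
averaged over all benchmark proteins with non-empty gold, and
$F(t) = 2pr/(p+r)$ (0 where $p + r = 0$). Unscored predictions are given
score 1.0 and collapse to a single operating point. The 0.01 grid follows
community convention; the test suite checks agreement with a 0.001-grid
brute-force sweep.

Functional profiles map each GO term to the summed abundance of genes
annotated with it. Profiles are compared by tie-corrected Spearman
correlation over the **union** of the two key sets (a term absent from one
profile contributes 0 there); at least 3 terms are required, constant
vectors yield an undefined (NaN) correlation, and the p-value uses the
large-sample t approximation (an exact permutation test is used by default
for n ≤ 10).

## Synthetic study conditions

The simulator provides everything the pipeline consumes, with recorded
ground truth. Defaults were chosen once as a small but structured clade and
are the conditions under which the package's figures are computed:

| parameter | default | rationale |
|---|---|---|
| species / branching | 20, 2–3 children | deep enough for three nested clade levels |
| gene families | 40 | ~1000 proteins, minutes-scale end-to-end runs |
| duplication rate | 0.1 per lineage per branch | visible paralogy without degenerate trees |
| loss rate | 0.05 | makes species-overlap labeling fallible, as in real trees |
| sequence length / substitution | 150 aa, 0.05 per site per branch | clear homology signal, non-trivial divergence |
| GO DAG | 60 terms, 30% double-parent | diamonds exercise set-semantics of closure |
| annotation gain/loss | 0.05 / 0.05 per branch | functional divergence between orthologs |
| model organisms | 30% of species, P(experimental) = 0.8 vs 0.1 | skewed curation mirrors real databases |

Gene trees evolve along the species tree (each lineage on each branch is
lost or duplicated, duplications may cascade); every internal node's true
event is recorded, and true ortholog pairs with relation types are derived
from those labels by naive enumeration, independently of the inference
module. Sequences evolve by per-site substitution; annotations evolve by
per-branch term gain/loss from a family root set; evidence codes are drawn
per (protein, term). Taxon constraints are derived from the generated
annotations so they hold by construction (a `never_in` clade contains no
carrier of the term or its descendants). Metagenomic samples draw
log-normal species abundances and Poisson per-gene read counts; the gold
profile counts reads from genes truly annotated with each term. Identical
configurations (including seed) produce byte-identical bundles; all tables
are written sorted.

What the generator does **not** emulate: indels and rate heterogeneity (so
sequence search is easier than in real proteomes), gene conversion and
horizontal transfer, incomplete or erroneous database trees, annotation
errors in the "experimental" gold standard, and read-level sequencing noise
(abundances are simulated at the gene level, not from FASTQ). Passing tests
therefore establish the correctness of the algorithms under their stated
models — exact event recovery without loss, exact transfer given the right
seed — not field performance on real data.

## Verification design

The loss-free regime (duplications only) is the exactness oracle: there,
species-overlap labels equal the true events, so inferred ortholog pairs
must match ground truth perfectly, and the suite asserts precision = recall
= 1 over 200 families. Under loss the labeling is fallible by design; the
suite quantifies but does not assert recovery there. Orthology inference is
also checked exhaustively against a brute-force reimplementation on every
rooted binary tree with ≤ 6 leaves over 3 species (~1,900 trees). The
end-to-end check simulates a loss-free bundle, holds out one well-curated
species (its taxon excluded from search and transfer, mirroring benchmark
practice of evaluating on species with substantial experimental
annotation and preventing self-annotation), and requires the transferred GO
sets to equal an independent walk of the simulator's recorded histories;
residual disagreements must be reproducible from the seed-relative walk,
pinning them on seed choice rather than transfer logic. DAG closure is
verified against boolean-matrix reachability; F-max against a finer-grid
sweep; Spearman against rank-then-Pearson.

`scripts/acceptance.py` recomputes all of this from scratch at those
problem sizes (200 loss-free families; a 20-species, 40-family bundle with
one held-out proteome; a 25-family bundle for the metagenomic sample) —
sizes chosen as the package's standard desk-scale conditions — and writes
each figure with the problem size it was measured on.

## Known limitations

* The coarse search phase scores groups by their best member, not a true
  profile HMM; sensitivity claims about profile search do not transfer.
  External domtblout input restores real HMM scoring.
* The species-overlap threshold is a convention (default 0); no attempt is
  made to learn it, and no gene/species-tree reconciliation with losses is
  performed.
* E-value statistics use fixed ungapped Karlin–Altschul constants; absolute
  E-values are internally consistent but not comparable to BLAST/HMMER
  output.
* The taxonomy is static: no merged/deleted taxid handling, no download
  synchronization. Real GO releases can be loaded from OBO 1.2, but taxon
  constraints must be supplied as the package's TSV format.
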