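# Methods

This note records the models implemented in `pangenet`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Ortholog clustering

Pairwise protein comparison uses Smith–Waterman local alignment with
BLOSUM62 and affine gap penalties (open 11, extend 1 — the standard protein
defaults; configurable via `ScoringConfig`).  Percent identity is identical
residue pairs over aligned non-gap columns, and query coverage is the
aligned query span over the query length, matching the BLAST-style
conventions most pangenome pipelines report.  Hits must reach ≥75% identity
and ≥75% coverage (both configurable); coverage is evaluated with respect to
each query, so the filter is directional while reciprocity is not.

`best_hits` scores *all* gene pairs between two genomes (score-only dynamic
programming) and performs tracebacks only for top-ranked candidates until a
passing hit is found; score ties break by higher identity, then
lexicographically smaller gene id, making results order-independent.  No
heuristic prefilter is applied: at the collection sizes this library targets
(tens of genomes × hundreds of genes) exhaustive scoring is fast, and it
keeps the implementation exactly equivalent to the brute-force definition.

BDBH seeds one cluster per reference gene (the first genome of the
collection by default) and admits at most one member per genome — the
variant suited to single-copy core curves.  COG-triangles computes
reciprocal best hits for all genome pairs, finds triangles of mutually
reciprocal genes (necessarily spanning three genomes, since reciprocal
edges never join genes of the same genome), and merges triangles sharing an
edge via union-find; reciprocal pairs in no triangle are reported
separately rather than promoted to clusters.  Paralog expansion is out of
scope: only each gene's single best hit is considered.

## Rarefaction and saturation curves

Rarefaction adds genomes in random order; core size at step *n* is the
number of families present in all *n* genomes sampled so far, pan size the
number present in at least one.  Ten permutations are the default.  Curves
are fitted to the per-*n* **means** across permutations (not the pooled
cloud of points): the mean curve is what the classic regression figures
show, and it stabilises the nonlinear fit.  Initial guesses are
scale-aware — Ω₀ = final mean core, κ₀ = first-point excess, τ₀ = G/3 — and
make the exponential fit converge on every profile we have encountered;
noiseless model data are recovered to ≲1e-9 relative error.  A perfectly
constant core short-circuits to κ = 0, Ω = constant (the optimizer cannot
identify τ there).  Both pan models are offered; Heaps' law is the default
because its single exponent γ is the conventional open/closed summary.

## Habitat gene sets

Habitats need ≥3 genomes to define a core (override available); genomes
without habitat metadata are excluded from the grouping but retained in the
matrix.  Habitat-specific sets default to *core-vs-core* subtraction (a
habitat's core minus the union of the other habitats' cores); a *strict*
mode subtracts all gene content of the other habitats' genomes.  Both are
kept because published practice is ambiguous between them; strict sets are
provably subsets of core-mode sets.  Cloud content counts the habitats a
family's genome incidence spans and keeps families spanning ≤2.  Pathway
screens are deliberately annotation-level: exact, case-insensitive gene
symbol matching against required-gene lists.  Sequence-based gene calling
is out of scope, so the screen's fidelity is bounded by the annotations
supplied.

## Distances and trees

Fragment ANI chops the query genome into consecutive 1,020 bp fragments
(trailing fragments under 100 bp are dropped), aligns each fragment and its
reverse complement locally against the subject (+1/−1 nucleotide scoring,
gap open −2, extend −1 — extension chosen mild so a single indel does not
split a fragment alignment), and averages the identity of fragments passing
≥30% identity and ≥70% coverage.  The two directions are averaged because
fragmenting is not symmetric; a pair with no passing fragment is reported
as missing, never as 0.  Ortholog ANI instead averages global-alignment
identity over single-copy core genes shared by a pair.

Correlation dendrograms cluster row profiles on `1 − Pearson r` with
average linkage (the era-typical default for expression-style matrices;
complete/single exposed).  Constant rows have undefined correlation and
raise an error naming the offending row.  The returned tree assigns each
child a branch length of (parent merge height − child merge height), so
cophenetic merge heights are preserved and tip-to-tip paths equal twice the
merge height for ultrametric inputs.

Poisson-corrected distances use complete deletion (columns containing a gap
in any sequence are removed), `p` = fraction of differing retained sites,
`d = −ln(1 − p)` via `log1p` for numerical accuracy at small `p`.
Saturated pairs (`p = 1`) get infinite distance and are refused by the NJ
stage with an explicit pair list.  Neighbor joining is canonical
Saitou–Nei; additive matrices are reproduced exactly (verified by
path-length oracle).  Bootstrap support resamples alignment columns with
replacement; replicates whose resampled distances saturate carry no usable
signal and are skipped, with support percentages computed over the usable
replicates.  The default of 1,000 replicates is scaled to ≤100 in tests and
examples for runtime.

## Network topology

The three profiles are computed from first principles on adjacency sets:
`P(k) = n_k/N`; node clustering `2E/[k(k−1)]` (nodes of degree <2 excluded,
having no defined coefficient) averaged per degree class; and neighborhood
connectivity as the per-node mean neighbor degree averaged per degree class
(isolated nodes skipped with a warning).  Tests pin all three to O(N³)
brute-force oracles and to the corresponding networkx functions.

Power-law order parameters come from ordinary least squares on
(log₁₀ x, log₁₀ y) over raw (non-binned) degree classes, reporting
exponent = −slope and r² — the regression form consistent with reporting a
Pearson r² per profile.  Zero-valued points are excluded (log undefined)
and counted.  A constant profile is reported as exponent 0 with r² = 1 (the
horizontal fit is exact).  Classification: hierarchical iff γ < 2 and β > 0
and α > 0; assortative iff α < 0; scale-free non-hierarchical iff γ ≥ 2
with |β| < 0.1; otherwise inconclusive, always with a rationale listing the
exponents seen.  Hubs default to degree strictly greater than mean + 2
population SDs (a regular graph has no hubs); a top-N rule is offered
because published hub lists often name a fixed number per network.

## Synthetic data

The generator plants: a universal core (every genome), habitat-private
cores (every genome of one habitat), and cloud families carried
independently with a fixed probability.  Family members are mutated copies
of a random ancestor protein; substitutions are chosen without replacement,
uniformly over the 19 alternative residues, with **no indels**, so realized
identities are analytically exact.  Each member diverges from the ancestor
at *half* the target divergence so that the expected **pairwise** identity
between members equals `within_family_identity` — mutating every member at
the full rate would compound to roughly the square of the target.  The
default target of 90% is a fixture choice giving families that are
unambiguous at 75/75 thresholds yet far from trivial; no claim about real
ortholog divergence is intended.  Gene lengths are uniform on the
configured range (default 120–300 residues, typical bacterial protein
scale).

Graphs: preferential attachment (Barabási–Albert) for connected scale-free
fixtures, and a deterministic Ravasz-style hierarchical-modular
construction (clique modules replicated per level, copy peripheries wired
to the original hub; `module_size^levels` nodes) whose C(k) ~ k⁻¹ signature
is reproducible because the seed only permutes node labels.  Trait matrices
plant contiguous genome blocks sharing random non-constant, pairwise
non-collinear profiles, with independent cell-flip noise.

What the generator does **not** emulate: nucleotide-level evolution
(indels, rearrangement, HGT, phage integration), genome-size or GC
variation tied to habitat, interaction-confidence scores, or any
correlation between protein divergence and network structure.  Passing
tests therefore demonstrate algorithmic correctness against planted truth,
not performance on real assemblies, where annotation noise, paralogy and
contamination dominate.

Everything is deterministic under seeds: identical seed + design reproduce
collections, graphs, matrices and rarefaction orderings bit-exactly.

## Bundled strain table

`pangenet.datasets` ships published characteristics of 27 *Novosphingobium*
strains (size, GC, gene count, accession) with habitat labels for the 19
strains whose isolation sites have ≥3 representatives (rhizosphere 3,
contaminated soil 5, freshwater 6, marine 5).  Group SDs are reported with
the sample (n−1) convention; note that published ±values for such tables
sometimes mix conventions, so only means should be compared across sources.
The freshwater mean genome size computes to 4.19 Mbp from the table at
two decimals.

## Problem sizes

Defaults in tests, examples and the acceptance script are sized for
interactive runs: orthology recovery uses 5 genomes × 60 families (~300
genes, exhaustive all-pairs alignment), rarefaction 15 genomes × 85
families × 10 permutations, ANI fixtures 3–4 kb genomes, network fits
graphs of 10³–2·10³ nodes, and bootstrap 50–100 replicates.  All scale
linearly (quadratically in gene count for orthology) if larger studies are
needed.
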