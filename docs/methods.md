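# Methods

This note documents the models, numerical procedures and design choices
behind `seclipid`, and what the synthetic-data generators do and do not
emulate.

## Data model and the packaged catalog

A gene cluster is an ordered list of genes, each an ordered list of typed
domains drawn from the iterative type I FAS/PKS vocabulary: KS (ketoacyl
synthase), MAT (malonyl-CoA:ACP transacylase), AT (acyltransferase), ACP
(acyl carrier protein), KR (ketoacyl reductase), DH (dehydratase/isomerase,
modelled as a single kind), ER (enoyl reductase), CLF (chain length factor)
and PPTase (phosphopantetheinyl transferase). Gene boundaries are preserved
in the model — Type definitions (split *pfaA*, fused *pfaBC*) depend on
them — but ignored when an architecture is encoded or compared, because the
chemical product is determined by domain content and order rather than by
operon layout.

The packaged catalog records the 20 cluster Types A–T: 86 distinct genomes
across 45 genera, with the two heterocystous cyanobacteria that carry both
a Type F and a Type G cluster appearing under both Types but counting once
as genomes. Template architectures stated in running text (Types A, B, C,
D, E, F, H, I, J, K, L, R) are marked `fully_specified`; the remaining
eight Types are depicted only graphically in the original survey, so their
packaged templates are this package's own reconstructions and are
deliberately chosen to be token-distinct from every fully specified
template (and from their single-deletion images) so that the catalog stays
identifiable; users can override them through the catalog files. ACP
copy-number ranges not stated anywhere are package choices in the 1–5
range typical of tandem-ACP regions.

## Letter coding and architecture similarity

Domains are letter coded with a fixed global alphabet: KS=A, MAT=B, ACP=C,
KR=D, ER=E, PPTase=F (forced by the worked example
KS-MAT-ACP₂-KR-ER-PPTase → `ABCCDEF`), then AT=G, CLF=H, DH=I by first
appearance in the canonical Type A architecture. The coding is injective
whenever the letter map is.

Architectures are aligned by exact global Needleman–Wunsch on domain
tokens with match +1, mismatch −1, gap −1 and a deterministic traceback
(diagonal, then gap-in-second, then gap-in-first). An exact aligner was
chosen over a heuristic multiple-sequence aligner because the token
sequences are short (≤ ~20 tokens) and exactness makes the distances
reproducible and order-invariant. The dissimilarity is
`d = 1 − n_matches/alignment_length`, which is symmetric, lies in [0, 1]
and is zero exactly for identical token sequences.

Two comparison modes exist. *Raw* mode uses every domain (the mode used for
ordination, where total domain count is informative). *Collapsed* mode
replaces each maximal tandem-ACP run with a single token, making the
comparison insensitive to ACP copy number (the mode used for Type
assignment, since copy number varies within a Type).

### Type assignment

`assign_type` returns the Type whose template minimises the collapsed-mode
distance; ties break alphabetically, and a best distance above the
threshold (default 0.2) is reported as "novel" with a warning. When a
cluster's collapsed ACP run is compared with a template's ACP token, the
run is compatible whenever it does not exceed the template's copy-number
maximum: any run inside the template's [min, max] matches, and runs below
the minimum are also accepted because tandem runs are commonly fragmented
or partially lost (a sub-minimum run is weak evidence against a Type,
whereas a run above the maximum is diagnostic). Enforcing the lower bound
strictly would charge a single internal substitution several mismatches
and misclassify lightly perturbed clusters wholesale.

Two confusions are intrinsic to the catalog and worth knowing about: the
Type B architecture is exactly Type A plus one KS (so deleting that KS
from a B cluster produces a literal Type A architecture), and Type I is
close to Type A minus its free-standing AT gene. The parameter-recovery
simulations reflect this: at per-entry perturbation 0.05 the expected
recovery rate is ≈ 95–96%, with the residual dominated by such
single-step adjacencies and by double perturbations of the shortest
templates (R has only six architecture entries, so two events already
produce distance 1/3).

## Non-metric MDS

The NMDS minimises Kruskal's stress-1,
`sqrt(Σ(d̂ᵢⱼ − d*ᵢⱼ)² / Σ d*ᵢⱼ²)`, where d̂ are configuration distances
and d* the disparities obtained by isotonic regression of d̂ on the rank
order of the input dissimilarities (primary treatment of ties via stable
sorting). Each iteration rescales the disparities to the configuration
norm and applies a Guttman transform; iteration stops when stress falls
below the minimum-stress floor (default 0.01, matching common ordination
software defaults), when the relative stress change drops below 1e-6, or
at 300 iterations. The reported solution is the best of 25 random starts
whose seeds derive from the master seed and the start index *after sorting
labels canonically*, so results are bit-reproducible and invariant to
input order. Stress is non-increasing across iterations within a start
(checked by test).

## Average linkage and dendrograms

UPGMA clustering delegates to `scipy.cluster.hierarchy.linkage(method=
"average")` and is verified against a naive O(n³) oracle on small
instances. Dendrograms serialise to newick with branch lengths equal to
differences of merge heights, giving an ultrametric tree with leaves at
height zero; cutting at a height (or at a group count) yields the Type
overlay groups.

## PPTase motif classification

Motifs are position patterns over {hydrophobic `h`, wildcard `x`,
literal/alternation}: P0 `hRxhLS` (6), P1a `x(G/D)xP` (4), P1b `(F/S)NxSH`
(5) for PUFA-type PPTases and P1b′ `hShxH` (5) for PKS/NRPS-type PPTases.
P1a′ is named in the source material but no generalised pattern is printed
for it, so it is not part of the default motif set; the classification
rule needs only P1a, P1b and P1b′. The hydrophobic set defaults to
{G, A, V, L, I, M, F, W, Y, C}: L, V, G and I are forced by the motif
generalisations themselves, and the rest follow the standard
hydrophobicity grouping; the set is configurable, and widening it can only
add hits (tested monotonicity). Scanning reports every (possibly
overlapping) window satisfying the pattern; an `X` residue matches only
the wildcard. Classification: PUFA-like requires a P1a hit followed by a
P1b hit (order optional via a flag); PKS/NRPS-like requires P1b′ and no
P1b; everything else is ambiguous. A sequence with both P1b and P1b′ is
called PUFA-like and flagged in the output note. P0 is reported separately
and never required, since the phenolic-lipid (Type P) PPTase lacks it.

## Trait statistics

Bray–Curtis dissimilarity on binary trait vectors feeds both tests; a pair
of all-zero organisms is undefined and rejected. PERMANOVA partitions
`SS_T = (1/N)Σᵢ<ⱼ d²ᵢⱼ` into within- and among-group components and forms
`pseudo-F = (SS_A/(g−1))/(SS_W/(N−g))`; on univariate Euclidean data this
equals the classical one-way ANOVA F (property-tested to 1e-9, and
cross-checked against scikit-bio's implementation). "Unrestricted
permutation of the raw data" is implemented as permutation of group labels
over observations, which is equivalent for one-way designs. Monte-Carlo
p-values use the (1+count)/(1+B) estimator so p is never zero; an
exhaustive mode enumerates all distinct label arrangements (identity
included) and reports count/total. Zero within-group sum of squares yields
pseudo-F = +∞. Pairwise tests report raw p-values without multiplicity
correction (a Holm adjustment can be applied downstream); p-values at the
permutation resolution are flagged. Formal tests are gated at n ≥ 5 per
group by `TraitMatrix.filter_by_group_size`, the default in the pipeline.

CAP performs PCoA via Gower double-centering of −½d², discards negative
eigenvalues without correction (their count and mass are recorded in the
result metadata), and relates the first m orthonormalised axes to the
centred group-indicator matrix; the eigenvalues of Q′HQ on the
orthonormalised axes are squared canonical correlations, computed with a
pseudo-inverse so singular indicator cross-products degrade gracefully.
Leave-one-out allocation refits the PCoA without each observation, places
it by Gower's projection formula, and allocates it to the nearest group
centroid in canonical coordinates; allocation success is the percentage
correct, with chance level 100/g %. `m="auto"` maximises LOO success over
1..(N−g) (smallest m on ties); because this optimises the reported
success, it is optimistic under the null, so null-calibration checks use a
fixed m. The permutation test permutes labels and compares the sum of
squared canonical correlations. Trait biplot tables report Spearman ρ of
each trait against each canonical axis, filtered at |ρ| ≥ 0.4; constant
traits are omitted with a warning.

## GC composition

GC fraction is (#G + #C)/#unambiguous bases, case-insensitive, with N and
IUPAC ambiguity codes excluded from numerator and denominator entirely
(excluding them fractionally would add complexity without changing any
conclusion at genomic lengths). The region-versus-background report carries
no significance statement: composition alone does not establish horizontal
transfer.

## Synthetic-data generators

All generators are fully determined by a seed (sub-seeds derive from
`numpy.random.SeedSequence`) and emit the same file dialects the readers
consume.

* **Clusters** derive from a Type template; each architecture entry (one
  domain, or one tandem-ACP run) is independently deleted or substituted
  with probability `perturb_p` (50/50 split), and surviving ACP entries
  expand to a run drawn uniformly from the template's copy-number range.
  The perturbation acts on architecture entries rather than expanded
  domain copies: presence/absence of a functional domain varies at the
  architecture level, while tandem-ACP copy number is modelled by the
  run-length draw.
* **PPTases** are uniform-composition random proteins (length 300 by
  default) whose background is rejection-resampled until free of all four
  motifs, after which sampled motif instances are planted in the required
  order at evenly spread positions; planted positions are returned as
  ground truth. Uniform composition maximises rejection efficiency and
  needs no external frequency table.
* **Trait matrices** give each trait, with probability θ, group-specific
  Bernoulli rates drawn from {0.1, 0.9}; otherwise a common rate 0.5.
  θ = 0 is the null, θ = 1 maximally informative. All-zero organism rows
  are resampled so Bray–Curtis stays defined. 33 traits and group sizes of
  5–10 mirror the scale of the original life-history analysis.
* **Genomes** are i.i.d. base draws at a target GC (default scenario: a
  20 kb cluster at 46% GC planted centrally in a 100 kb genome at 39% GC,
  mirroring the reported aberrant-composition case), with 1-based
  inclusive coordinates as ground truth.

What the generators do *not* emulate: phylogenetic correlation among
organisms, annotation noise in domain boundaries, sequence-level evolution
of domains, trait correlation structure, and genomic context (flanking
genes, operon strandedness). Passing the calibration and recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated generative assumptions, not performance on real annotation
pipelines.

## Problem sizes and numerical choices

Default test and acceptance problem sizes — 204 clusters for recovery, 50
replicates of 70 organisms for CAP null calibration, 200 simulations for
p-value calibration, 8-point configurations for NMDS — were chosen as the
smallest sizes at which the binomial/Monte-Carlo noise is comfortably
inside the asserted tolerances. Distance-matrix symmetry is validated at
1e-12; PCoA eigenvalues are considered positive above a 1e-9 relative
threshold; permutation comparisons use a 1e-12 slack so exact ties count
as exceedances. Everything stochastic flows from one master seed.

## Known limitations

* The original MOTHUR/Primer distance on MAFFT-aligned letter strings is
  unspecified in the source material; the exact-alignment distance here is
  a recorded substitute, so absolute distances (and any fixed cut height)
  are not comparable with the original analysis, though the induced
  grouping of distinct architectures is.
* Fig-only Type templates are reconstructions; classifications against
  Types G, M, N, O, P, Q, S, T should be treated as provisional unless the
  user supplies curated templates.
* CAP's auto-m is optimistic under the null by construction; report m and
  prefer fixed m when comparing allocation success against chance.
* The 33-trait matrix of the original survey is unpublished; trait-space
  results here are validated on synthetic matrices only.
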