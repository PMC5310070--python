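# Methods

This note documents the models, conventions and numerical choices behind
`mhcrep`, in the order the pipeline runs.

## The data-generating model (simlib)

The simulator emulates a replicated clone-and-Sanger survey of a multigene
MHC class IIB family and is the package's primary validation instrument:
every filter downstream is tested against its ground truth.

**Repertoire.** A random in-frame ancestral coding sequence (default 552 bp
= 184 codons, laid out as 91 β1-like + 93 β2-like codons, matching the
exon-2/exon-3 amplicon the calling stage targets) is diversified into locus
founders at `locus_divergence` (default 0.15 substitutions/site) and
within-locus alleles at `allele_divergence` (0.03).  Mutations are proposed
per site with transition:transversion weight κ (default 2, which makes the
K2P distance the simulator's natural metric) and accepted with probability
min(1, ω) if nonsynonymous and min(1, 1/ω) if synonymous, so the realised
nonsynonymous/synonymous rate ratio tracks ω.

**Locus classes.** Loci are split deterministically into
*nonclassical* (fraction 1 − `expressed_fraction`, default 30%),
*pseudogene* (`pseudogene_fraction`, 10%, premature in-frame stop), and
*classical* (the rest).  Classical loci evolve with ω = 3 at PBR-like
codons (every 4th codon of the β1 region — roughly the density of
peptide-contact residues) over a purifying ω = 0.3 background; founder
(between-locus) divergence uses a net `framework_omega` = 0.7, the mildly
purifying regime typical of functional MHC framework regions.
Nonclassical loci descend from a single recent class founder with
strictly nonsynonymous (ω = ∞), very low divergence — reproducing the
empirical signature of a non-classical group: one tight cluster, gDNA-only,
essentially zero d_S.  Pseudogene and nonclassical loci are absent from
cDNA.

**Individuals.** Each of 13 individuals draws two alleles per locus
(uniformly from the locus pool; homozygosity allowed).  Locus recovery is
heterogeneous: a per-individual retention rate is drawn from
Beta(3r, 3(1−r)) with mean `locus_retention` = 0.6 and each locus is kept
with that probability.  This models the strong between-individual variation
in amplification success seen in real surveys (template quality,
primer-allele mismatch, intron-length failures) and is what spreads
per-individual allele counts widely (means ~12–15, SDs ~5–6, maxima ~20+
under the defaults) — without dropout, a 13-locus diploid could never
average ~12.5 distinct alleles.  cDNA libraries exist for the first 7
individuals (`n_cdna_individuals`), as in the survey design the package
mirrors.

**Libraries.** Per individual × template × replicate (2 replicates,
`depth_per_replicate` = 24 clones), template sampling weights are drawn
once per individual × replicate from a symmetric Dirichlet (concentration
1.0) scaled by germline copy number.  Each clone is a faithful copy with
iid per-base errors (default 5·10⁻⁴, a Sanger-consensus-scale rate), or
with probability `chimera_rate` (0.03) a single-breakpoint concatenation of
two distinct templates of the same reaction.  A chimeric sequence is never
allowed to recur in any other PCR product (redrawn if it would); this
enforces by construction the single-reaction property the downstream filter
assumes, which in real data holds because independent reactions essentially
never produce the identical recombinant.  Randomness is split into named
substreams keyed on (seed, stage, individual, replicate), so adding an
individual perturbs nobody else and a fixed seed is byte-reproducible.

**What the simulator does not model** — and hence what passing tests do not
show about real data: chromatogram-level miscalls and quality variation
(errors are iid substitutions), indels inside exons, heteroduplex and
multi-breakpoint chimeras, primer-sequence bias tied to actual primer
binding sites, alternative splicing, and locus-specific copy-number
variation beyond simple presence/absence.

## Allele calling

Exact identity plus replication, no probabilistic denoising.  Reads
collapse when identical (a shorter read merges into a longer one iff it is
its exact prefix, the shared-5'-anchor case; an ambiguous shorter read goes
to the better-supported variant, ties by sequence order).  The chimera
rule flags a variant iff it occurs in exactly one PCR product (one
individual × template × replicate amplification — the unit pooled before
cloning) and some breakpoint splits it into a prefix matching one
co-occurring variant and a suffix matching another; the parent search is
exhaustive over ordered pairs (O(V²·L), trivial at clone-library scale) and
the reported breakpoint window is the full interval of valid breakpoints.
Variants in ≥ 2 independent PCR products are confirmed; singletons are kept
as provisional.  Probable point artifacts (single-copy, single-reaction
variants within 2 substitutions of a confirmed allele of equal length) are
split into a separate artifact table; the pipeline excludes them from
per-individual counts by default (`drop_artifacts`), mirroring the manual
curation that published per-individual counts reflect, but never discards
them silently.  The locus lower bound is ⌈max/2⌉ for a diploid.

Names follow the hierarchical `Amci-DXB*NNNN[NN]` convention: a new
sequence joins the nearest existing major lineage when within 5% nucleotide
divergence of its founder (two-digit sub-variant counter), else opens the
next major number.  The 5% threshold is this package's documented
convention; the original nomenclature rule was never published.

## Annotation

The six-exon gene model (55 / 273 / 214 / 69 / 114 / 120 bp exons) carries
synthetic reference exon sequences (generated, not database-derived;
`default_gene_model` is labelled accordingly).  Exons are located by best
infix alignment (edlib), accepted at ≥ 80% identity over ≥ 80% of the
reference length; introns are the gaps; out-of-order hits are structural
errors.  A located exon's 5' boundary is refined to the nearest upstream
splice acceptor (AG) within 24 bp, which is how extra 5' coding bases (the
known 12 bp exon-5 variant) are detected and flagged.  Tandem repeats are
found by a period-k self-match scan scored +1/match, −4/mismatch (so any
non-negative-score segment has ≤ 20% mismatches and segments cannot drift
into random flanks); fractional copy numbers are span/period.  Cysteine
landmarks are read off translated alignments anchored at residue 1
including the leader peptide: leader Cys at 7, β1 pair 29/94, β2 pair
132/188; anything else is "extra", and a missing canonical pair raises a
structural-stability flag.

## Grouping

Default distance: K2P on nucleotides with complete deletion of
gapped/ambiguous columns (the closed-form kin of composite-likelihood
distances, and the simulator's generating model; p-distance and JC69 are
selectable, saturated pairs go NaN with a warning).  Average-linkage
clustering is cut at the midpoint of the largest gap between successive
merge heights (overridable); clusters below 4 members are "ungrouped";
labels I, II, ... go by decreasing size; the matrix is internally reordered
by allele name so ties break identically regardless of input order.
Validation: for each group of size k, the observed mean within-group
pairwise distance is compared to 999 random k-subsets drawn without
replacement from the full pool (focal group included — the natural reading
of "random selection of equivalent alleles");
p = (1 + #{null ≤ obs})/(n+1), never zero by construction.

## Selection tests

NG86 counting is table-driven: per-codon potential synonymous sites exclude
stop-producing mutations from the denominator (so S + N = 3 per codon
exactly), and difference counts average over all minimal mutational
pathways that avoid stops (all pathways when every one is blocked).
PBL classifies degeneracy per site (fourfold = 3 synonymous one-step
changes, twofold = 1–2, nondegenerate = 0; threefold sites fold into
twofold), pro-rates sites and differences 50/50 between the two codons'
classes, and combines K2P components per the L-weighted formulas.

The group-level test averages pairwise d_N and d_S over all unordered
pairs; a pair enters iff the two sequences share ≥ 30 fully resolved codons
in the domain (a documented choice — the averaging convention for
partially sequenced alleles was never published).  SEs come from a codon
bootstrap (resampled codon columns, pair inclusion fixed at the point
estimate); the bootstrap unit is the codon column, the standard for
MEGA-style Z-test variance.  One-tailed p-values are read from the
bootstrap distribution of d_N − d_S ((1 + count)/(B + 1)); the normal
approximation Z = (d_N − d_S)/SE is reported alongside.  Defaults:
B = 1000 in test fidelity, 10000 in full fidelity.  ω is NaN when
d_S = 0.  Method per scope: PBL + K2P for the low-divergence first group
(where a two-parameter correction is the better model), NG86 + JC
elsewhere; difference *numbers* always come from NG86 counting.

A calibration subtlety: under transition bias (κ > 1), synonymous sites
genuinely evolve faster than nonsynonymous ones even at ω = 1, because
transitions are enriched for synonymy.  The Z-test's null is equal rates
per site, so its type-I calibration uses κ = 1 in
`simulate_codon_alignment`; the repertoire simulator keeps κ = 2.

## Trees and TSP

Neighbor joining is delegated to scikit-bio on the package's distance
matrices (taxa pre-sorted by label for deterministic ties; negative branch
estimates clamped to zero and logged).  The TSP screen is a
nearest-neighbor criterion on the distance matrix — foreign-species
neighbor strictly closer than any conspecific — a deliberate proxy for
clade-based reading of a phylogeny; borderline alleles can differ between
the two, and species with a single allele yield NA.

## Published-survey margins

`mhcrep.published` carries the survey's count-table *margins* (19 column
totals, 13 per-individual allele counts, 69 allele names) and a
deterministic cell-level reconstruction satisfying every margin exactly,
used to exercise the report/summary path.  Cells are synthetic; margins are
data.  The per-individual counts sum to 165 (mean 12.69, SD 6.13), while
the survey prose rounds the mean to 12.5 — an internal inconsistency of the
source table that the margins, whose SD matches the printed 6.1, resolve in
favour of the table.

## Problem sizes

Test-fidelity defaults keep the full suite fast on one CPU: simulated
libraries of ~1000 clones, 1000-replicate bootstraps, 999 permutations,
type-I calibration over 500 seeded datasets of 20 alleles × 100 codons, and
power checks over 100 datasets at 200 codons.  These sizes give binomial
99% bands tight enough to detect miscalibration of a 5% test while staying
desk-scale.

## Known limitations

Orientation detection needs a reference anchor; the comparable-region trim
assumes a shared 5' anchor; the chimera filter cannot flag a recombinant
whose parents were not cloned from the same reaction (and will flag a true
allele that happens to decompose exactly into two co-occurring variants —
the price the replication design accepts); PBL attributes nonsynonymous
differences at twofold sites partly to d_S by construction, so "d_S = 0"
groups can show tiny positive values; the nomenclature threshold and the
≥ 30-shared-codon rule are conventions, not published rules.
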