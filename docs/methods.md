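# Methods

`beepan` re-implements, as a tested pipeline over synthetic data with known
ground truth, the comparative pan-genomics workflow used for honeybee-gut
lactobacilli and bifidobacteria: ortholog clustering, core/accessory
partitioning, core-genome phylogenetics with monophyly testing, a
three-statistic recombination scan, CRISPR spacer-protospacer mapping, and
rule-based PTS transporter classification. This note records the models,
parameter choices and their rationale, what the generator does and does not
emulate, and the numerical decisions that matter.

## The synthetic pangenome generator

The generator (`beepan.sim`) is first-class, tested code; its defaults are
the study conditions used throughout the tests and the acceptance script.

**Strain tree.** One pure-birth subtree per group (a leaf is split uniformly
at random until the group size is reached; every branch length is
Exponential with mean `subs_within = 0.02` substitutions/site), hung on a
root through deep branches of `subs_between / 2 = 0.075` each, so
inter-group distances are ~0.15-0.2 substitutions/site — deep enough that
groups are unambiguous, shallow enough that cross-group homologs still score
as similar. The default community is two groups of three strains.

**Genes.** 200 single-copy core families and 150 accessory families of 900 bp
(300 sense codons). Evolution is Jukes-Cantor on nucleotides with no indels,
so a family's alignment is column-wise identity and the ground truth is
exact; `evolve_gene` is pure JC and is tested against the closed form
E[diff] = L·(3/4)(1 − e^(−4t/3)). In-frame stop codons created by
substitution are reverted to the parent codon so that every CDS translates
cleanly under the bacterial code; this slightly depresses the realized
substitution rate (three of 61 sense codons are one step from a stop) and is
irrelevant to every consumer of the data.

**Accessory families** originate on a uniformly chosen edge within one
group's subtree and are lost on each descendant branch with probability
0.25; empty leaf sets are redrawn. Families are therefore confined to one
group, which keeps the group-accessory ground-truth label well defined. A
fraction 0.02 of core families additionally carries one duplicated
(paralogous) copy in one random strain, diverged by 0.02 substitutions/site.

**Recombination.** A fraction 0.1 of core families receives one imported
tract of 300 bp (codon-aligned) into one random strain. The donor is a
strain of *another* group — the distant-donor scenario of between-phylotype
transfer within the community. An earlier draft used a synthetic external
donor at 0.5 substitutions/site; such imports produce mostly
singleton-state columns, which are invisible to parsimony-informative-site
statistics by construction, and detection power was accordingly poor (~0.2).
Imports from a resident distant lineage produce the mosaic signal the three
statistics are designed for, and match the biology being emulated. The
single-group configuration falls back to the external donor.

**Genome assembly.** Each genome is the concatenation of its genes (reverse
complemented on the minus strand) with 100-bp random intergenic spacers;
operon-internal gaps are 50 bp. CRISPR arrays (default: one per strain, five
exact 32-bp repeats, four distinct 33-bp spacers) and protospacers are
inserted only into intergenic segments, so they never disturb the
gene-family ground truth. Two guards keep planted ground truth well defined
for any seed: (1) the column of bases immediately flanking the repeat copies
is forced non-unanimous, so "exact array coordinates" is unambiguous for a
detector that extends repeats through conserved columns; (2) genes flanking
planted PTS operons sit on the opposite strand, so the operon's extent under
the same-strand/max-gap rule equals the planted extent.

**Protospacers** are planted with probability 0.3 per spacer into a random
other strain of the same group, probability 0.0 across groups, zero
mismatches — the phylotype-restricted spacer-hit structure of the real
community. **PTS content** per strain: two complete Man-family (4.A.6)
operons with IIA/IIB/IIC/IID subunit genes, one incomplete operon (missing
IID), and one isolated decoy gene carrying both a strong 4.A.6 hit and an
EII domain — the decoy is what the operon-context rule must reject.

**What the generator does not emulate**: indels and alignment uncertainty,
codon/selection structure, rearrangements and gene-order evolution, plasmids
and prophages, sequencing/assembly artifacts (everything is one contig, so
the "partial gene at contig border" exclusion is exercised only by unit
fixtures), and realistic intergenic architecture. Passing recovery tests
therefore show that the *inference rules* are implemented correctly and are
mutually consistent with their definitions — not that they are robust to
alignment error or assembly noise in real data, where the pipeline ingests
externally built alignments and trees instead.

## Ortholog clustering

The built-in scorer computes ungapped percent identity over the shorter
sequence (coverage = shorter/longer), emitting hits at identity ≥ 50% and
coverage ≥ 0.5 with the e-value surrogate 10^(−identity). Real-data runs
supply a standard 12-column hits table instead and these knobs become the
search engine's.

Edge weights are −log10(e-value) capped at 200, reciprocal hits averaged,
then every edge between genomes X and Y is divided by the mean X-Y edge
weight. This mean normalization — the step that makes between-species edges
comparable to within-species ones — is the one piece of the published
clustering tool's weighting retained here; reciprocal-best-hit
preprocessing is not reproduced, which is the documented simplification of
this implementation.

Markov clustering runs at inflation 1.5 (the setting used for the real
genomes), self-loops at each node's maximum incident edge weight (1 when
isolated), pruning at 1e-6 and convergence at max element change < 1e-8.
Clusters are read off as connected components of the attractor support;
nodes claimed by several clusters go to the largest (ties to the cluster
containing the lexicographically smallest member), and unclaimed nodes
become singletons — all deterministic. A brute-force dense-matrix
implementation of the same recurrence, written independently in the test
suite, pins the behavior on 200 random graphs.

## Pan-genome partitioning

All labels are pure membership-count predicates: pan-orthologs (exactly one
member in every genome), group core (exactly one copy per group strain, any
outside membership), group accessory (≥1 but not all group strains, any
copy number; group-member singletons included), group-specific core
(present in every group strain, absent outside). "Subset of strains" in the
accessory definition is read as proper nonempty subset, complementary to
the core definition; a family present in all group strains but duplicated in
one of them is accessory, not core, because it violates "a single gene copy
for each". The functional-category rule assigns a gene to a category iff
exactly one category has ≥2 hits below e-value 0.01.

## Phylogenetics

Gap pruning removes columns with gap fraction ≥ 0.5 (a column with exactly
half gaps is removed — the comparison is ≥, per the rule's "50% or more").
Back-translation expands each residue to its codon ('---' for gaps) after
verifying the CDS translates to the protein. Concatenation is in ascending
family-id order (the source does not state an order; this is the
deterministic choice), with a partition map of column spans.

Built-in tree inference is JC distance (d = −(3/4)ln(1 − 4p/3), capped at
5.0 for p ≥ 0.749, pairwise deletion of gaps/missing) plus neighbor-joining
with the standard Q criterion, ties broken by the smallest (row, column)
index pair and negative branch lengths clamped to zero. Maximum-likelihood
inference is deliberately out of scope; every consumer (rooting, monophyly,
ordering) accepts externally built Newick trees. Bootstrap supports are
percentages of 100 column-resampled NJ replicates containing each internal
bipartition of the full-data tree. Rooting places the root at the midpoint
of the unique edge separating the outgroup, and returns a failure flag
rather than guessing when no such edge exists; gene trees that cannot be
rooted are reported "untested" in the monophyly census rather than being
counted either way.

## Recombination scan

All three statistics share one substrate: the parsimony-informative columns
(≥2 states each carried by ≥2 non-missing taxa; columns > 50% missing are
dropped). Pair incompatibility is the cycle rank (edges − vertices +
components) of the partition-intersection bipartite graph over observed
joint states; it is 0 iff the two characters are compatible, reduces to the
four-gamete test for binary pairs, and equals the minimum number of extra
parsimony steps on small cases, which a brute-force tree-enumeration oracle
verifies in the tests.

* Phi: mean incompatibility over site pairs ≤ 100 alignment positions apart
  (the delegated package's documented window default). Low observed values
  signal recombination, so the permutation p-value counts permutations with
  Phi ≤ observed.
* NSS is simplified to the fraction of *adjacent* informative-site pairs
  that are compatible (the original neighbourhood-similarity matrix
  formulation is not implemented); high values are extreme.
* MaxChi: for every taxon pair and every breakpoint with full flanks of
  k = max(10, m/10) informative sites, the 2×2 Pearson chi-square of
  (flank × match/mismatch) without continuity correction; with both flank
  margins fixed at k this collapses algebraically to 2k(r−l)²/((l+r)(2k−l−r)),
  degenerate tables scoring 0. High values are extreme.

P-values use the add-one permutation estimator (1 + #extreme)/(n + 1) with
1000 permutations of informative-site column order, seeded per gene from a
spawned seed sequence so results are independent of input ordering. A gene
is recombinant only when all three p-values fall below 0.01 — the combined
rule used for the real core genomes — and "not-evaluable" when any
statistic is undefined. On 500 clonal 600-bp genes (8 taxa, two clades)
each test's rejection rate at 0.01 sits inside the 99% binomial interval,
and the all-three rule makes no false calls; on 40 genes with planted
300-bp distant-donor tracts the rule's sensitivity was 0.825 at the frozen
experiment seed (the recorded first-run fixture the power test asserts
against). The calibration/power experiments use an 8-taxon tree because a
3-strain group admits no parsimony-informative sites at all — with the
default 2×3 community the group-core scan is honestly reported
not-evaluable.

## CRISPR

Detection chains exact 16-mer seeds recurring at periods within
[repeat_min+spacer_min, repeat_max+spacer_max] = [43, 115] bp, extends
repeat copies through columns where every copy agrees, and validates repeat
length 23-55, spacer lengths 20-60, consecutive spacers non-identical, and
copy identity ≥ 0.8 to the consensus; arrays with two repeats are
"questionable", three or more "confirmed"; overlapping candidates merge
keeping the higher repeat count. These ranges mirror the delegated
detector's published conventions (the source states no numbers) and are all
configuration. Both strands are scanned with arrays reported on forward
coordinates. Spacer masking replaces spacer intervals with 'N' (idempotent,
length-preserving). The protospacer search is an exact Hamming scan of both
strands, default ≤2 mismatches, accelerated by chunk pigeonholing (a match
with ≤k mismatches contains one exact chunk among k+1); windows overlapping
any masked position are discarded outright, so no hit ever lands in a
spacer interval, while self-genome hits elsewhere are allowed. Cas-subtype
labels are a pass-through from user annotations, never inferred.

## PTS classification

The rule chain: keep hits to TC family 4.A at e-value ≤ 0.01 (the boundary
value passes — "0.01 or lower"); operons are maximal same-strand CDS runs
with intergenic gaps ≤ 200 bp (the source asserts operon membership without
a rule; 200 bp is the common prokaryotic heuristic, configurable); a gene
is called iff it has a filtered hit, a PTS EII domain class (from the
shipped, editable domain→class map), and sits in an operon of ≥2 genes with
≥2 PTS-domain genes — "consistent PFAM predictions" operationalized at
operon level, which is exactly what rejects an isolated decoy gene. Family
is the lowest-e-value hit's (ties to the numerically smallest family). A
Man (4.A.6) operon is complete when its calls cover IIA/IIB/IIC/IID, with
fused IIA-IIB genes counting for both roles.

## Synteny and genome statistics

Comparison filters are literal: keep identity ≥ 80% and length ≥ 200 bp
(both boundaries pass; "below" excludes strictly), with the 50-bp length
dialect for the more distantly related Firm-4 strains. Genome pairs are
ordered by a deterministic ladderized leaf order (children by subtree size,
ties by smallest descendant leaf). Genome size and GC are over contigs
> 500 bp; CDS counts exclude partial and pseudogene flags; mean gene size
is total included-CDS length divided by CDS count — the natural ratio; the
source's footnote wording ("divided by total length") inverts it, and this
implementation documents rather than reproduces that wording. GC-island
flagging pools GC over sliding 5-gene windows, flags deviations ≥ 0.04 from
genomic GC (the real depressed regions sit 5-8 points low, so 0.04 captures
them with margin), merges overlapping flags, and trims boundary genes that
do not themselves deviate, so the reported region is the island proper.

## Problem sizes and determinism

The default study conditions (1,478 genes across 6 genomes; 500-gene
calibration at 1000 permutations; 40-gene power experiment; 200
oracle-checked random graphs; 100 random additive matrices) were chosen so
each analysis states its result at a scale where the ground-truth
comparison is exact and the whole suite reruns quickly on one CPU. Every
stage consumes a seed derived from the single run seed; identical
configuration yields byte-identical outputs, which the manifest's sha256
checksums make checkable.

## Known limitations

* The clustering scorer is ungapped; real proteomes need an external search
  engine's hits table (the supported real-data path).
* NSS is the adjacent-pair simplification; Phi has no analytical null, only
  the permutation one.
* Detection of recombination imported from truly external (unsampled)
  donors is structurally weak for informative-site statistics — see the
  generator's donor choice above.
* The CRISPR extension rule requires exact repeat copies over the extended
  region; degenerate repeats shorten to their exact core.
* r/m-style quantification of recombination-to-mutation substitution ratios
  is out of scope, as is maximum-likelihood tree inference.
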