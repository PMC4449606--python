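# beepan

Comparative pan-genomics of honeybee-gut bacteria, as a tested, reusable
pipeline. The honeybee crop hosts a small set of deeply divergent
*Lactobacillus* and *Bifidobacterium* phylotypes ("Firm-4", "Firm-5",
"Bifido") whose strains share a clonal core genome but differ sharply in
accessory gene content — sugar transporters above all — and appear to be
attacked by phylotype-specific phages. Analyzing that structure takes a
chain of inferences: protein families from all-vs-all similarity, core
versus accessory partitioning, core-genome phylogenies with monophyly
tests, recombination scanning, CRISPR spacer-to-protospacer mapping, and
rule-based PTS transporter classification. `beepan` implements every link
of that chain as a library, and ships a synthetic-pangenome generator with
exact ground truth so that each stage has a recovery test that needs no
downloads.

It is written for microbial comparative genomicists who want the analysis
logic — the definitions, filters and decision rules — explicit, testable
and reusable on their own data (FASTA, 12-column hits tables, Newick).

## Methods at a glance

* **Families**: Markov clustering (MCL) of a similarity graph at inflation
  1.5; edge weights −log₁₀ e, reciprocal hits averaged, normalized per
  genome pair by the mean inter-genome weight.
* **Partition**: pan-orthologs (single copy in every genome), group core
  (single copy per group strain), group accessory (proper subset, any copy
  number, singletons included), group-specific core (all group strains,
  absent elsewhere), with Venn region counts.
* **Phylogeny**: gap-column pruning (≥50% gaps), protein→codon
  back-translation, concatenation; Jukes-Cantor distances
  d = −¾ ln(1 − 4p/3) with neighbor-joining and 100 column-bootstrap
  replicates; outgroup rooting and exact monophyly tests per gene tree.
* **Recombination**: Phi (windowed mean pairwise incompatibility — cycle
  rank of the partition-intersection graph), NSS (adjacent-site
  compatibility fraction), MaxChi (maximal flanking-window 2×2 chi-square),
  each with a 1000-permutation null of informative-site order; a gene is
  recombinant only when **all three** p-values < 0.01.
* **CRISPR**: seed-and-extend array detection (repeats 23-55 bp, spacers
  20-60 bp, ≥3 repeats confirmed), spacer masking, exact Hamming
  protospacer search (≤2 mismatches) against the masked genomes, and
  within/between-group hit tallies.
* **PTS**: TC 4.A hits at e ≤ 0.01, operons as same-strand runs with gaps
  ≤ 200 bp, calls requiring hit + EII domain + operon context; complete Man
  (4.A.6) operons must cover subunits IIA/IIB/IIC/IID.

## Worked example

Run the numbered analyses (each regenerates what it needs, seeded, in a few
seconds to a couple of minutes):

```
python analysis/01_simulate.py
python analysis/02_cluster_families.py
python analysis/05_recombination_scan.py
```

which prints:

```
simulated 6 genomes, 1478 genes
data written under results/data

6176 similarity hits -> 422 families (truth: 422); adjusted Rand index 1.000
families written to results/groups.txt

calibration: 500 evaluable clonal genes
  phi: rejection rate 0.0080 at alpha 0.01
  nss: rejection rate 0.0040 at alpha 0.01
  maxchi: rejection rate 0.0060 at alpha 0.01
  all-three rule: 0 false calls
power: 33/40 genes with 300-bp distant-donor tracts flagged (sensitivity 0.825)
```

Reading those numbers: the default community is two groups of three strains
with 200 core and 150 accessory families; clustering recovers the planted
families exactly (adjusted Rand index 1.0 against ground truth). On clonal
genes each recombination test rejects at close to its nominal 1% level, the
combined all-three rule makes no false calls, and on genes carrying a
planted 300-bp tract from a distant donor it flags 33 of 40. The remaining
scripts partition the pan-genome, build the bootstrap core tree and
monophyly census (`03`, `04`), map CRISPR spacers to protospacers — all
planted hits recovered, none crossing groups (`06`) — recover the planted
Man-family PTS operons exactly (`07`), and print per-genome summary
statistics (`08`).

The same functionality is exposed as a CLI (`beepan run`, `beepan cluster`,
`beepan recomb`, `beepan crispr`, `beepan pts`, `beepan synteny`,
`beepan stats`, ...) for running individual stages on your own files.

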