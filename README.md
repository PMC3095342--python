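# plastidmark

Tools for chloroplast-genome (plastome) analysis in ornamental orchids
and similar systems where varieties are intergeneric hybrids and the
maternally inherited plastome is the tractable record of parentage:

- **Quadripartite structure** — detect the inverted-repeat pair (IRa/IRb)
  of a circular plastome, partition it into LSC / IRb / SSC / IRa, and
  compute genome statistics (GC, coding fractions, gene counts), plus
  the PCR-walking helpers used to sequence such genomes (overlapping
  amplicon tiling, greedy amplicon assembly).
- **ndh pseudogene classification** — compare each NAD(P)H dehydrogenase
  subunit gene (ndhA–ndhK) of a query variety against a functional
  reference CDS and assign one of five categories: functional, absent,
  truncated, frame shift (indels, in-frame deletions included), or
  internal stop codon; assemble the varieties × genes status matrix.
- **Marker extraction** — in-silico PCR of marker regions (trnH-psbA,
  trnF-ndhJ, matK, rbcL, …) from plastome templates, per-region
  progressive alignment, and concatenation into a partitioned
  supermatrix.
- **Phylogenetics at desk scale** — p/JC69 distances, neighbor-joining
  and UPGMA, Fitch parsimony with a random-addition + NNI heuristic
  search, nonparametric bootstrap with majority-rule consensus
  (branches under 50% support collapsed), Robinson–Foulds distances.
- **Pedigree congruence** — score trees against the maternal pedigree
  (a maternal group is *recovered* when an edge bipartitions exactly
  that group) and rank marker-region subsets to find the smallest set
  matching the full multi-region analysis.
- **Synthetic data** — every input above can be simulated with ground
  truth: structured plastomes with exactly planted IRs, lesion-bearing
  gene panels, and marker regions evolved with strictly maternal
  inheritance along a known 15-variety hybridization pedigree.

## The model in brief

A plastome is a circle `LSC + IRb + SSC + IRa` with
`IRa = revcomp(IRb)`. Distances use the Jukes–Cantor correction
`d = -(3/4) ln(1 - 4p/3)`; parsimony uses Fitch counting with gaps as
missing data and reports CI (over parsimony-informative characters) and
RI. Bootstrap supports are the percentage of column-resampled
replicates containing each bipartition. Because plastids are
maternally inherited, taxa sharing a maternal founder (followed through
female-parent links) must form a clade; per-taxon placement is scored
from bipartition recovery of those groups.

## Worked example

```python
from plastidmark import synthetic_data as sd, genome_structure as st, gene_status as gs

cfg = sd.SimConfig(seed=1)                      # study-condition defaults
record, annotations = sd.simulate_plastome(cfg)
part = st.detect_inverted_repeats(record, min_len=1000)
print(st.partition_lengths(part))

refs = {a.gene: a.spliced_sequence(record) for a in annotations}
mut, anns2, truth = sd.inject_lesions(
    record, annotations, [sd.Lesion("v", "ndhC", "delete_internal", 17)], seed=1)
region = sd.variety_regions(mut, anns2, ["ndhC"], 100)["ndhC"]
cmp = gs.align_gene_to_reference(region, refs["ndhC"], gene="ndhC")
print(gs.classify_gene_status(cmp).category, cmp.indel_events)
```

prints

```
(82324, 25755, 12650, 25755, 146484)
frame_disrupted [(246, 17, 'deletion')]
```

i.e. the detector recovers the planted structure exactly — a 146,484 bp
genome with 25,755 bp inverted repeats, a 12,650 bp SSC and an
82,324 bp LSC — and a 17 bp deletion in ndhC is read as a frameshift
(here with three premature stops appearing downstream in the shifted
reading frame).

The same workflow is available from the shell:

```
plastidmark simulate --seed 2 --out fixtures/
plastidmark structure --fasta fixtures/genome.fasta --gff fixtures/genome.gff3 --out stats.json
plastidmark evaluate --regions fixtures/regions --pedigree fixtures/pedigree.tsv --out ranking.tsv
plastidmark run-all --seed 7 --out results/
```

`run-all` writes `stats.json`, the gene-status `matrix.tsv`, a
bootstrap consensus `tree.nwk`, the marker-subset `ranking.tsv` and a
markdown summary.

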