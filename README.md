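# mirkit

Analysis toolkit for the regulatory genomics of animal miRNA loci, built
around the Drosophila *miR-317* / *Peony* locus: a miRNA hairpin lying a
couple of kilobases downstream of a lncRNA gene, with alternative
polyadenylation deciding whether the hairpin is transcribed at all.

It is aimed at fly (and other invertebrate) groups who have a miRNA
mutant, an RNA-seq comparison, and a qPCR machine, and want the
computational steps between those and a candidate-target table to be
scripted, tested and reproducible rather than done by hand in a
spreadsheet.

## What it computes

**Canonical seed sites.** For a mature miRNA `m` (5'→3', 1-based), the
seed is `m[2..7]` and the five canonical target-site classes on the
transcript strand are

| site        | sequence                  | length |
|-------------|---------------------------|--------|
| 8mer        | revcomp(m[2..8]) + A      | 8      |
| 7mer-m8     | revcomp(m[2..8])          | 7      |
| 7mer-A1     | revcomp(m[2..7]) + A      | 7      |
| offset-6mer | revcomp(m[3..8])          | 6      |
| 6mer        | revcomp(m[2..7])          | 6      |

The scanner finds every occurrence of the 6mer core on a transcript,
classifies it by its flanking bases (most specific type wins), and
reports offset-6mers separately unless subsumed by an 8mer/7mer-m8 call.

**Genomic context of miRNA genes.** From a GFF3 annotation, each miRNA
gene is classified as exonic, intronic, intergenic, or *putatively
co-transcribed* — lying within a configurable gap (default 2 kb) of a
same-strand neighbour gene, the arrangement of *Peony* and *miR-317*.

**Target integration.** Multi-database prediction lists are merged with
provenance, intersected with an RNA-seq differential-expression table,
and filtered (strict `padj < 0.05`, `log2FC > 0.5`, upregulated by
default) to candidate direct targets.

**qPCR.** ΔΔCt fold changes (`FC = 2^−ΔΔCt`, technical replicates
averaged on the Ct scale) and within-sample two-amplicon abundance
ratios (`ratio = 2^(Ct_b − Ct_a)`, geometric mean over samples) with a
Student's t-test on per-sample log2 ratios — the arithmetic behind the
lncRNA-body : pre-miRNA ratio used to infer alternative polyadenylation.

**Synthetic data.** Every stage has a seeded generator with recorded
ground truth (planted sites, planted contexts, exact DE fractions, true
ratios), so the whole pipeline runs and is tested without any downloads.

## Worked example

```console
$ mirkit derive-sites --mirna UGAACACAGUGCUAAAUGAAAGA
mirna	mirna
seed	GAACAC
8mer	UGUGUUCA
7mer-m8	UGUGUUC
7mer-A1	GUGUUCA
offset-6mer	UGUGUU
6mer	GUGUUC
```

The input is the mature miR-317-3p sequence; the output is its seed
(positions 2–7) and the five site strings a target transcript may carry.
Scanning a small FASTA:

```console
$ mirkit scan --mirna UGAACACAGUGCUAAAUGAAAGA --fasta demo.fa --out hits.tsv
$ cat hits.tsv
# coordinates are 1-based inclusive on the transcript sense strand
transcript_id	start	end	site_type	matched_seq
t1	3	10	8mer	UGUGUUCA
t3	2	8	7mer-A1	GUGUUCA
```

`t1` carries the full 8mer (seed match + m8 pairing + target adenosine);
`t3` has the seed match with the A1 adenosine but the wrong base opposite
miRNA position 8; `t2` (all C) has no site and is absent.

The same functions are available as a library:

```python
from mirkit import MatureMiRNA, derive_site_sequences, filter_candidates
from mirkit.datasets import mir317_testis_candidates

sites = derive_site_sequences(MatureMiRNA("miR-317-3p", "UGAACACAGUGCUAAAUGAAAGA"))
candidates = filter_candidates(mir317_testis_candidates())
print(len(candidates), candidates.loc[0, "gene_name"])   # 15 Osi17
```

Other subcommands: `mirkit classify-context`, `mirkit integrate`,
`mirkit qpcr ddct|ratio|compare`, `mirkit simulate
transcripts|annotation|de|ct`. Every run writes a JSON manifest (input
digests, parameters, seed) next to its outputs.

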