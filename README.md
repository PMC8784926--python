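# hapshift

Haplotype-level eDNA metabarcoding and coastline range-shift analysis for
marine non-native species.

Natural-resource managers tracking non-native species (NNS) along a
coastline typically hold three kinds of evidence: ordinal rapid-assessment
surveys (cover scored as absent / scarce / common / dominant per site),
COI sequences from tissue-sampled individuals, and eDNA metabarcoding of
replicated seawater samples. `hapshift` implements the full analysis chain
that combines them:

* **Amplicon denoising** — length-window and expected-error read filtering,
  pooled dereplication, and an abundance-skew (UNOISE-style) denoiser: a
  unique of abundance *a* at distance *d* from its nearest centroid of
  abundance *c* is absorbed when *a/c* ≤ β(d) = 1/2^(αd+1), α = 5; reads are
  then mapped back to centroids at ≥ 99.5 % identity to build the
  ASV × sample table.
* **Quality control** — within-site replicate-consistency filtering,
  max-across-negatives subtraction with flooring, relative read abundance
  (RRA), replicate averaging.
* **Rule-based taxonomy** — COI: ≥ 2 independent reference hits > 97 %
  identity at 100 % coverage with no competing species ≥ 97 %; 18S-style:
  exact 100 %/100 % match plus ≥ 1 bp distance from every congener.
* **Haplotype population genetics** — joint tissue/eDNA alignment windows,
  nucleotide diversity π, unbiased haplotype diversity Hd, ε = 0 minimum
  spanning networks (the union of all minimum spanning trees), and
  tissue-vs-eDNA haplotype concordance.
* **Hierarchical AMOVA** — variance components σ²(among years),
  σ²(among sites within years), σ²(within sites) with Φ_CT, Φ_SC, Φ_ST and
  stratum-appropriate permutation tests.
* **Range shifts** — range extent (east–west span of occupied sites along a
  1-D transect), change between survey years, spread rate in km yr⁻¹, and
  eDNA-vs-field density concordance (Spearman with permutation p).

A ground-truthed synthetic-data generator reproduces the study design
(12 sites, 4 species, 3 water replicates + negative controls, ~313 bp
amplicons, two survey years), so the entire pipeline is testable without
any external data. See `docs/methods.md` for the models and choices.

## Worked example

Run the packaged demonstration study (synthesis → denoise → QC → taxonomy →
haplotypes/AMOVA/range, one CPU, a few seconds):

```bash
hapshift run --outdir demo_run --seed 42
```

which prints, among the other species:

```
Clavelina lepadiformis
  range: 840.0 -> 1120.0 km (expansion, +35.0 km/yr)
  2009: n=105 pi=0.0060 Hd=0.778 (313 bp)
  2017: n=135 pi=0.0060 Hd=0.805 (313 bp)
  AMOVA: p(year)=0.930 p(site|year)=0.005 p(overall)=0.005
  eDNA vs tissue haplotypes: shared=6 tissue_only=0 edna_only=0
```

Reading this: the species' occupied range grew from 840 to 1120 km of
coastline between the two surveys (an expansion of 35 km per year);
nucleotide and haplotype diversity are statistically indistinguishable
between years; the AMOVA finds no year effect (p = 0.93) but strong genetic
differentiation among sites within years (p = 0.005); and eDNA
metabarcoding recovered all six tissue-derived haplotypes on the shared
alignment window. The run directory contains the machine-readable outputs
(ASV tables, RRA tables, assignment CSVs, AMOVA JSONs, MSN edge lists, a
manifest of output hashes) and is byte-identical when re-run with the same
seed.

Individual stages are available as subcommands (`simulate`, `denoise`,
`qc`, `assign`, `haplotypes`, `amova`, `range`, `report`) operating on
plain FASTQ/FASTA/CSV/TSV files, and everything is importable as a library
(`hapshift.denoise`, `hapshift.amova`, ...).

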