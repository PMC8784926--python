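# Methods

`hapshift` re-creates, as a tested library, the analysis chain used to study
range shifts and haplotype-level genetic structure of marine non-native
ascidians from three evidence streams: ordinal rapid-assessment surveys
along a coastline, Sanger-sequenced COI tissue samples, and eDNA
metabarcoding of replicated seawater samples. Because the raw reads and
traces behind such studies are rarely re-usable at desk scale, the package
ships a ground-truthed synthetic-data generator that emulates the sampling
design, and every analysis stage is validated against that truth or against
independent brute-force oracles.

## Synthetic study generator

The generator models a 1-D coastline transect (positions in km along a line
drawn parallel to the coast) with 12 sites, four target species, two survey
years (2009 and 2017), three replicate water samples per site plus negative
controls, and ~313 bp COI amplicons.

* **Haplotype pools.** Each species receives a connected mutation network:
  a random root sequence plus haplotypes derived from uniformly chosen
  existing members by 1–2 substitutions. This mirrors the star-like,
  few-step networks typical of introduced populations.
* **Site frequencies.** Occupied sites draw one Dirichlet(α=1) vector over
  the species' haplotypes. The same vector is reused for both survey years
  (a `drift` parameter exists but defaults to 0), encoding the temporally
  stable, spatially variable regime the analyses are designed to detect.
* **Occupancy → read allocation.** Ordinal cover categories map to biomass
  midpoints (absent 0, scarce 0.05, common 0.30, dominant 0.75) — the
  simplest monotone mapping consistent with the cover bands absent (0%),
  scarce (<10%), common (10–50%), dominant (>50%).
* **Reads.** eDNA reads are generated pre-merged and correctly oriented,
  with independent per-base substitutions (default 0.001) and constant Q30
  quality strings; indels are not simulated, so Hamming-distance algebra
  downstream is exact. Negative controls receive reads only through a
  per-read contamination probability. Tissue samples are multinomial draws
  of whole haplotypes (default 15 individuals per occupied species-site,
  within the study's 10–30 range).
* **Not modelled:** eDNA transport/decay, PCR chimeras, strand orientation,
  quality-score heterogeneity (beyond explicit fixtures), and indels.
  Passing tests therefore demonstrate the correctness of the algorithms
  under substitution-only error, not robustness to every artefact of real
  libraries.

Everything derives deterministically from a seed; per-stage seeds are the
CRC32 of `"{master_seed}:{stage}"`, so adding a stage never perturbs the
randomness of earlier stages.

## Denoising

Reads pass a length window (303–323 bp, ±10 around the expected 313) and an
expected-error filter (Σ 10^(−Q/10) ≤ 1). After pooling across samples and
exact dereplication (singletons discarded), an abundance-skew denoiser
visits uniques in descending abundance: a candidate of abundance *a* at
distance *d* from its nearest centroid of abundance *c* is absorbed when
*a/c* ≤ β(d) = 1/2^(αd+1), with α = 5 — the published UNOISE formulation, at
the setting recommended for resolving metazoan intraspecific variation on
313 bp COI fragments. Ties in the nearest-centroid choice go to the most
abundant, then lexicographically smallest, centroid. Candidates below the
denoiser's minimum cluster size (8, the reference implementation's default)
never seed centroids; their reads are recovered by the final mapping step,
which assigns each read to its best centroid at ≥ 99.5 % identity and
rebuilds per-sample counts. Unequal-length comparisons fall back to
end-gap-free mismatch counting; identity is matching columns over aligned
columns.

## Quality control

Four steps, in the order used on the real data: (1) retain ASVs present in
≥ 2 replicates of at least one site (a within-site reading of replicate
consistency — a dataset-wide reading is available behind `scope="global"`,
but within-site is the default because replicates are the site-level unit
and the global reading would let two different sites' one-off observations
validate each other); (2) for ASVs seen in any negative control, subtract
the maximum negative-control count from every experimental sample, flooring
at 0, then drop the control columns; (3) divide by per-sample totals
(all-zero samples are excluded with a warning, preserving the
absent-vs-zero distinction); (4) average replicate proportion vectors per
site.

## Taxonomy rules

Assignments are made against a user-supplied labelled reference FASTA with
a reference_id → (species, genus) map; no remote databases are queried.

* **COI rule:** species-level assignment requires ≥ 2 reference records
  with distinct ids at identity > 97 % and coverage = 100 %, and no other
  species reaching ≥ 97 % identity (such a competitor makes the call
  *ambiguous*). The strict `> 97` for the target and `≥ 97` for
  competitors makes the decision flip exactly at the boundary.
* **18S-style exact rule:** requires a 100 %/100 % match and, when
  same-genus references of other species exist, at least 1 bp separating
  the query from every congener. An identical congener blocks assignment —
  the mechanism by which a conserved marker goes silent for recently
  diverged taxa while COI keeps detecting them. When no congener exists in
  the database the assignment is made but flagged
  `no congener check possible`; this is a documented package choice, since
  the original workflow's behaviour in that case is not stated.

ASVs assigned to the same species are merged (summed relative read
abundance) for distribution analyses; the unmerged ASV table is preserved
for haplotype work.

## Haplotype analyses

Tissue alignments and shorter eDNA-derived sequences are trimmed to the
maximal window covered by every sequence (coordinates 0-based half-open in
tissue-alignment space; eDNA fragments are located by best ungapped
placement, and placements under 75 % identity are rejected as
non-overlapping). Sequences with ambiguity codes are discarded and logged.

* Nucleotide diversity: π = mean pairwise Hamming distance over C(n,2)
  pairs, per site.
* Haplotype diversity: Hd = n(1 − Σp²)/(n − 1).
* Minimum spanning network at ε = 0: unique edge weights processed in
  increasing order, adding every weight-w edge joining components as they
  stood before any weight-w edge was added. This equals the union of all
  minimum spanning trees, which the tests verify by exhaustive spanning-tree
  enumeration. ε is exposed as a parameter (default 0).
* Concordance: exact-sequence set comparison of tissue and eDNA haplotypes
  on the shared window; eDNA haplotypes are weighted by relative read
  abundance, tissue by individual counts, and the two are never pooled in
  one statistic.

## AMOVA

Two-level hierarchical decomposition (years ⊃ sites ⊃ individuals) from
squared distances equal to pairwise nucleotide difference counts (no
distance correction is applied — none is warranted at these divergences).
Sums of squares are computed from within-group distance sums; variance
components use the standard expected-mean-square coefficients for unequal
sample sizes; Φ statistics are component ratios. Negative components are
reported as-is and flagged rather than truncated, so percent-variance
columns remain auditable. Degenerate inputs (all sequences identical)
report zero SS and NaN Φ with a flag.

Permutation schemes: Φ_ST permutes individuals among all sites; Φ_SC
permutes individuals among sites within years; Φ_CT permutes whole
site-populations among years (populations are relabelled uniquely first so
reassigned populations cannot merge by name). p = (1 + #{perm ≥ obs}) /
(1 + N), default N = 999.

## Range shifts

Range extent per species-year is the distance between the westernmost and
easternmost occupied sites; change between years yields a delta, a spread
rate (delta over the year gap, reported to 1 decimal with half-up rounding
— the reporting convention for spread rates, so e.g. 168.4 km over 8 years
prints 21.1), bound shifts with sign conventions (positive = expansion on
that side), and a classification with a 0 km stability tolerance. Cover
percentages map to categories with 10 % and 50 % assigned to "common"
(the band edges are not specified by the survey protocol; this convention
is documented here). eDNA-vs-field density concordance is a Spearman rank
correlation with a two-sided permutation p, computed only over sites with
detections in both sources and declared not testable below 4 shared sites.

## Evaluation scenarios and problem sizes

`hapshift.benchmarks` regenerates the standard evaluation scenarios used by
both the test-suite and `scripts/acceptance.py`:

* denoiser recovery — 20 seeds, one site, 3 replicates × 10⁴ reads, five
  true haplotypes (pairwise distance ≥ 2) at ≥ 2 % frequency, 0.001 error;
* AMOVA regime recovery — 50 seeds, 6 sites × 15 individuals × 2 years,
  999 permutations;
* type-I calibration — 200 null simulations (2 years × 6 sites × 3
  individuals for AMOVA, so the whole-site permutation space of the
  year-level test stays large; 8 sites for concordance) at 199
  permutations, which gives p-value granularity of 0.005 while keeping the
  calibration loops fast;
* the marker-failure mechanism — one species with a congener at divergence
  30 bp (COI) and 0 bp (conserved locus).

These sizes are the package's reference conditions; they are deliberately
modest so the full evaluation reruns in a couple of minutes on one core.

## Known limitations

* The pluggable denoiser interface currently has a single implementation
  (the abundance-skew algorithm); contrasting denoisers can be expressed as
  parameterisations but no independent error-model denoiser is included.
* Alignment handling assumes end-gap padding only; internal indels are out
  of scope, consistent with the substitution-only generator.
* The AMOVA is limited to the two-level year/site design; no
  allele-frequency F-statistics.
* Geodesic coastline distances are an input (a site CSV with km positions),
  not computed from coordinates.
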