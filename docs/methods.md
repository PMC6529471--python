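# Methods

## Model and procedure

The pipeline treats a hair specimen's proteome as evidence about its
donor's genotype at missense SNP loci. At each locus a protein carries one
amino acid per allele; tryptic peptides spanning the variant residue exist
as a major and a minor form (GVPs). The per-sample observation at a locus is
one of four phenotype categories — both forms detected, major only, minor
only, or neither — derived from presence/absence matching of identified
peptides against a locus catalog.

**Catalog.** For each SNP both allele-specific sequences are digested
in silico. Cleavage is C-terminal to K/R; the proline rule (no cleavage
before P) is off by default and configurable — recall is maximised by
cleaving before proline, and strict engines can re-enable the rule. Up to
3 missed cleavages are allowed by default. Peptides of length 5–50 covering
the variant site are retained; with the semi-specific option, truncations of
those windows with one non-tryptic terminus are added, since cysteine/serine
rich hair-matrix proteins yield many non-tryptic peptides. Windows are
paired across alleles by protein coordinates. When a variant creates or
destroys a K/R site the two digests differ; only coordinate-matched windows
are emitted, so every emitted pair differs at exactly the variant residue.
This drops allele-private windows of K/R-involving variants — a documented
limitation, not an error path.

**Indistinguishability rules.** Isoleucine and leucine are isobaric and not
separated by the assumed fragmentation, so sequences are compared after I→L
collapse both when testing whether a GVP pair is discriminative and when
matching observations (configurable). Deamidation converts N→D and Q→E; a
locus whose two alleles are exactly such a pair has the deamidated form of
one allele isobaric and isomeric with the genomic form of the other, so the
mimicked record is flagged, and a strict mode refuses to credit it from
observations carrying a deamidation modification at the variant offset.

**Detection.** A GVP is detected when any observation's bare sequence
(modifications stripped) equals the catalog sequence under the equivalence
rule. One peptide-spectrum match suffices; no intensity threshold is applied
(areas feed quantification only). Detection over a growing observation set
is monotone, and duplicated observations are idempotent.

**Consistency and panel selection.** Against the donor's exome genotype,
each allele of each state is a TP/FN (allele carried) or FP/TN (not
carried). The panel filters run in a fixed order: (1) any FP call anywhere
removes the locus — an FP under any allele disqualifies the locus even if
the other allele is clean, the conservative reading of "no false
positives"; (2) loci whose calls are all TP/TN across every sample for at
least one allele form are kept; (3) the major- and minor-consistent lists
merge into one locus list; (4) loci without an rsID are dropped, since
population genotype frequencies are unavailable for them; (5) one SNP per
gene — the lowest minor-allele frequency wins, ties broken by
lexicographically smallest id (deterministic; real frequency data
essentially never ties). Intermediate counts and a per-SNP decision log are
reported so the filter cascade is auditable.

**Scoring.** Observed phenotype frequencies account for the uncertainty of
incomplete detection: detecting only one form is consistent with the
corresponding homozygote *and* the heterozygote, so the score is the sum of
those genotype frequencies; detecting both forms is consistent only with
the heterozygote and scores `f_het` (the unique genotype consistent with the
observation — the natural completion of the single-form rule); an absent
locus is not scored. The RMP multiplies scores over scored loci, assuming
inter-locus independence (supported by the one-SNP-per-gene rule). A
profile with no scored locus has no RMP and raises a distinct error rather
than returning 1.

**Comparison statistics.** Profile difference counts loci whose categories
differ; detected-vs-absent counts as a difference even though absent loci
are skipped in the RMP — the two rules serve different statistics and are
kept independent. Difference is a metric on category vectors (verified
exhaustively on 3-locus panels). For an I × L × R design the pair counts
are `I·L·C(R,2)` replicate, `I·(C(L·R,2) − L·C(R,2))` within-individual,
and `C(I,2)·(L·R)²` between-individual; the default 3 × 3 × 4 design gives
54 + 144 + 432 = 630. Group differences are tested with Kruskal–Wallis over
five groups (replicate, within-individual, and the three between-individual
pairs) followed by Dunn's rank z-tests with ties correction and Bonferroni
adjustment. Dunn's test is implemented in-package (no installed dependency
provides it); the variance term is `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)`.

**Quantification.** Within a sample, duplicate observations of a peptide
collapse to the maximum area (robust to repeated sampling of one
precursor); unique-peptide areas are normalized to the sample total —
making the table invariant to per-sample scaling, i.e. to on-column mass
loading — and protein abundance is the sum of its peptides' normalized
areas. Shared peptides credit every mapped accession and are flagged; the
normalizing denominator counts each unique sequence once. The
differential-expression screen fits `abundance ~ location * individual` per
protein (α = 0.05), zero-filling missing proteins, with Tukey HSD location
contrasts starred at p ≤ 0.05/0.01/0.001. The SNP–abundance screen
correlates per-(individual, location) identification frequency with mean
protein abundance, one-sided for positive association.

## Synthetic data: what it emulates and what it does not

The generator reproduces the design (3 individuals × head/arm/pubic × 4
replicates), Hardy–Weinberg genotypes at 8 loci with minor-allele
frequencies spread over 0.10–0.45, per-allele detection dropout, optional
false positives, log-normal precursor areas, and multiplicative
per-location abundance effects on a subset of background proteins
(pubic-enriched, arm-depleted by default, mirroring the usual ordering of
hair-protein yields). Variant-bearing proteins carry no location effect:
robust GVP markers come from proteins without location-specific expression.

Default sensitivity is 0.95 per allele per sample: with ~8 loci this gives
replicate profile-difference means around one, the intraindividual
variation scale reported for real single-inch hair data. Dropout is
independent across samples and loci (data-dependent acquisition
stochasticity), with no run-to-run chromatography correlation. Detection is
simulated per allele and emits the canonical fully tryptic
zero-missed-cleavage GVP, which makes the per-locus detection-outcome table
exactly enumerable (the calibration oracle
`replicate_mismatch_probability`).

Not emulated: spectrum-level identification and FDR, PTM occurrence on
GVPs, retention time and charge states, shared peptides between paralogs,
haplotype phase, and population substructure. Consequently, passing tests
demonstrate the correctness of the analysis logic under the stated noise
model, not identification performance on real hair data. Two emergent
behaviours of the model are worth noting when reading simulated outputs:
(i) total-area normalization is compositional, so scaling a few proteins up
at one location necessarily shifts every other protein's fraction down —
location effects therefore propagate to non-scaled proteins in the ANOVA
screen, as they would in real normalized data; (ii) requiring all-sample
consistency under a uniform sensitivity preferentially retains loci whose
minor allele is absent from the cohort (all-TN), so simulated panels are
smaller and less informative than a real panel whose robust markers have
near-unit sensitivity — RMPs of roughly 1 in 1 to 1 in 60 at desk scale
rather than 1 in several hundred.

## Numerical and interface choices

* All residue positions are 1-based; peptide coordinates are 1-based
  inclusive (protein-variant convention).
* Genotype-frequency triples must sum to 1 within 1e-6; the implied minor
  allele frequency `f_het/2 + f_minor_hom` must not exceed 0.5, which
  catches swapped allele labels at read time.
* Readers never silently drop rows: PSM rows failing validation are
  collected as (row, message) errors and counted; other tables raise on the
  first violation.
* "Amino acids" in profile metrics is the summed length of distinct peptide
  sequences.
* All randomness derives from one integer seed through per-stage
  `numpy` `SeedSequence` streams; identical seeds give byte-identical
  output files. Stage boundaries are plain TSV/JSON.
* Degenerate inputs: an empty protein digests to the empty set; an
  all-identical comparison table yields a degenerate omnibus test (p = 1,
  nothing significant); constant-abundance proteins and zero-variance
  correlations are reported with notes instead of statistics; zero-area
  samples are excluded from quantification with a warning.
* Problem sizes in the test and acceptance runs (36-sample design, 8 loci,
  1000 replicate pairs for calibration, 200 sequences for the digestion
  oracle) are chosen to exercise every code path at desk scale.

## Known limitations

* Multi-variant haplotypes within one peptide window are not resolved; loci
  sharing a window are mutually flagged (`overlapping_snps`) and their
  shared-peptide evidence is not partitioned.
* Windows private to one allele of a cleavage-site-changing variant are not
  catalogued.
* Linkage disequilibrium is handled only by the one-SNP-per-gene rule, not
  modelled.
* The VCF format is out of scope; genotypes enter as a minimal TSV table.
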