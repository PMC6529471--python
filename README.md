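# gvppanel

Protein-based human identification from hair, for forensic proteomics:
catalogs of genetically variant peptides (GVPs), inference of missense SNPs
from peptide detections, selection of a robust SNP panel, and random match
probabilities (RMPs) from observed phenotype frequencies.

Hair shafts retain little intact nuclear DNA, but their proteome is abundant
and durable. A missense SNP changes one amino acid in a protein, so a
tryptic peptide spanning that residue exists in two forms — the *major* GVP
(major allele) and the *minor* GVP (minor allele). Detecting either form in
a hair digest by LC-MS/MS infers the allele, and a panel of such loci yields
a profile with a quantifiable probability that a random person would match
it.

## What the package computes

Given protein sequences (FASTA), a missense SNP table with population
genotype frequencies `(f_AA, f_Aa, f_aa)`, per-sample peptide-spectrum-match
exports, a sample manifest (individual × body location × replicate), and an
exome genotype table, the pipeline:

1. **Catalog** (`gvp_catalog`) — applies each allele to the protein,
   digests in silico (cleavage after K/R, up to 3 missed cleavages by
   default, optional proline rule and semi-specific termini), and keeps
   site-covering windows as major/minor GVP pairs. Pairs indistinguishable
   after I→L collapse are flagged non-discriminative; pairs mimicked by
   deamidation (N→D, Q→E) are flagged modification-confounded.
2. **Detection** (`detection`) — matches observed peptides to the catalog
   (exact bare-sequence equality under I/L equivalence) and produces a
   per-(sample, SNP) detection state plus per-sample profile metrics
   (proteins, unique peptides, amino acids, SNPs from major/minor GVPs).
3. **Consistency & panel** (`consistency_panel`) — scores each state
   against the exome genotype as TP/TN/FP/FN per allele and applies ordered
   filters: drop loci with any false positive; keep loci consistent across
   all samples for major or minor GVPs; merge; drop loci without an rsID;
   keep the lowest-MAF SNP per gene.
4. **Profiling** (`profiling`) — scores each sample's panel loci with
   observed phenotype frequencies: only-major ⇒ `f_AA + f_Aa`, only-minor ⇒
   `f_aa + f_Aa`, both ⇒ `f_Aa`, absent ⇒ not scored. The RMP is the product
   over scored loci:

   `RMP = Π_i f_pheno(i)`, reported as "1 in round(1/RMP)".

   Pairwise profile differences (count of loci whose categories differ) are
   summarised by comparison category — replicate, within-individual,
   between-individual per pair of individuals — with a Kruskal–Wallis
   omnibus test and Dunn post-hoc z-tests (Bonferroni-adjusted).
5. **Abundance** (`abundance`) — label-free quantification: per-sample
   precursor areas of unique peptides normalized to the sample total,
   summed per protein; per-protein two-way ANOVA (location × individual)
   with Tukey HSD contrasts; per-SNP one-sided Pearson correlation between
   identification frequency and protein abundance.
6. **Synthetic data** (`synthetic_data`) — generates the full study design
   (default 3 individuals × 3 locations × 4 replicates, 8 Hardy–Weinberg
   loci) with per-allele detection dropout, optional false positives, and
   location-specific protein abundance effects, writing the exact file
   formats the readers consume, plus truth tables.

## Worked example

Run the whole pipeline on a simulated study:

```sh
gvppanel all --out-dir run1 --seed 123 --n-snps 6
```

which prints, stage by stage:

```text
simulated 36 samples, 6 SNPs, 5737 observations -> run1
wrote 96 GVP records -> run1/catalog.tsv
wrote 216 detection states -> run1/states.tsv
wrote 432 consistency calls -> run1/calls.tsv
panel: 3 SNPs (6 -> 6 -> 3 -> 3 -> 3)
wrote 36 profiles -> run1/profiles.tsv
wrote 630 comparisons -> run1/comparisons.tsv
wrote RMP table -> run1/rmp.tsv
wrote abundance matrix -> run1/abundance.tsv
pipeline complete -> run1
```

Reading the panel line: 6 simulated loci entered; none had false-positive
calls (6); 3 were exome–proteome consistent across all 36 samples for at
least one GVP form (3); all 3 carry rsIDs and sit in distinct genes, so the
panel holds 3 SNPs. `run1/comparisons.tsv` contains the 630 unordered
sample pairs (54 replicate, 144 within-individual, 432 between-individual),
`run1/comparison_summary.json` their per-category means and rank tests, and
`run1/rmp.tsv` one RMP per sample with its "1 in N" form. The same
operations are available as library functions (`simulate_scenario`,
`build_catalog`, `match_observations`, `classify`, `select_panel`,
`build_profile`, `pairwise_compare`, `rmp`).

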