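"""Synthetic study generator: genotypes, proteins, and PSM-like observations
with the statistical structure the pipeline assumes.

The default design mirrors the study layout the pipeline targets: 3
individuals x 3 body locations (head, arm, pubic) x 4 replicate hair
specimens, with Hardy-Weinberg genotypes at each simulated locus. Detection
of a carried GVP is an independent Bernoulli draw per sample x locus x
allele with sensitivity ``s`` (modelling data-dependent acquisition
dropout); a false-positive draw with rate ``fp`` can emit a GVP the
individual does not carry. Precursor areas are log-normal; per-location
multiplicative effects on a subset of background proteins emulate body
location-specific differential expression. Variant-bearing proteins carry no
location effect, matching the observation that robust GVP markers derive
from proteins without location-specific expression.

All randomness flows from a single integer seed; the same seed reproduces
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import iodata
from .detection import PhenotypeCategory, categorize
from .gvp_catalog import (
    AlleleType,
    GVPRecord,
    MissenseSNP,
    build_catalog,
)
from .iodata import (
    GenotypeTable,
    Genotype,
    PeptideObservation,
    SampleKey,
)

# residues used to build scaffold peptides: no K/R (cleavage sites are
# planted explicitly), no I (avoids accidental I/L-indistinguishable pairs),
# and the deamidation-pair residues N/Q/D/E are excluded so default variants
# are never modification-confounded
_SEGMENT_ALPHABET = "ACFGHMPSTVWY"
_VARIANT_ALPHABET = "ACFGHMSTVWY"  # also no P: keeps windows proline-rule-invariant


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults encode the emulated study conditions: 3 individuals, head/arm/
    pubic locations, 4 replicates each, 8 loci with minor-allele frequencies
    spread over [0.10, 0.45], per-GVP detection sensitivity 0.95 and no false
    positives, and 20 background proteins of which 6 carry multiplicative
    per-location abundance effects. ``seed`` is mandatory.
    """

    seed: int
    n_individuals: int = 3
    locations: tuple[str, ...] = ("head", "arm", "pubic")
    n_replicates: int = 4
    n_snps: int = 8
    mafs: tuple[float, ...] | None = None
    sensitivity: float = 0.95
    false_positive_rate: float = 0.0
    n_background_proteins: int = 20
    peptides_per_protein: int = 8
    n_differential_proteins: int = 6
    location_effects: Mapping[str, float] = field(
        default_factory=lambda: {"head": 1.0, "arm": 0.6, "pubic": 2.5}
    )
    background_sensitivity: float = 0.95
    log_area_mu: float = 16.0  # natural-log mean of precursor areas (~9e6)
    log_area_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.mafs is None:
            self.mafs = tuple(
                round(q, 4) for q in np.linspace(0.10, 0.45, self.n_snps)
            )
        self.mafs = tuple(float(q) for q in self.mafs)
        if len(self.mafs) != self.n_snps:
            raise ValueError(f"need {self.n_snps} minor-allele frequencies, got {len(self.mafs)}")
        if any(not 0.0 <= q <= 1.0 for q in self.mafs):
            raise ValueError("minor-allele frequencies must lie in [0, 1]")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")
        if not 0.0 <= self.false_positive_rate < 1.0:
            raise ValueError("false_positive_rate must lie in [0, 1)")
        if not 0.0 <= self.background_sensitivity <= 1.0:
            raise ValueError("background_sensitivity must lie in [0, 1]")
        if self.n_differential_proteins > self.n_background_proteins:
            raise ValueError("n_differential_proteins exceeds n_background_proteins")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage, derived from the config seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SimulatedScenario:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    proteome: dict[str, str]
    snps: list[MissenseSNP]
    background_accessions: list[str]
    differential_accessions: list[str]
    manifest: list[SampleKey]
    genotypes: GenotypeTable
    catalog: list[GVPRecord]
    observations: list[PeptideObservation]
    truth: dict


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, n_segments: int) -> tuple[str, list[tuple[int, int]]]:
    """A protein of ``n_segments`` tryptic segments; returns (sequence, segment spans).

    Each segment is 6-10 non-K/R residues followed by a K or R terminator
    (the final segment is unterminated), so the zero-missed-cleavage digest
    is exactly the segment list.
    """
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    position = 1
    for i in range(n_segments):
        length = int(rng.integers(6, 11))
        body = "".join(rng.choice(list(_SEGMENT_ALPHABET), size=length))
        segment = body + (str(rng.choice(["K", "R"])) if i < n_segments - 1 else "")
        parts.append(segment)
        spans.append((position, position + len(segment) - 1))
        position += len(segment)
    return "".join(parts), spans


def _hardy_weinberg(q: float) -> tuple[float, float, float]:
    return ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q**2)


def simulate_proteins(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[MissenseSNP], list[str], list[str]]:
    """Variant-bearing and background protein scaffolds plus the SNP table.

    One SNP per variant protein, planted mid-segment so the canonical GVP is
    a fully tryptic peptide of length 6-11; major/minor residues are chosen
    to be discriminative (never an I/L swap) and never deamidation mimics.
    """
    rng = config.rng(0)
    proteome: dict[str, str] = {}
    snps: list[MissenseSNP] = []
    for i in range(config.n_snps):
        accession = f"GVP{i + 1:03d}"
        sequence, spans = _random_protein(rng, n_segments=5)
        start, end = spans[2]  # an internal segment
        position = (start + end) // 2
        major_aa = sequence[position - 1]
        minor_aa = str(
            rng.choice([aa for aa in _VARIANT_ALPHABET if aa != major_aa])
        )
        q = config.mafs[i]
        snps.append(
            MissenseSNP(
                snp_id=f"rs{100000 + i}",
                gene=f"GVPG{i + 1}",
                protein_accession=accession,
                residue_position=position,
                major_aa=major_aa,
                minor_aa=minor_aa,
                genotype_freqs=_hardy_weinberg(q),
            )
        )
        proteome[accession] = sequence
    background, differential = [], []
    for j in range(config.n_background_proteins):
        accession = f"BGP{j + 1:03d}"
        sequence, _ = _random_protein(rng, n_segments=config.peptides_per_protein)
        proteome[accession] = sequence
        background.append(accession)
        if j < config.n_differential_proteins:
            differential.append(accession)
    return proteome, snps, background, differential


def make_manifest(config: SimulationConfig) -> list[SampleKey]:
    """Sample keys for the full crossed design, in deterministic order."""
    manifest = []
    for i in range(config.n_individuals):
        individual = f"Ind{i + 1}"
        for location in config.locations:
            for replicate in range(1, config.n_replicates + 1):
                manifest.append(
                    SampleKey(
                        sample_id=f"{individual}_{location}_r{replicate}",
                        individual_id=individual,
                        body_location=location,
                        replicate=replicate,
                    )
                )
    return manifest


def simulate_genotypes(config: SimulationConfig, snps: Sequence[MissenseSNP]) -> GenotypeTable:
    """Hardy-Weinberg genotype draw per individual per SNP, seeded."""
    rng = config.rng(1)
    table = GenotypeTable()
    genotype_values = [Genotype.major_hom, Genotype.het, Genotype.minor_hom]
    for i in range(config.n_individuals):
        individual = f"Ind{i + 1}"
        for snp in snps:
            idx = rng.choice(3, p=np.asarray(snp.genotype_freqs) / sum(snp.genotype_freqs))
            table.set(individual, snp.snp_id, genotype_values[int(idx)])
    return table


# ---------------------------------------------------------------------------
# observation generation
# ---------------------------------------------------------------------------

def _canonical_record(catalog: Sequence[GVPRecord], snp_id: str, allele: AlleleType) -> GVPRecord:
    candidates = [
        r
        for r in catalog
        if r.snp.snp_id == snp_id
        and r.allele_type is allele
        and r.missed_cleavages == 0
        and not r.semi_specific
    ]
    if not candidates:
        raise ValueError(f"no fully tryptic 0-missed-cleavage GVP for {snp_id}/{allele.value}")
    return min(candidates, key=lambda r: (len(r.sequence), r.start))


def simulate_observations(
    config: SimulationConfig,
    genotypes: GenotypeTable,
    catalog: Sequence[GVPRecord],
    manifest: Sequence[SampleKey],
    proteome: Mapping[str, str],
    background_accessions: Sequence[str],
    differential_accessions: Sequence[str],
) -> tuple[list[PeptideObservation], dict]:
    """Per-sample peptide observations plus truth tables.

    For each sample and locus, each allele the individual carries is emitted
    (as the canonical fully tryptic GVP) with probability ``sensitivity``;
    each allele not carried is emitted with probability
    ``false_positive_rate``. Background peptides are emitted with probability
    ``background_sensitivity``; differential background proteins have their
    log-normal areas scaled by the location effect. Truth records every
    intended detection decision.
    """
    from .gvp_catalog import digest  # local import to avoid cycles at module load

    rng = config.rng(2)
    snp_ids = sorted({r.snp.snp_id for r in catalog})
    canonical = {
        (snp_id, allele): _canonical_record(catalog, snp_id, allele)
        for snp_id in snp_ids
        for allele in AlleleType
    }
    effects = dict(config.location_effects)
    differential = set(differential_accessions)
    background_peptides = {
        accession: sorted(
            (pep, start)
            for pep, start, mc in digest(proteome[accession], 0)
            if mc == 0 and len(pep) >= 5
        )
        for accession in background_accessions
    }
    observations: list[PeptideObservation] = []
    detections: list[dict] = []
    for sample in manifest:
        effect = effects.get(sample.body_location, 1.0)
        for snp_id in snp_ids:
            genotype = genotypes.get(sample.individual_id, snp_id)
            for allele in AlleleType:
                record = canonical[(snp_id, allele)]
                present = (
                    genotype is not Genotype.minor_hom
                    if allele is AlleleType.major
                    else genotype is not Genotype.major_hom
                )
                p_emit = config.sensitivity if present else config.false_positive_rate
                emitted = bool(rng.random() < p_emit)
                detections.append(
                    {
                        "sample_id": sample.sample_id,
                        "snp_id": snp_id,
                        "allele_type": allele.value,
                        "carried": present,
                        "emitted": emitted,
                    }
                )
                if emitted:
                    observations.append(
                        PeptideObservation(
                            sample_id=sample.sample_id,
                            sequence=record.sequence,
                            modifications=(),
                            protein_accessions=(record.snp.protein_accession,),
                            precursor_area=float(
                                np.exp(rng.normal(config.log_area_mu, config.log_area_sigma))
                            ),
                        )
                    )
        for accession, peptides in background_peptides.items():
            scale = effect if accession in differential else 1.0
            for pep, _ in peptides:
                if rng.random() < config.background_sensitivity:
                    observations.append(
                        PeptideObservation(
                            sample_id=sample.sample_id,
                            sequence=pep,
                            modifications=(),
                            protein_accessions=(accession,),
                            precursor_area=float(
                                scale
                                * np.exp(rng.normal(config.log_area_mu, config.log_area_sigma))
                            ),
                        )
                    )
    truth = {
        "genotypes": {
            f"{ind}|{snp}": genotype.value for (ind, snp), genotype in sorted(genotypes.items())
        },
        "detections": detections,
        "differential_accessions": sorted(differential),
    }
    return observations, truth


def simulate_scenario(config: SimulationConfig) -> SimulatedScenario:
    """Generate a complete in-memory study under the configured conditions."""
    proteome, snps, background, differential = simulate_proteins(config)
    manifest = make_manifest(config)
    genotypes = simulate_genotypes(config, snps)
    catalog = build_catalog(snps, proteome, max_missed=3)
    observations, truth = simulate_observations(
        config, genotypes, catalog, manifest, proteome, background, differential
    )
    return SimulatedScenario(
        config=config,
        proteome=proteome,
        snps=snps,
        background_accessions=background,
        differential_accessions=differential,
        manifest=manifest,
        genotypes=genotypes,
        catalog=catalog,
        observations=observations,
        truth=truth,
    )


def write_scenario(scenario: SimulatedScenario, out_dir) -> dict[str, Path]:
    """Write the scenario in the exact formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "snps": out / "snps.tsv",
        "manifest": out / "manifest.tsv",
        "genotypes": out / "genotypes.tsv",
        "psms": out / "psms.tsv",
        "truth": out / "truth.json",
    }
    iodata.write_fasta(scenario.proteome, paths["fasta"])
    iodata.write_snp_table(scenario.snps, paths["snps"])
    iodata.write_manifest(scenario.manifest, paths["manifest"])
    iodata.write_genotypes(scenario.genotypes, paths["genotypes"])
    iodata.write_psm_table(scenario.observations, paths["psms"])
    config_dict = asdict(scenario.config)
    config_dict["location_effects"] = dict(config_dict["location_effects"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"config": config_dict, **scenario.truth}, fh, indent=2, sort_keys=True
        )
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# exact detection-outcome enumeration (calibration oracle)
# ---------------------------------------------------------------------------

def category_distribution(
    genotype: Genotype, sensitivity: float, false_positive_rate: float = 0.0
) -> dict[PhenotypeCategory, float]:
    """Exact per-locus phenotype-category probabilities under the noise model.

    Each carried allele is detected independently with probability
    ``sensitivity``; each non-carried allele with ``false_positive_rate``.
    """
    p_major = sensitivity if genotype is not Genotype.minor_hom else false_positive_rate
    p_minor = sensitivity if genotype is not Genotype.major_hom else false_positive_rate
    dist: dict[PhenotypeCategory, float] = {}
    for major_detected, pm in ((True, p_major), (False, 1.0 - p_major)):
        for minor_detected, pn in ((True, p_minor), (False, 1.0 - p_minor)):
            category = categorize(major_detected, minor_detected)
            dist[category] = dist.get(category, 0.0) + pm * pn
    return dist


def replicate_mismatch_probability(
    genotype: Genotype, sensitivity: float, false_positive_rate: float = 0.0
) -> float:
    """Probability that two independent replicates disagree at one locus.

    Enumerates the 4x4 table of category pairs for two independent draws
    from :func:`category_distribution`: mismatch = 1 - sum of squared
    category probabilities.
    """
    dist = category_distribution(genotype, sensitivity, false_positive_rate)
    return 1.0 - sum(p * p for p in dist.values())
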