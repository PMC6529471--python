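"""Variant application, in-silico tryptic digestion, and GVP catalog construction.

A genetically variant peptide (GVP) is a proteolytic peptide that spans the
residue changed by a missense SNP. Each catalogued SNP yields two peptide
forms per digestion window: the *major* form carrying the major allele's
amino acid and the *minor* form carrying the minor allele's. Detecting either
form in a sample's peptide identifications infers the presence of the
corresponding allele.

The catalog builder substitutes each allele into the protein sequence,
digests both allele-specific sequences with trypsin rules (cleavage C-terminal
to K/R, optionally suppressed before proline), retains windows covering the
variant site, and flags windows whose two forms are indistinguishable in
practice:

* ``discriminative=False`` when the major and minor sequences are identical
  after collapsing isoleucine onto leucine (isobaric residues that CID/HCD
  fragmentation cannot tell apart);
* ``modification_confounded=True`` when deamidation (N→D or Q→E) of the
  opposite allele's peptide produces this allele's sequence at the variant
  site, so a detected peptide may be a chemical artifact rather than genetic
  evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# deamidation converts the key residue into the value; a peptide carrying the
# key plus the PTM is isobaric with the genomically encoded value
_DEAMIDATION = {"N": "D", "Q": "E"}

_FREQ_TOL = 1e-6


class CatalogError(ValueError):
    """Raised for invalid catalog inputs (missing accession, bad coordinates)."""


class ReferenceMismatchError(CatalogError):
    """Raised when the residue found in the sequence is not the expected allele."""


class AlleleType(str, Enum):
    major = "major"
    minor = "minor"


def il_normalize(sequence: str) -> str:
    """Collapse isoleucine onto leucine (isobaric; indistinguishable by MS/MS)."""
    return sequence.replace("I", "L")


@dataclass(frozen=True)
class MissenseSNP:
    """One missense SNP locus in protein coordinates with population frequencies.

    Parameters
    ----------
    snp_id : str
        Reference SNP id (``rs...``) or an HGVS genomic string for loci
        without one.
    gene : str
        Gene symbol.
    protein_accession : str
        Accession of the protein the residue coordinates refer to.
    residue_position : int
        1-based position of the polymorphic residue in the protein sequence.
    major_aa, minor_aa : str
        Single-letter amino acids of the major and minor alleles.
    genotype_freqs : tuple of float
        Population genotype frequencies ``(f_major_hom, f_het, f_minor_hom)``;
        must sum to 1 within 1e-6.
    """

    snp_id: str
    gene: str
    protein_accession: str
    residue_position: int
    major_aa: str
    minor_aa: str
    genotype_freqs: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype_freqs", tuple(float(f) for f in self.genotype_freqs))
        if self.major_aa not in AMINO_ACIDS or self.minor_aa not in AMINO_ACIDS:
            raise ValueError(
                f"{self.snp_id}: alleles must be single amino acids, "
                f"got {self.major_aa!r}/{self.minor_aa!r}"
            )
        if self.major_aa == self.minor_aa:
            raise ValueError(f"{self.snp_id}: major and minor alleles are identical")
        if self.residue_position < 1:
            raise ValueError(f"{self.snp_id}: residue_position must be >= 1")
        if len(self.genotype_freqs) != 3 or any(not 0.0 <= f <= 1.0 for f in self.genotype_freqs):
            raise ValueError(f"{self.snp_id}: genotype frequencies must be three reals in [0, 1]")
        if abs(sum(self.genotype_freqs) - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"{self.snp_id}: genotype frequencies sum to {sum(self.genotype_freqs):.8f}, not 1"
            )
        if self.maf > 0.5 + 1e-9:
            raise ValueError(
                f"{self.snp_id}: minor allele frequency {self.maf:.4f} exceeds 0.5; "
                "allele labels are likely swapped"
            )

    @property
    def maf(self) -> float:
        """Minor allele frequency implied by the genotype frequencies."""
        _, f_het, f_minor_hom = self.genotype_freqs
        return f_het / 2.0 + f_minor_hom

    def has_rsid(self) -> bool:
        return self.snp_id.startswith("rs")

    def allele_aa(self, allele: AlleleType) -> str:
        return self.major_aa if allele is AlleleType.major else self.minor_aa


@dataclass(frozen=True)
class GVPRecord:
    """One variant-peptide form (major or minor) for a SNP.

    ``start`` is the 1-based position of the peptide's first residue in the
    protein; ``variant_offset`` locates the polymorphic residue within the
    peptide (1-based). ``overlapping_snps`` lists other catalogued SNPs whose
    variant site falls inside this window — evidence from such a peptide is
    shared between loci and cannot be partitioned without haplotype data.
    """

    snp: MissenseSNP
    allele_type: AlleleType
    sequence: str
    start: int
    preceding_residue: str
    missed_cleavages: int
    semi_specific: bool = False
    discriminative: bool = True
    modification_confounded: bool = False
    overlapping_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        off = self.variant_offset
        if not 1 <= off <= len(self.sequence):
            raise ValueError(
                f"{self.snp.snp_id} {self.allele_type.value}: window "
                f"[{self.start}, {self.end}] does not cover residue {self.snp.residue_position}"
            )
        expected = self.snp.allele_aa(self.allele_type)
        if self.sequence[off - 1] != expected:
            raise ValueError(
                f"{self.snp.snp_id} {self.allele_type.value}: expected {expected} at "
                f"peptide offset {off}, found {self.sequence[off - 1]}"
            )

    @property
    def end(self) -> int:
        """1-based position of the peptide's last residue in the protein."""
        return self.start + len(self.sequence) - 1

    @property
    def variant_offset(self) -> int:
        return self.snp.residue_position - self.start + 1


# ---------------------------------------------------------------------------
# variant application
# ---------------------------------------------------------------------------

def apply_variant(sequence: str, position: int, ref_aa: str, alt_aa: str) -> str:
    """Substitute ``alt_aa`` at 1-based ``position``, checking the reference.

    The reference check guards against stale coordinates: the residue found
    at ``position`` must equal ``ref_aa`` or a :class:`ReferenceMismatchError`
    is raised naming both residues.
    """
    if not 1 <= position <= len(sequence):
        raise CatalogError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    found = sequence[position - 1]
    if found != ref_aa:
        raise ReferenceMismatchError(
            f"reference mismatch at position {position}: expected {ref_aa}, found {found}"
        )
    return sequence[: position - 1] + alt_aa + sequence[position:]


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def cleavage_sites(sequence: str, proline_rule: bool = False) -> list[int]:
    """0-based indices i such that trypsin cleaves between residues i and i+1.

    Cleavage occurs C-terminal to K or R; with ``proline_rule`` it is
    suppressed when the next residue is proline. The protein C-terminus is
    never a site (there is nothing to cleave off).
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P")
    ]


def digest(
    sequence: str, max_missed: int = 0, proline_rule: bool = False
) -> set[tuple[str, int, int]]:
    """Fully tryptic peptides of ``sequence`` with up to ``max_missed`` missed cleavages.

    Returns a set of ``(peptide, start, missed_cleavages)`` with 1-based
    ``start``. Both peptide termini coincide with cleavage boundaries or the
    protein's ends; ``missed_cleavages`` counts uncut internal K/R sites.
    Case-insensitive in the input; the empty sequence digests to the empty set.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = sequence.upper()
    if not seq:
        return set()
    bounds = [0] + [i + 1 for i in cleavage_sites(seq, proline_rule)] + [len(seq)]
    out: set[tuple[str, int, int]] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            out.add((seq[bounds[i] : bounds[j]], bounds[i] + 1, j - i - 1))
    return out


def _missed_in_window(sites: Sequence[int], start: int, end: int) -> int:
    """Number of cleavage sites strictly internal to the 1-based window [start, end]."""
    # a 0-based site i cleaves between residues i+1 and i+2 (1-based); it is
    # internal when start <= i+1 < end
    return sum(1 for i in sites if start <= i + 1 < end)


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def _site_windows(
    seq: str,
    pos: int,
    max_missed: int,
    proline_rule: bool,
    semi_specific: bool,
    min_length: int,
    max_length: int,
) -> dict[tuple[int, int], tuple[str, int, bool]]:
    """Map (start, end) -> (peptide, missed_cleavages, semi_specific) for windows covering pos."""
    sites = cleavage_sites(seq, proline_rule)
    windows: dict[tuple[int, int], tuple[str, int, bool]] = {}
    tryptic = [
        (pep, start, mc)
        for pep, start, mc in digest(seq, max_missed, proline_rule)
        if start <= pos <= start + len(pep) - 1
    ]
    for pep, start, mc in tryptic:
        if min_length <= len(pep) <= max_length:
            windows[(start, start + len(pep) - 1)] = (pep, mc, False)
    if semi_specific:
        for pep, start, _ in tryptic:
            end = start + len(pep) - 1
            # truncate from the N side (non-tryptic N-terminus, tryptic C-terminus)
            for new_start in range(start + 1, pos + 1):
                _add_semi(windows, seq, sites, new_start, end, min_length, max_length)
            # truncate from the C side (tryptic N-terminus, non-tryptic C-terminus)
            for new_end in range(pos, end):
                _add_semi(windows, seq, sites, start, new_end, min_length, max_length)
    return windows


def _add_semi(windows, seq, sites, start, end, min_length, max_length) -> None:
    if (start, end) in windows:
        return
    length = end - start + 1
    if not min_length <= length <= max_length:
        return
    mc = _missed_in_window(sites, start, end)
    windows[(start, end)] = (seq[start - 1 : end], mc, True)


def build_catalog(
    snps: Iterable[MissenseSNP],
    proteome: Mapping[str, str],
    *,
    max_missed: int = 3,
    proline_rule: bool = False,
    semi_specific: bool = False,
    min_length: int = 5,
    max_length: int = 50,
) -> list[GVPRecord]:
    """Derive the major/minor GVP catalog for every SNP.

    For each SNP both allele-specific sequences are digested and windows
    covering the variant site are paired by protein coordinates; each pair
    yields one major and one minor :class:`GVPRecord`. When the variant
    creates or destroys a K/R cleavage site the two digests differ; only
    windows present in both are emitted, so every emitted pair differs at
    exactly the variant site.
    """
    snps = list(snps)
    records: list[GVPRecord] = []
    for snp in snps:
        if snp.protein_accession not in proteome:
            raise CatalogError(
                f"SNP {snp.snp_id}: accession {snp.protein_accession!r} not in proteome"
            )
        ref = proteome[snp.protein_accession].upper()
        pos = snp.residue_position
        if pos > len(ref):
            raise CatalogError(
                f"SNP {snp.snp_id}: residue {pos} beyond {snp.protein_accession} "
                f"length {len(ref)}"
            )
        observed = ref[pos - 1]
        if observed == snp.major_aa:
            major_seq = ref
        elif observed == snp.minor_aa:
            major_seq = apply_variant(ref, pos, snp.minor_aa, snp.major_aa)
        else:
            raise ReferenceMismatchError(
                f"SNP {snp.snp_id}: residue at {snp.protein_accession}:{pos} is "
                f"{observed}, matching neither allele {snp.major_aa}/{snp.minor_aa}"
            )
        minor_seq = apply_variant(major_seq, pos, snp.major_aa, snp.minor_aa)

        per_allele = {
            AlleleType.major: _site_windows(
                major_seq, pos, max_missed, proline_rule, semi_specific, min_length, max_length
            ),
            AlleleType.minor: _site_windows(
                minor_seq, pos, max_missed, proline_rule, semi_specific, min_length, max_length
            ),
        }
        shared_windows = sorted(
            set(per_allele[AlleleType.major]) & set(per_allele[AlleleType.minor])
        )
        confounded = {
            # this allele's peptide can arise by deamidation of the other's
            AlleleType.minor: _DEAMIDATION.get(snp.major_aa) == snp.minor_aa,
            AlleleType.major: _DEAMIDATION.get(snp.minor_aa) == snp.major_aa,
        }
        for (start, end) in shared_windows:
            maj_pep, maj_mc, maj_semi = per_allele[AlleleType.major][(start, end)]
            min_pep, _, _ = per_allele[AlleleType.minor][(start, end)]
            disc = il_normalize(maj_pep) != il_normalize(min_pep)
            preceding = major_seq[start - 2] if start > 1 else "-"
            for allele, pep in ((AlleleType.major, maj_pep), (AlleleType.minor, min_pep)):
                records.append(
                    GVPRecord(
                        snp=snp,
                        allele_type=allele,
                        sequence=pep,
                        start=start,
                        preceding_residue=preceding,
                        missed_cleavages=maj_mc,
                        semi_specific=maj_semi,
                        discriminative=disc,
                        modification_confounded=confounded[allele],
                    )
                )

    records = _flag_overlaps(records, snps)
    records.sort(key=lambda r: (r.snp.snp_id, r.allele_type.value, r.start, len(r.sequence)))
    return records


def _flag_overlaps(records: list[GVPRecord], snps: Sequence[MissenseSNP]) -> list[GVPRecord]:
    """Mark windows containing the variant site of another catalogued SNP."""
    by_accession: dict[str, list[MissenseSNP]] = {}
    for snp in snps:
        by_accession.setdefault(snp.protein_accession, []).append(snp)
    out = []
    for rec in records:
        others = tuple(
            sorted(
                s.snp_id
                for s in by_accession.get(rec.snp.protein_accession, [])
                if s.snp_id != rec.snp.snp_id and rec.start <= s.residue_position <= rec.end
            )
        )
        out.append(replace(rec, overlapping_snps=others) if others else rec)
    return out


# ---------------------------------------------------------------------------
# catalog persistence (TSV)
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "snp_id",
    "gene",
    "allele_type",
    "peptide",
    "start",
    "preceding_residue",
    "missed_cleavages",
    "semi_specific",
    "discriminative",
    "modification_confounded",
    "overlapping_snps",
]


def write_catalog(records: Iterable[GVPRecord], path) -> None:
    rows = [
        {
            "snp_id": r.snp.snp_id,
            "gene": r.snp.gene,
            "allele_type": r.allele_type.value,
            "peptide": r.sequence,
            "start": r.start,
            "preceding_residue": r.preceding_residue,
            "missed_cleavages": r.missed_cleavages,
            "semi_specific": r.semi_specific,
            "discriminative": r.discriminative,
            "modification_confounded": r.modification_confounded,
            "overlapping_snps": ",".join(r.overlapping_snps),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path, snps: Iterable[MissenseSNP]) -> list[GVPRecord]:
    """Read a catalog TSV, reattaching :class:`MissenseSNP` objects by id."""
    by_id = {s.snp_id: s for s in snps}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        if row.snp_id not in by_id:
            raise CatalogError(f"catalog references unknown SNP {row.snp_id!r}")
        records.append(
            GVPRecord(
                snp=by_id[row.snp_id],
                allele_type=AlleleType(row.allele_type),
                sequence=row.peptide,
                start=int(row.start),
                preceding_residue=row.preceding_residue,
                missed_cleavages=int(row.missed_cleavages),
                semi_specific=row.semi_specific == "True",
                discriminative=row.discriminative == "True",
                modification_confounded=row.modification_confounded == "True",
                overlapping_snps=tuple(
                    s for s in row.overlapping_snps.split(",") if s
                ),
            )
        )
    return records
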