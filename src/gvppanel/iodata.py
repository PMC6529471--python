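"""Readers and writers for the pipeline's external formats.

All stage boundaries are plain text: FASTA for protein sequences, delimited
tables (TSV by default, CSV accepted) for SNP definitions, peptide-spectrum
matches, sample manifests and genotypes, and YAML for configuration. Readers
validate against the domain-type invariants and never drop rows silently:
every input row becomes either a returned record or a reported error.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .gvp_catalog import AMINO_ACIDS, MissenseSNP

logger = logging.getLogger(__name__)

DEFAULT_BODY_LOCATIONS = ("head", "arm", "pubic")


class ParseError(ValueError):
    """A file could not be parsed at all (structure, not content)."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration (dialect, column mapping, YAML) is invalid."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class Genotype(str, Enum):
    major_hom = "major_hom"
    het = "het"
    minor_hom = "minor_hom"


@dataclass(frozen=True)
class SampleKey:
    """One physical specimen: individual x body location x replicate."""

    sample_id: str
    individual_id: str
    body_location: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if int(self.replicate) < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be a positive integer")
        object.__setattr__(self, "replicate", int(self.replicate))


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one sample, with its precursor peak area.

    ``modifications`` is a tuple of ``(position, name)`` with 1-based
    positions inside the peptide; ``precursor_area`` is in arbitrary
    intensity units (0 when the export reported none).
    """

    sample_id: str
    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    protein_accessions: tuple[str, ...] = ()
    precursor_area: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.sample_id}: empty peptide sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{self.sample_id}: non-amino-acid characters {sorted(bad)} in "
                f"{self.sequence!r}"
            )
        for pos, name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValidationError(
                    f"{self.sample_id}: modification {name!r} position {pos} outside "
                    f"peptide of length {len(self.sequence)}"
                )
        if self.precursor_area < 0:
            raise ValidationError(f"{self.sample_id}: negative precursor area")
        object.__setattr__(self, "modifications", tuple(self.modifications))
        object.__setattr__(self, "protein_accessions", tuple(self.protein_accessions))


class GenotypeTable:
    """Mapping ``(individual_id, snp_id) -> Genotype``."""

    def __init__(self, entries: Mapping[tuple[str, str], Genotype] | None = None):
        self._entries: dict[tuple[str, str], Genotype] = dict(entries or {})

    def set(self, individual_id: str, snp_id: str, genotype: Genotype) -> None:
        self._entries[(individual_id, snp_id)] = Genotype(genotype)

    def get(self, individual_id: str, snp_id: str) -> Genotype:
        try:
            return self._entries[(individual_id, snp_id)]
        except KeyError:
            raise KeyError(
                f"no genotype for individual {individual_id!r} at SNP {snp_id!r}"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeTable) and self._entries == other._entries

    @property
    def individuals(self) -> list[str]:
        return sorted({ind for ind, _ in self._entries})

    @property
    def snp_ids(self) -> list[str]:
        return sorted({snp for _, snp in self._entries})

    def items(self):
        return self._entries.items()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into ``{accession: sequence}``.

    The accession is the first whitespace-delimited token of the header.
    Sequences are uppercased and validated against the 20-letter amino acid
    alphabet; duplicate accessions are rejected. An empty file yields an
    empty mapping with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped:
                if not stripped.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>'"
                    )
                break
        else:
            logger.warning("FASTA file %s is empty", path)
            return {}
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        sequence = str(record.seq).upper()
        if accession in proteome:
            raise ValidationError(f"{path}: duplicate accession {accession!r}")
        if not sequence:
            raise ValidationError(f"{path}: accession {accession!r} has an empty sequence")
        bad = set(sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"{path}: accession {accession!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        proteome[accession] = sequence
    return proteome


def write_fasta(proteome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for accession in proteome:
            fh.write(f">{accession}\n")
            seq = proteome[accession]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

@dataclass
class PSMDialect:
    """Column mapping and inline notations for a PSM export.

    Defaults fit the package's own TSV layout; override the column names (or
    load a YAML mapping with :meth:`from_yaml`) to consume other engines'
    exports without code change. Modifications use ``<AA><pos>:<name>``
    tokens (e.g. ``M7:Oxidation (M)``) joined by the modification separator;
    the residue letter is optional but checked against the peptide when given.
    """

    delimiter: str = "\t"
    sample_column: str = "sample_id"
    peptide_column: str = "peptide"
    modification_column: str = "modifications"
    accession_column: str = "accessions"
    area_column: str = "area"
    accession_separator: str = ";"
    modification_separator: str = ";"
    empty_tokens: tuple[str, ...] = ("", "-", "nan", "none")

    @classmethod
    def from_yaml(cls, path) -> "PSMDialect":
        data = load_config(path)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown PSM dialect keys: {sorted(unknown)}")
        for key in ("empty_tokens",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PSMReadResult:
    """Parsed observations plus per-row errors; rows read = records + errors."""

    observations: list[PeptideObservation]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.observations) + len(self.errors)


_MOD_TOKEN = re.compile(r"^\s*(?:([A-Za-z]))?(\d+)\s*:\s*(.+?)\s*$")


def strip_flanking_residues(token: str) -> str:
    """Strip single-character flank notation: ``R.LEGEINTYR.A`` -> ``LEGEINTYR``.

    A single leading ``X.`` and/or trailing ``.X`` (X one character, ``-`` for
    a protein terminus) is removed; anything else is returned unchanged.
    """
    peptide = token.strip()
    if len(peptide) > 2 and peptide[1] == ".":
        peptide = peptide[2:]
    if len(peptide) > 2 and peptide[-2] == ".":
        peptide = peptide[:-2]
    return peptide


def _parse_modifications(
    text: str, peptide: str, dialect: PSMDialect
) -> tuple[tuple[int, str], ...]:
    if text is None or str(text).strip().lower() in dialect.empty_tokens:
        return ()
    mods = []
    for token in str(text).split(dialect.modification_separator):
        if not token.strip():
            continue
        m = _MOD_TOKEN.match(token)
        if not m:
            raise ValidationError(f"unparseable modification token {token!r}")
        residue, pos_s, name = m.groups()
        pos = int(pos_s)
        if not 1 <= pos <= len(peptide):
            raise ValidationError(
                f"modification {token!r}: position {pos} outside peptide "
                f"{peptide!r}"
            )
        if residue and peptide[pos - 1] != residue.upper():
            raise ValidationError(
                f"modification {token!r}: residue {residue.upper()} does not match "
                f"peptide residue {peptide[pos - 1]} at position {pos}"
            )
        mods.append((pos, name))
    return tuple(mods)


def read_psm_table(path, dialect: PSMDialect | None = None) -> PSMReadResult:
    """Read a delimited PSM export into :class:`PeptideObservation` records.

    Rows whose modification string cannot be parsed (or that violate a type
    invariant) are collected as ``(row_index, message)`` errors and skipped;
    the count is logged. Rows with a missing or zero area are admitted with
    area 0.
    """
    dialect = dialect or PSMDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    required = {
        dialect.sample_column,
        dialect.peptide_column,
        dialect.modification_column,
        dialect.accession_column,
        dialect.area_column,
    }
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing mandatory PSM columns {sorted(missing)}")
    observations: list[PeptideObservation] = []
    errors: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            peptide = strip_flanking_residues(row[dialect.peptide_column])
            mods = _parse_modifications(row[dialect.modification_column], peptide, dialect)
            accessions = tuple(
                a.strip()
                for a in str(row[dialect.accession_column]).split(dialect.accession_separator)
                if a.strip()
            )
            area_text = str(row[dialect.area_column]).strip()
            area = 0.0 if area_text.lower() in dialect.empty_tokens else float(area_text)
            observations.append(
                PeptideObservation(
                    sample_id=str(row[dialect.sample_column]).strip(),
                    sequence=peptide,
                    modifications=mods,
                    protein_accessions=accessions,
                    precursor_area=area,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append((idx, str(exc)))
    if errors:
        logger.warning("%s: skipped %d of %d rows with errors", path, len(errors), len(df))
    return PSMReadResult(observations=observations, errors=errors)


def write_psm_table(
    observations: Iterable[PeptideObservation], path, dialect: PSMDialect | None = None
) -> None:
    dialect = dialect or PSMDialect()
    rows = [
        {
            dialect.sample_column: o.sample_id,
            dialect.peptide_column: o.sequence,
            dialect.modification_column: dialect.modification_separator.join(
                f"{o.sequence[pos - 1]}{pos}:{name}" for pos, name in o.modifications
            )
            or "-",
            dialect.accession_column: dialect.accession_separator.join(o.protein_accessions),
            dialect.area_column: repr(o.precursor_area),
        }
        for o in observations
    ]
    columns = [
        dialect.sample_column,
        dialect.peptide_column,
        dialect.modification_column,
        dialect.accession_column,
        dialect.area_column,
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=dialect.delimiter, index=False)


# ---------------------------------------------------------------------------
# SNP / manifest / genotype tables
# ---------------------------------------------------------------------------

_SNP_COLUMNS = [
    "snp_id",
    "gene",
    "protein_accession",
    "residue_position",
    "major_aa",
    "minor_aa",
    "f_major_hom",
    "f_het",
    "f_minor_hom",
]


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_snp_table(path) -> list[MissenseSNP]:
    """Read missense SNP definitions; genotype frequencies must sum to 1 ± 1e-6."""
    df = _read_table(path, _SNP_COLUMNS)
    snps = []
    for row in df.itertuples(index=False):
        try:
            snps.append(
                MissenseSNP(
                    snp_id=row.snp_id,
                    gene=row.gene,
                    protein_accession=row.protein_accession,
                    residue_position=int(row.residue_position),
                    major_aa=row.major_aa.strip().upper(),
                    minor_aa=row.minor_aa.strip().upper(),
                    genotype_freqs=(
                        float(row.f_major_hom),
                        float(row.f_het),
                        float(row.f_minor_hom),
                    ),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: SNP {row.snp_id!r}: {exc}") from exc
    seen: set[str] = set()
    for snp in snps:
        if snp.snp_id in seen:
            raise ValidationError(f"{path}: duplicate SNP id {snp.snp_id!r}")
        seen.add(snp.snp_id)
    return snps


def write_snp_table(snps: Iterable[MissenseSNP], path) -> None:
    rows = [
        {
            "snp_id": s.snp_id,
            "gene": s.gene,
            "protein_accession": s.protein_accession,
            "residue_position": s.residue_position,
            "major_aa": s.major_aa,
            "minor_aa": s.minor_aa,
            "f_major_hom": repr(s.genotype_freqs[0]),
            "f_het": repr(s.genotype_freqs[1]),
            "f_minor_hom": repr(s.genotype_freqs[2]),
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=_SNP_COLUMNS).to_csv(path, sep="\t", index=False)


_MANIFEST_COLUMNS = ["sample_id", "individual_id", "body_location", "replicate"]


def read_manifest(
    path,
    locations: Sequence[str] = DEFAULT_BODY_LOCATIONS,
    extensible: bool = False,
) -> list[SampleKey]:
    """Read the sample manifest, enforcing uniqueness of sample ids and design keys."""
    df = _read_table(path, _MANIFEST_COLUMNS)
    manifest = []
    for row in df.itertuples(index=False):
        loc = row.body_location.strip()
        if loc not in locations and not extensible:
            raise ValidationError(
                f"{path}: unknown body location {loc!r} for sample {row.sample_id!r} "
                f"(known: {list(locations)}; pass extensible=True to accept)"
            )
        manifest.append(
            SampleKey(
                sample_id=row.sample_id.strip(),
                individual_id=row.individual_id.strip(),
                body_location=loc,
                replicate=int(row.replicate),
            )
        )
    ids = [s.sample_id for s in manifest]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dup}")
    keys = [(s.individual_id, s.body_location, s.replicate) for s in manifest]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{path}: duplicate (individual, location, replicate) keys")
    return manifest


def write_manifest(manifest: Iterable[SampleKey], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "individual_id": s.individual_id,
            "body_location": s.body_location,
            "replicate": s.replicate,
        }
        for s in manifest
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


_GENOTYPE_COLUMNS = ["individual_id", "snp_id", "genotype"]


def read_genotypes(path) -> GenotypeTable:
    df = _read_table(path, _GENOTYPE_COLUMNS)
    table = GenotypeTable()
    for row in df.itertuples(index=False):
        try:
            genotype = Genotype(row.genotype.strip())
        except ValueError:
            raise ValidationError(
                f"{path}: unknown genotype {row.genotype!r} for "
                f"({row.individual_id}, {row.snp_id}); expected one of "
                f"{[g.value for g in Genotype]}"
            ) from None
        key = (row.individual_id.strip(), row.snp_id.strip())
        if key in table:
            raise ValidationError(f"{path}: duplicate genotype entry for {key}")
        table.set(*key, genotype)
    return table


def write_genotypes(table: GenotypeTable, path) -> None:
    rows = [
        {"individual_id": ind, "snp_id": snp, "genotype": g.value}
        for (ind, snp), g in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=_GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top-level YAML must be a mapping")
    return data
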