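"""Match observed peptides to the GVP catalog and summarise per-sample profiles.

Detection is presence/absence: a GVP counts as detected in a sample when any
observed peptide's bare sequence (modifications stripped) equals the GVP
sequence, by default under I/L equivalence. Precursor areas play no role
here; they feed the abundance module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .gvp_catalog import AlleleType, GVPRecord, il_normalize
from .iodata import PeptideObservation

logger = logging.getLogger(__name__)


class PhenotypeCategory(str, Enum):
    both = "both"
    major_only = "major_only"
    minor_only = "minor_only"
    absent = "absent"


def categorize(major_detected: bool, minor_detected: bool) -> PhenotypeCategory:
    if major_detected and minor_detected:
        return PhenotypeCategory.both
    if major_detected:
        return PhenotypeCategory.major_only
    if minor_detected:
        return PhenotypeCategory.minor_only
    return PhenotypeCategory.absent


@dataclass(frozen=True)
class DetectionState:
    """Per (sample, SNP) detection booleans for the two GVP forms."""

    sample_id: str
    snp_id: str
    major_detected: bool
    minor_detected: bool

    @property
    def phenotype_category(self) -> PhenotypeCategory:
        return categorize(self.major_detected, self.minor_detected)


@dataclass(frozen=True)
class ProfileMetrics:
    """Per-sample protein-profile summary counts.

    ``n_amino_acids`` is the summed length of the distinct peptide sequences,
    i.e. the amino acids contributed by unique peptides.
    """

    sample_id: str
    n_proteins: int
    n_unique_peptides: int
    n_amino_acids: int
    n_snps_major: int
    n_snps_minor: int

    def __post_init__(self) -> None:
        if min(
            self.n_proteins,
            self.n_unique_peptides,
            self.n_amino_acids,
            self.n_snps_major,
            self.n_snps_minor,
        ) < 0:
            raise ValueError("profile metric counts must be non-negative")


def _has_deamidation_at(obs: PeptideObservation, offset: int) -> bool:
    return any(pos == offset and "deamid" in name.lower() for pos, name in obs.modifications)


def match_observations(
    observations: Iterable[PeptideObservation],
    catalog: Sequence[GVPRecord],
    *,
    il_equiv: bool = True,
    strict_confounded: bool = False,
    sample_ids: Sequence[str] | None = None,
) -> list[DetectionState]:
    """Produce one :class:`DetectionState` per (sample, catalogued SNP).

    A GVP form is detected when any observation's sequence equals a catalog
    record for that form, compared after I/L normalization when ``il_equiv``.
    With ``strict_confounded``, a record flagged ``modification_confounded``
    is only credited by observations carrying no deamidation at the variant
    site, so chemically deamidated peptides cannot masquerade as the variant.

    ``sample_ids`` fixes the set of samples reported (e.g. the manifest);
    samples without observations then yield all-absent states. By default the
    samples present in the observations are reported.
    """
    norm = il_normalize if il_equiv else (lambda s: s)
    by_sample: dict[str, dict[str, list[PeptideObservation]]] = {}
    for obs in observations:
        by_sample.setdefault(obs.sample_id, {}).setdefault(norm(obs.sequence), []).append(obs)
    samples = list(sample_ids) if sample_ids is not None else sorted(by_sample)

    snp_ids: list[str] = []
    for rec in catalog:
        if rec.snp.snp_id not in snp_ids:
            snp_ids.append(rec.snp.snp_id)

    states = []
    for sample in samples:
        seq_index = by_sample.get(sample, {})
        detected: dict[tuple[str, AlleleType], bool] = {}
        for rec in catalog:
            key = (rec.snp.snp_id, rec.allele_type)
            if detected.get(key):
                continue
            candidates = seq_index.get(norm(rec.sequence), [])
            if strict_confounded and rec.modification_confounded:
                candidates = [
                    o for o in candidates if not _has_deamidation_at(o, rec.variant_offset)
                ]
            if candidates:
                detected[key] = True
        for snp_id in snp_ids:
            states.append(
                DetectionState(
                    sample_id=sample,
                    snp_id=snp_id,
                    major_detected=detected.get((snp_id, AlleleType.major), False),
                    minor_detected=detected.get((snp_id, AlleleType.minor), False),
                )
            )
    return states


def profile_metrics(
    observations: Iterable[PeptideObservation],
    states: Iterable[DetectionState] = (),
    sample_id: str | None = None,
) -> ProfileMetrics:
    """Summary counts for one sample's observations (and its detection states).

    All observations must share one sample id; an empty observation list
    yields all-zero counts (pass ``sample_id`` to label it).
    """
    observations = list(observations)
    sample_ids = {o.sample_id for o in observations}
    if len(sample_ids) > 1:
        raise ValueError(f"observations span multiple samples: {sorted(sample_ids)}")
    if sample_id is None:
        sample_id = next(iter(sample_ids), "")
    sequences = {o.sequence for o in observations}
    accessions = {acc for o in observations for acc in o.protein_accessions}
    states = [s for s in states if s.sample_id == sample_id]
    return ProfileMetrics(
        sample_id=sample_id,
        n_proteins=len(accessions),
        n_unique_peptides=len(sequences),
        n_amino_acids=sum(len(s) for s in sequences),
        n_snps_major=sum(1 for s in states if s.major_detected),
        n_snps_minor=sum(1 for s in states if s.minor_detected),
    )


def metrics_table(
    observations: Iterable[PeptideObservation],
    states: Iterable[DetectionState] = (),
    sample_ids: Sequence[str] | None = None,
) -> list[ProfileMetrics]:
    """:func:`profile_metrics` per sample, over a mixed-sample observation list."""
    observations = list(observations)
    states = list(states)
    by_sample: dict[str, list[PeptideObservation]] = {}
    for obs in observations:
        by_sample.setdefault(obs.sample_id, []).append(obs)
    samples = list(sample_ids) if sample_ids is not None else sorted(by_sample)
    return [
        profile_metrics(by_sample.get(s, []), states, sample_id=s) for s in samples
    ]


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_STATE_COLUMNS = ["sample_id", "snp_id", "major_detected", "minor_detected"]


def write_detection_states(states: Iterable[DetectionState], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "snp_id": s.snp_id,
            "major_detected": s.major_detected,
            "minor_detected": s.minor_detected,
        }
        for s in states
    ]
    pd.DataFrame(rows, columns=_STATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_detection_states(path) -> list[DetectionState]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        DetectionState(
            sample_id=row.sample_id,
            snp_id=row.snp_id,
            major_detected=row.major_detected == "True",
            minor_detected=row.minor_detected == "True",
        )
        for row in df.itertuples(index=False)
    ]


def write_metrics(metrics: Iterable[ProfileMetrics], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "n_proteins": m.n_proteins,
            "n_unique_peptides": m.n_unique_peptides,
            "n_amino_acids": m.n_amino_acids,
            "n_snps_major": m.n_snps_major,
            "n_snps_minor": m.n_snps_minor,
        }
        for m in metrics
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "n_proteins",
            "n_unique_peptides",
            "n_amino_acids",
            "n_snps_major",
            "n_snps_minor",
        ],
    ).to_csv(path, sep="\t", index=False)
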