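"""Exome-proteome consistency classification and SNP panel selection.

Each detection state is scored against the individual's exome genotype,
per allele: an allele is *present* in the genotype unless the individual is
homozygous for the other allele, and the call is

====================  ==========  ====
allele in genotype    detected    call
====================  ==========  ====
present               yes         TP
present               no          FN
absent                yes         FP
absent                no          TN
====================  ==========  ====

Panel selection applies ordered filters: SNPs with any false-positive call
are removed; SNPs whose calls are all TP/TN across every sample for at least
one allele type are kept; the surviving major- and minor-consistent loci are
merged; loci without a reference SNP id are dropped (no population genotype
frequencies); and within each gene only the SNP with the lowest minor allele
frequency is retained, a conservative guard against linkage disequilibrium
between markers used in a product-rule match probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detection import DetectionState
from .gvp_catalog import AlleleType, MissenseSNP
from .iodata import Genotype, GenotypeTable, SampleKey


class Call(str, Enum):
    TP = "TP"
    TN = "TN"
    FP = "FP"
    FN = "FN"


@dataclass(frozen=True)
class ConsistencyCall:
    sample_id: str
    snp_id: str
    allele_type: AlleleType
    call: Call


def allele_present(genotype: Genotype, allele: AlleleType) -> bool:
    """Whether the genotype carries the allele (het carries both)."""
    if allele is AlleleType.major:
        return genotype is not Genotype.minor_hom
    return genotype is not Genotype.major_hom


def classify(
    states: Iterable[DetectionState],
    genotypes: GenotypeTable,
    manifest: Sequence[SampleKey],
) -> list[ConsistencyCall]:
    """Two calls (major, minor) per detection state against the exome genotype.

    Raises ``KeyError`` naming the (individual, SNP) pair when a genotype is
    missing.
    """
    individual_of = {s.sample_id: s.individual_id for s in manifest}
    calls = []
    for state in states:
        if state.sample_id not in individual_of:
            raise KeyError(f"sample {state.sample_id!r} not in manifest")
        individual = individual_of[state.sample_id]
        genotype = genotypes.get(individual, state.snp_id)
        for allele, detected in (
            (AlleleType.major, state.major_detected),
            (AlleleType.minor, state.minor_detected),
        ):
            present = allele_present(genotype, allele)
            if present:
                call = Call.TP if detected else Call.FN
            else:
                call = Call.FP if detected else Call.TN
            calls.append(
                ConsistencyCall(
                    sample_id=state.sample_id,
                    snp_id=state.snp_id,
                    allele_type=allele,
                    call=call,
                )
            )
    return calls


_CONSISTENT = frozenset({Call.TP, Call.TN})


def consistent_snps(
    calls: Iterable[ConsistencyCall],
    manifest: Sequence[SampleKey],
    scope: str = "per_location",
) -> dict[str, dict[str, set[str]]] | dict[str, set[str]]:
    """SNPs whose calls are all TP/TN within scope, per allele type.

    With ``scope="per_location"`` returns ``{allele: {location: set of snp_id}}``
    where a SNP qualifies when every call from samples at that location is
    consistent. With ``scope="all_samples"`` returns ``{allele: set}`` over
    all samples (the intersection across locations).
    """
    location_of = {s.sample_id: s.body_location for s in manifest}
    locations = sorted({s.body_location for s in manifest})
    # (allele, location, snp) -> all consistent so far
    clean: dict[tuple[str, str, str], bool] = {}
    seen_snps: set[str] = set()
    for call in calls:
        loc = location_of[call.sample_id]
        key = (call.allele_type.value, loc, call.snp_id)
        clean[key] = clean.get(key, True) and call.call in _CONSISTENT
        seen_snps.add(call.snp_id)
    per_location = {
        allele.value: {
            loc: {
                snp
                for snp in seen_snps
                if clean.get((allele.value, loc, snp), False)
            }
            for loc in locations
        }
        for allele in AlleleType
    }
    if scope == "per_location":
        return per_location
    if scope == "all_samples":
        return {
            allele: set.intersection(*per_location[allele].values())
            if per_location[allele]
            else set()
            for allele in per_location
        }
    raise ValueError(f"unknown scope {scope!r}")


@dataclass
class PanelReport:
    """Panel membership plus the per-filter counts and per-SNP provenance."""

    n_input: int
    n_after_fp_removal: int
    consistent_by_location: dict
    n_consistent_major: int
    n_consistent_minor: int
    n_after_overlap: int
    n_after_rsid: int
    panel: list[str]
    provenance: dict[str, str] = field(default_factory=dict)


def select_panel(
    calls: Iterable[ConsistencyCall],
    snps: Iterable[MissenseSNP],
    manifest: Sequence[SampleKey] | None = None,
) -> PanelReport:
    """Apply the ordered panel filters and record every exclusion's reason.

    Filters: (1) remove SNPs with any FP call; (2) keep SNPs with all-TP/TN
    calls across all samples for the major or the minor allele; (3) merge the
    two allele-type lists into one locus list; (4) drop loci without an rsID;
    (5) keep the lowest-MAF SNP per gene (ties broken by lexicographically
    smallest snp_id). Deterministic and invariant to input row order.
    """
    calls = list(calls)
    snp_by_id = {s.snp_id: s for s in snps}
    call_snps = sorted({c.snp_id for c in calls})
    unknown = [s for s in call_snps if s not in snp_by_id]
    if unknown:
        raise KeyError(f"calls reference SNPs missing from the SNP table: {unknown}")
    provenance: dict[str, str] = {}

    # filter 1: any false-positive call anywhere disqualifies the SNP
    fp_snps = {c.snp_id for c in calls if c.call is Call.FP}
    survivors = [s for s in call_snps if s not in fp_snps]
    for snp in sorted(fp_snps):
        provenance[snp] = "removed: false positive call(s)"

    # filter 2: all-sample consistency for at least one allele type
    clean: dict[tuple[str, str], bool] = {}
    for c in calls:
        key = (c.snp_id, c.allele_type.value)
        clean[key] = clean.get(key, True) and c.call in _CONSISTENT
    consistent_major = {s for s in survivors if clean.get((s, "major"), False)}
    consistent_minor = {s for s in survivors if clean.get((s, "minor"), False)}
    merged = sorted(consistent_major | consistent_minor)  # filter 3: overlap merge
    for snp in survivors:
        if snp not in merged:
            provenance[snp] = "removed: inconsistent across samples for both allele types"

    # filter 4: population frequencies require a reference SNP id
    with_rsid = [s for s in merged if snp_by_id[s].has_rsid()]
    for snp in merged:
        if snp not in with_rsid:
            provenance[snp] = "removed: no reference SNP id"

    # filter 5: one SNP per gene, lowest minor allele frequency wins
    by_gene: dict[str, list[str]] = {}
    for snp in with_rsid:
        by_gene.setdefault(snp_by_id[snp].gene, []).append(snp)
    panel = []
    for gene in sorted(by_gene):
        ranked = sorted(by_gene[gene], key=lambda s: (snp_by_id[s].maf, s))
        panel.append(ranked[0])
        for snp in ranked[1:]:
            provenance[snp] = (
                f"removed: gene {gene} already represented by lower-MAF {ranked[0]}"
            )
    panel.sort()
    for snp in panel:
        via = []
        if snp in consistent_major:
            via.append("major")
        if snp in consistent_minor:
            via.append("minor")
        provenance[snp] = f"retained: panel member (consistent via {'/'.join(via)})"

    by_location = (
        consistent_snps(calls, manifest, scope="per_location") if manifest else {}
    )
    return PanelReport(
        n_input=len(call_snps),
        n_after_fp_removal=len(survivors),
        consistent_by_location={
            allele: {loc: sorted(v) for loc, v in locs.items()}
            for allele, locs in by_location.items()
        },
        n_consistent_major=len(consistent_major),
        n_consistent_minor=len(consistent_minor),
        n_after_overlap=len(merged),
        n_after_rsid=len(with_rsid),
        panel=panel,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_calls(calls: Iterable[ConsistencyCall], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "snp_id": c.snp_id,
            "allele_type": c.allele_type.value,
            "call": c.call.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample_id", "snp_id", "allele_type", "call"]).to_csv(
        path, sep="\t", index=False
    )


def read_calls(path) -> list[ConsistencyCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ConsistencyCall(
            sample_id=row.sample_id,
            snp_id=row.snp_id,
            allele_type=AlleleType(row.allele_type),
            call=Call(row.call),
        )
        for row in df.itertuples(index=False)
    ]


def write_panel_report(report: PanelReport, tsv_path, json_path=None) -> None:
    rows = [
        {"snp_id": snp, "decision": reason}
        for snp, reason in sorted(report.provenance.items())
    ]
    pd.DataFrame(rows, columns=["snp_id", "decision"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if json_path is not None:
        payload = {
            "n_input": report.n_input,
            "n_after_fp_removal": report.n_after_fp_removal,
            "consistent_by_location": report.consistent_by_location,
            "n_consistent_major": report.n_consistent_major,
            "n_consistent_minor": report.n_consistent_minor,
            "n_after_overlap": report.n_after_overlap,
            "n_after_rsid": report.n_after_rsid,
            "panel": report.panel,
            "provenance": report.provenance,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
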