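"""Label-free protein quantification and the downstream statistical screens.

Quantification follows the normalized precursor-area scheme: within each
sample, duplicate peptide observations are collapsed to unique sequences
(keeping the maximum area, robust to repeat sampling of one precursor), each
unique peptide's area is divided by the sample's total unique-peptide area —
removing bias from unequal on-column mass loadings — and a protein's
abundance is the sum of the normalized areas of its assigned peptides.
Peptides shared between accessions contribute to each (and are flagged), as
no parsimony razor is applied; a unique-only mode is available.

Two screens operate on the resulting table: a per-protein two-factor
analysis of variance (body location x individual, with interaction) with
Tukey HSD post-hoc location contrasts, and a per-SNP one-sided Pearson
correlation between SNP identification frequency and mean protein abundance
across (individual, location) groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import DetectionState
from .gvp_catalog import MissenseSNP
from .iodata import PeptideObservation, SampleKey

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTable:
    """Normalized protein abundances per sample.

    ``abundances`` is a samples x proteins frame of dimensionless fractions;
    ``peptide_fractions`` maps each sample to its per-peptide normalized
    areas (these sum to 1 by construction); ``totals`` holds the raw
    per-sample total areas; ``shared_peptides`` lists sequences assigned to
    more than one accession.
    """

    abundances: pd.DataFrame
    peptide_fractions: dict[str, pd.Series]
    totals: pd.Series
    shared_peptides: frozenset[str]


def normalize_and_rollup(
    observations: Iterable[PeptideObservation],
    *,
    shared_policy: str = "all",
) -> AbundanceTable:
    """Normalize precursor areas per sample and roll peptides up to proteins.

    ``shared_policy="all"`` credits a shared peptide to every mapped
    accession; ``"unique_only"`` drops shared peptides from the rollup (they
    still count in the normalizing denominator, which is defined over unique
    peptide sequences once per sample). Samples with zero total area are
    excluded with a warning.
    """
    if shared_policy not in ("all", "unique_only"):
        raise ValueError(f"unknown shared_policy {shared_policy!r}")
    per_sample: dict[str, dict[str, float]] = {}
    accessions_of: dict[tuple[str, str], set[str]] = {}
    for obs in observations:
        areas = per_sample.setdefault(obs.sample_id, {})
        areas[obs.sequence] = max(areas.get(obs.sequence, 0.0), obs.precursor_area)
        accessions_of.setdefault((obs.sample_id, obs.sequence), set()).update(
            obs.protein_accessions
        )
    shared = frozenset(
        seq for (_, seq), accs in accessions_of.items() if len(accs) > 1
    )
    rows: dict[str, dict[str, float]] = {}
    peptide_fractions: dict[str, pd.Series] = {}
    totals: dict[str, float] = {}
    for sample in sorted(per_sample):
        areas = per_sample[sample]
        total = sum(areas.values())
        if total <= 0.0:
            logger.warning("sample %s has zero total peptide area; excluded", sample)
            continue
        fractions = {seq: area / total for seq, area in areas.items()}
        peptide_fractions[sample] = pd.Series(fractions, dtype=float).sort_index()
        totals[sample] = total
        protein_abundance: dict[str, float] = {}
        for seq, fraction in fractions.items():
            if shared_policy == "unique_only" and seq in shared:
                continue
            for accession in accessions_of[(sample, seq)]:
                protein_abundance[accession] = (
                    protein_abundance.get(accession, 0.0) + fraction
                )
        rows[sample] = protein_abundance
    abundances = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0.0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return AbundanceTable(
        abundances=abundances,
        peptide_fractions=peptide_fractions,
        totals=pd.Series(totals, dtype=float).sort_index(),
        shared_peptides=shared,
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def differential_expression(
    table: AbundanceTable,
    manifest: Sequence[SampleKey],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein two-factor ANOVA (location, individual, interaction).

    Proteins missing from a sample enter as abundance 0, so
    presence/absence-like proteins are compared rather than skipped. Tukey
    HSD post-hoc contrasts between locations are reported (with star levels
    for p <= 0.05 / 0.01 / 0.001) when the location effect is significant at
    ``alpha``. Constant-abundance proteins are reported with a note instead
    of a fit.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    samples = [s.sample_id for s in manifest if s.sample_id in table.abundances.index]
    if len(samples) < len(manifest):
        dropped = sorted({s.sample_id for s in manifest} - set(samples))
        logger.warning("manifest samples without abundances excluded: %s", dropped)
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in manifest if s.sample_id in samples],
            "location": [s.body_location for s in manifest if s.sample_id in samples],
            "individual": [s.individual_id for s in manifest if s.sample_id in samples],
        }
    ).set_index("sample_id")
    if meta["location"].nunique() < 2 or meta["individual"].nunique() < 2:
        raise ValueError("differential expression requires >= 2 levels per factor")
    results = []
    for protein in table.abundances.columns:
        values = table.abundances[protein].reindex(samples).fillna(0.0)
        row = {
            "protein": protein,
            "F_location": np.nan,
            "p_location": np.nan,
            "F_individual": np.nan,
            "p_individual": np.nan,
            "F_interaction": np.nan,
            "p_interaction": np.nan,
            "significant_location": False,
            "contrasts": "",
            "note": "",
        }
        if np.ptp(values.to_numpy()) == 0.0:
            row["note"] = "constant abundance; skipped"
            results.append(row)
            continue
        frame = meta.copy()
        frame["abundance"] = values
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.ols(
                    "abundance ~ C(location) * C(individual)", data=frame
                ).fit()
                anova = anova_lm(fit, typ=2)
        except Exception as exc:  # degenerate design for this protein
            row["note"] = f"ANOVA failed: {exc}"
            results.append(row)
            continue
        row["F_location"] = float(anova.loc["C(location)", "F"])
        row["p_location"] = float(anova.loc["C(location)", "PR(>F)"])
        row["F_individual"] = float(anova.loc["C(individual)", "F"])
        row["p_individual"] = float(anova.loc["C(individual)", "PR(>F)"])
        row["F_interaction"] = float(anova.loc["C(location):C(individual)", "F"])
        row["p_interaction"] = float(anova.loc["C(location):C(individual)", "PR(>F)"])
        if np.isfinite(row["p_location"]) and row["p_location"] <= alpha:
            row["significant_location"] = True
            tukey = pairwise_tukeyhsd(
                frame["abundance"].to_numpy(), frame["location"].to_numpy(), alpha=alpha
            )
            means = frame.groupby("location")["abundance"].mean()
            contrasts = []
            summary = pd.DataFrame(
                tukey.summary().data[1:], columns=tukey.summary().data[0]
            )
            for _, trow in summary.iterrows():
                if bool(trow["reject"]):
                    g1, g2 = str(trow["group1"]), str(trow["group2"])
                    hi, lo = (g1, g2) if means[g1] > means[g2] else (g2, g1)
                    contrasts.append(f"{hi}>{lo}{_stars(float(trow['p-adj']))}")
            row["contrasts"] = ";".join(contrasts)
        results.append(row)
    return pd.DataFrame(results).set_index("protein")


# ---------------------------------------------------------------------------
# SNP identification frequency vs protein abundance
# ---------------------------------------------------------------------------

def snp_abundance_correlation(
    states: Iterable[DetectionState],
    table: AbundanceTable,
    manifest: Sequence[SampleKey],
    snps: Sequence[MissenseSNP],
    min_points: int = 3,
) -> pd.DataFrame:
    """Per SNP: one-sided Pearson test for a positive association between the
    fraction of replicates detecting the SNP and the mean abundance of its
    protein, across (individual, body location) groups.

    Groups are the replicate sets of each individual at each location; the
    identification frequency is the fraction of a group's replicates in which
    either GVP form was detected. SNPs with fewer than ``min_points`` groups
    or zero variance on either axis are reported with r = NaN and a note.
    """
    detected: dict[tuple[str, str], bool] = {}
    for s in states:
        detected[(s.sample_id, s.snp_id)] = s.major_detected or s.minor_detected
    groups: dict[tuple[str, str], list[str]] = {}
    for sample in manifest:
        groups.setdefault((sample.individual_id, sample.body_location), []).append(
            sample.sample_id
        )
    rows = []
    for snp in snps:
        freqs, abunds = [], []
        for (_, _), sample_ids in sorted(groups.items()):
            freqs.append(
                float(np.mean([detected.get((sid, snp.snp_id), False) for sid in sample_ids]))
            )
            if snp.protein_accession in table.abundances.columns:
                present = [
                    sid for sid in sample_ids if sid in table.abundances.index
                ]
                abunds.append(
                    float(table.abundances.loc[present, snp.protein_accession].mean())
                    if present
                    else 0.0
                )
            else:
                abunds.append(0.0)
        row = {
            "snp_id": snp.snp_id,
            "protein_accession": snp.protein_accession,
            "n_groups": len(freqs),
            "r": np.nan,
            "p_one_sided": np.nan,
            "note": "",
        }
        if len(freqs) < min_points:
            row["note"] = f"fewer than {min_points} groups"
        elif np.ptp(freqs) == 0.0 or np.ptp(abunds) == 0.0:
            row["note"] = "undefined: zero variance"
        else:
            r, p = stats.pearsonr(freqs, abunds, alternative="greater")
            row["r"] = float(r)
            row["p_one_sided"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("snp_id")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_abundance_table(table: AbundanceTable, path) -> None:
    table.abundances.rename_axis("sample_id").to_csv(path, sep="\t")


def read_abundance_table(path) -> AbundanceTable:
    """Read a written abundance matrix (peptide-level detail is not persisted)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return AbundanceTable(
        abundances=df,
        peptide_fractions={},
        totals=pd.Series(dtype=float),
        shared_peptides=frozenset(),
    )
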