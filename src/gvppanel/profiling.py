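"""GVP profiles, observed phenotype frequencies, random match probabilities,
and pairwise profile comparison statistics.

A sample's GVP profile records, at each panel locus, which peptide forms were
detected (both, major only, minor only, or neither) and the population
frequency of the phenotype consistent with that observation:

* only the major GVP detected — the individual could be major-homozygous or
  heterozygous, so the observed phenotype frequency is
  ``f_major_hom + f_het``;
* only the minor GVP detected — ``f_minor_hom + f_het``;
* both forms detected — only the heterozygote is consistent, ``f_het``;
* neither detected — the locus is uninformative and carries no frequency.

The random match probability (RMP) of a profile is the product of the
observed phenotype frequencies over its non-absent loci, assuming
independence between loci (supported upstream by the one-SNP-per-gene panel
rule). Profile similarity is quantified as the number of loci at which two
profiles' phenotype categories differ; a detected-vs-absent disagreement
counts as a difference even though absent loci are skipped in the RMP.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import DetectionState, PhenotypeCategory
from .gvp_catalog import MissenseSNP
from .iodata import Genotype, GenotypeTable, SampleKey

logger = logging.getLogger(__name__)


class AllAbsentProfileError(ValueError):
    """Raised when an RMP is requested for a profile with no detected locus."""


class ComparisonCategory(str, Enum):
    replicate = "replicate"
    within_individual = "within_individual"
    between_individual = "between_individual"


@dataclass(frozen=True)
class GVPProfile:
    """Ordered per-locus phenotype categories and observed phenotype frequencies.

    ``entries`` maps snp_id to ``(category, frequency)``; the frequency is
    ``None`` exactly when the category is ``absent``.
    """

    sample: SampleKey
    entries: Mapping[str, tuple[PhenotypeCategory, float | None]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for snp_id, (category, freq) in self.entries.items():
            if (freq is None) != (category is PhenotypeCategory.absent):
                raise ValueError(
                    f"{self.sample.sample_id}/{snp_id}: frequency must be present "
                    "iff the category is not absent"
                )
            if freq is not None and not 0.0 < freq <= 1.0:
                raise ValueError(
                    f"{self.sample.sample_id}/{snp_id}: frequency {freq} outside (0, 1]"
                )

    @property
    def loci(self) -> list[str]:
        return list(self.entries)

    def category(self, snp_id: str) -> PhenotypeCategory:
        return self.entries[snp_id][0]


@dataclass(frozen=True)
class ProfileComparison:
    sample_a: SampleKey
    sample_b: SampleKey
    category: ComparisonCategory
    n_differences: int

    @property
    def individual_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.sample_a.individual_id, self.sample_b.individual_id)))


# ---------------------------------------------------------------------------
# phenotype frequencies and profiles
# ---------------------------------------------------------------------------

def phenotype_frequency(
    category: PhenotypeCategory, genotype_freqs: Sequence[float]
) -> float | None:
    """Population frequency of the genotypes consistent with a detection pattern.

    ``genotype_freqs`` is ``(f_major_hom, f_het, f_minor_hom)``. Returns
    ``None`` for an absent locus, which is not scored.
    """
    f_major_hom, f_het, f_minor_hom = genotype_freqs
    if category is PhenotypeCategory.major_only:
        return f_major_hom + f_het
    if category is PhenotypeCategory.minor_only:
        return f_minor_hom + f_het
    if category is PhenotypeCategory.both:
        return f_het
    return None


def build_profile(
    sample: SampleKey,
    states: Iterable[DetectionState],
    panel: Sequence[MissenseSNP],
) -> GVPProfile:
    """Assemble the sample's profile over the panel loci from detection states.

    Panel loci without a detection state are recorded as absent.
    """
    by_snp = {
        s.snp_id: s for s in states if s.sample_id == sample.sample_id
    }
    entries = {}
    for snp in panel:
        state = by_snp.get(snp.snp_id)
        category = state.phenotype_category if state else PhenotypeCategory.absent
        entries[snp.snp_id] = (category, phenotype_frequency(category, snp.genotype_freqs))
    return GVPProfile(sample=sample, entries=entries)


_GENOTYPE_CATEGORY = {
    Genotype.major_hom: PhenotypeCategory.major_only,
    Genotype.het: PhenotypeCategory.both,
    Genotype.minor_hom: PhenotypeCategory.minor_only,
}


def expected_profile(
    individual_id: str,
    genotypes: GenotypeTable,
    panel: Sequence[MissenseSNP],
    sample: SampleKey | None = None,
) -> GVPProfile:
    """The profile implied by full detection of every genotype-consistent GVP.

    Homozygotes show only their allele's form; heterozygotes show both.
    """
    if sample is None:
        sample = SampleKey(
            sample_id=f"{individual_id}:expected",
            individual_id=individual_id,
            body_location="expected",
            replicate=1,
        )
    entries = {}
    for snp in panel:
        category = _GENOTYPE_CATEGORY[genotypes.get(individual_id, snp.snp_id)]
        entries[snp.snp_id] = (category, phenotype_frequency(category, snp.genotype_freqs))
    return GVPProfile(sample=sample, entries=entries)


# ---------------------------------------------------------------------------
# RMP
# ---------------------------------------------------------------------------

def rmp(profile: GVPProfile) -> float:
    """Random match probability: product of frequencies over non-absent loci."""
    freqs = [f for _, f in profile.entries.values() if f is not None]
    if not freqs:
        raise AllAbsentProfileError(
            f"{profile.sample.sample_id}: all panel loci absent; RMP undefined"
        )
    return math.prod(freqs)


def rmp_one_in(value: float) -> int:
    """Express an RMP in the conventional '1 in N' form."""
    if not 0.0 < value <= 1.0:
        raise ValueError(f"RMP must be in (0, 1], got {value}")
    return round(1.0 / value)


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------

def profile_difference(a: GVPProfile, b: GVPProfile) -> int:
    """Number of panel loci at which the two phenotype categories differ."""
    if set(a.entries) != set(b.entries):
        raise ValueError(
            f"profiles cover different panels: {sorted(a.entries)} vs {sorted(b.entries)}"
        )
    return sum(1 for snp_id in a.entries if a.category(snp_id) is not b.category(snp_id))


def comparison_category(a: SampleKey, b: SampleKey) -> ComparisonCategory:
    if a.individual_id == b.individual_id:
        if a.body_location == b.body_location:
            return ComparisonCategory.replicate
        return ComparisonCategory.within_individual
    return ComparisonCategory.between_individual


def pairwise_compare(
    profiles: Sequence[GVPProfile],
) -> tuple[list[ProfileComparison], dict]:
    """All unordered profile pairs with per-category difference summaries.

    Returns the comparison list (ordered by sample id) and a summary mapping
    each category to ``{mean, sd, n}`` (sd is the sample standard deviation),
    with between-individual comparisons additionally summarised per
    individual pair.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    ordered = sorted(profiles, key=lambda p: p.sample.sample_id)
    comparisons = [
        ProfileComparison(
            sample_a=a.sample,
            sample_b=b.sample,
            category=comparison_category(a.sample, b.sample),
            n_differences=profile_difference(a, b),
        )
        for a, b in itertools.combinations(ordered, 2)
    ]
    summary: dict = {}
    for category in ComparisonCategory:
        values = [c.n_differences for c in comparisons if c.category == category]
        summary[category.value] = _summarise(values)
    pair_summary = {}
    for comparison in comparisons:
        if comparison.category is ComparisonCategory.between_individual:
            pair_summary.setdefault(
                "-".join(comparison.individual_pair), []
            ).append(comparison.n_differences)
    summary["between_individual_pairs"] = {
        pair: _summarise(values) for pair, values in sorted(pair_summary.items())
    }
    return comparisons, summary


def _summarise(values: Sequence[int]) -> dict:
    if not values:
        return {"mean": None, "sd": None, "n": 0}
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return {"mean": round(float(arr.mean()), 2), "sd": round(sd, 2), "n": len(arr)}


# ---------------------------------------------------------------------------
# rank-based group test (Kruskal-Wallis + Dunn post hoc, Bonferroni)
# ---------------------------------------------------------------------------

@dataclass
class CategoryTestResult:
    statistic: float
    pvalue: float
    group_sizes: dict[str, int]
    posthoc: list[dict]
    excluded: list[str] = field(default_factory=list)


def comparison_groups(
    comparisons: Sequence[ProfileComparison],
) -> dict[str, list[int]]:
    """Difference counts grouped as replicate, within-individual, and one
    between-individual group per individual pair."""
    groups: dict[str, list[int]] = {}
    for c in comparisons:
        if c.category is ComparisonCategory.between_individual:
            name = "between:" + "-".join(c.individual_pair)
        else:
            name = c.category.value
        groups.setdefault(name, []).append(c.n_differences)
    return dict(sorted(groups.items()))


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> list[dict]:
    """Dunn's rank-sum z-tests for all group pairs, Bonferroni-adjusted.

    Uses the ties-corrected variance ``(N(N+1)/12 - T)(1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t) / (12(N - 1))`` over tied-value multiplicities.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    ranks = stats.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes, offset = {}, {}, 0
    for name in names:
        size = len(groups[name])
        mean_ranks[name] = float(ranks[offset : offset + size].mean())
        sizes[name] = size
        offset += size
    n_pairs = len(names) * (len(names) - 1) // 2
    results = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(variance * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = float((mean_ranks[a] - mean_ranks[b]) / se) if se > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        p_adj = min(1.0, p_raw * n_pairs)
        results.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": bool(p_adj <= 0.05),
            }
        )
    return results


def category_test(comparisons: Sequence[ProfileComparison]) -> CategoryTestResult:
    """Kruskal-Wallis across the comparison groups with Dunn post-hoc tests.

    Groups with fewer than two members are excluded with a warning. When all
    groups hold identical values the omnibus test is degenerate; the result
    reports statistic 0 and p-value 1 with no significant pairs.
    """
    groups = comparison_groups(comparisons)
    excluded = [name for name, vals in groups.items() if len(vals) < 2]
    for name in excluded:
        logger.warning("category %s has < 2 comparisons; excluded from test", name)
    groups = {name: vals for name, vals in groups.items() if len(vals) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least two non-degenerate comparison groups")
    flat = [v for vals in groups.values() for v in vals]
    if len(set(flat)) == 1:
        return CategoryTestResult(
            statistic=0.0,
            pvalue=1.0,
            group_sizes={n: len(v) for n, v in groups.items()},
            posthoc=[
                {
                    "group_a": a,
                    "group_b": b,
                    "z": 0.0,
                    "p_raw": 1.0,
                    "p_adjusted": 1.0,
                    "significant": False,
                }
                for a, b in itertools.combinations(groups, 2)
            ],
            excluded=excluded,
        )
    statistic, pvalue = stats.kruskal(*groups.values())
    return CategoryTestResult(
        statistic=float(statistic),
        pvalue=float(pvalue),
        group_sizes={n: len(v) for n, v in groups.items()},
        posthoc=dunn_posthoc(groups),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "sample_id",
    "individual_id",
    "body_location",
    "replicate",
    "snp_id",
    "category",
    "frequency",
]


def write_profiles(profiles: Iterable[GVPProfile], path) -> None:
    rows = []
    for p in profiles:
        for snp_id, (category, freq) in p.entries.items():
            rows.append(
                {
                    "sample_id": p.sample.sample_id,
                    "individual_id": p.sample.individual_id,
                    "body_location": p.sample.body_location,
                    "replicate": p.sample.replicate,
                    "snp_id": snp_id,
                    "category": category.value,
                    "frequency": "" if freq is None else repr(freq),
                }
            )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[GVPProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    profiles: dict[str, tuple[SampleKey, dict]] = {}
    for row in df.itertuples(index=False):
        if row.sample_id not in profiles:
            key = SampleKey(
                sample_id=row.sample_id,
                individual_id=row.individual_id,
                body_location=row.body_location,
                replicate=int(row.replicate),
            )
            profiles[row.sample_id] = (key, {})
        freq = None if row.frequency == "" else float(row.frequency)
        profiles[row.sample_id][1][row.snp_id] = (PhenotypeCategory(row.category), freq)
    return [GVPProfile(sample=key, entries=entries) for key, entries in profiles.values()]


def write_comparisons(comparisons: Iterable[ProfileComparison], path) -> None:
    rows = [
        {
            "sample_a": c.sample_a.sample_id,
            "sample_b": c.sample_b.sample_id,
            "individual_a": c.sample_a.individual_id,
            "individual_b": c.sample_b.individual_id,
            "category": c.category.value,
            "n_differences": c.n_differences,
        }
        for c in comparisons
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_a",
            "sample_b",
            "individual_a",
            "individual_b",
            "category",
            "n_differences",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_rmp_table(profiles: Iterable[GVPProfile], path) -> None:
    rows = []
    for p in profiles:
        try:
            value = rmp(p)
            rows.append(
                {
                    "sample_id": p.sample.sample_id,
                    "individual_id": p.sample.individual_id,
                    "body_location": p.sample.body_location,
                    "rmp": repr(value),
                    "one_in": rmp_one_in(value),
                    "n_loci_scored": sum(
                        1 for _, f in p.entries.values() if f is not None
                    ),
                }
            )
        except AllAbsentProfileError:
            rows.append(
                {
                    "sample_id": p.sample.sample_id,
                    "individual_id": p.sample.individual_id,
                    "body_location": p.sample.body_location,
                    "rmp": "undefined",
                    "one_in": "",
                    "n_loci_scored": 0,
                }
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "individual_id", "body_location", "rmp", "one_in", "n_loci_scored"],
    ).to_csv(path, sep="\t", index=False)
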