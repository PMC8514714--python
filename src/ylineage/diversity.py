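"""Forensic diversity indexes for Y-STR data.

Per-locus gene diversity GD = n(1 − Σx_i²)/(n − 1) with x_i the allele
frequencies and n the number of individuals typed at the locus (pairwise
deletion of missing calls, locus-specific n).  Sample-level indexes are
computed from the occurrence spectrum of distinct haplotypes:

    HMP = Σ p_i²             (haplotype match probability)
    HD  = n(1 − HMP)/(n − 1) (haplotype diversity, Nei's unbiased form)
    DC  = k/n                (discrimination capacity, k distinct haplotypes)

Partial profiles are pooled with complete ones by *compatibility
clustering*: two profiles belong to one haplotype cluster when they carry
equal alleles at every series typed in both.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .haplotypes import Haplotype
from .panels import PanelDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleCounts",
    "HaplotypeSpectrum",
    "DiversityResult",
    "PanelComparison",
    "allele_counts",
    "gene_diversity",
    "gene_diversity_table",
    "cluster_haplotypes",
    "haplotype_diversity",
    "group_gd_means",
    "panel_comparison",
]


@dataclass
class AlleleCounts:
    """Allele occurrence counts at one series (missing calls excluded)."""

    locus: str
    counts: dict[float, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class HaplotypeSpectrum:
    """Occurrence spectrum: how many distinct haplotypes were seen k times.

    ``occurrence_counts[k]`` is the number of clusters of size k, so that
    Σ k·occurrence_counts[k] = n and Σ occurrence_counts[k] = n_distinct.
    """

    occurrence_counts: dict[int, int]
    members: list[list[str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(k * c for k, c in self.occurrence_counts.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.occurrence_counts.values())

    def cluster_sizes(self) -> list[int]:
        out: list[int] = []
        for k in sorted(self.occurrence_counts):
            out.extend([k] * self.occurrence_counts[k])
        return out


@dataclass
class DiversityResult:
    hd: float
    hmp: float
    dc: float
    n: int
    n_distinct: int
    per_locus_gd: dict[str, float | None] = field(default_factory=dict)


def allele_counts(haps: list[Haplotype], series: str) -> AlleleCounts:
    """Tally typed alleles at one series across a sample."""
    counter = Counter(h.calls[series] for h in haps if h.calls.get(series) is not None)
    return AlleleCounts(series, dict(counter))


def gene_diversity(counts: AlleleCounts) -> float | None:
    """Unbiased gene diversity GD = n(1 − Σx_i²)/(n − 1); None if n < 2."""
    n = counts.n
    if n < 2:
        logger.warning("gene diversity undefined at %s: n=%d < 2", counts.locus, n)
        return None
    ss = sum((c / n) ** 2 for c in counts.counts.values())
    return n * (1.0 - ss) / (n - 1)


def gene_diversity_table(
    haps: list[Haplotype], panel: PanelDefinition
) -> dict[str, float | None]:
    return {s: gene_diversity(allele_counts(haps, s)) for s in panel.series}


def _compatible(calls: dict[str, float | None], consensus: dict[str, float]) -> int | None:
    """Shared-and-equal series count, or None if any shared series differs."""
    shared = 0
    for s, v in calls.items():
        if v is None or s not in consensus:
            continue
        if v != consensus[s]:
            return None
        shared += 1
    return shared


def cluster_haplotypes(
    haps: list[Haplotype], panel: PanelDefinition
) -> HaplotypeSpectrum:
    """Greedy compatibility clustering of (possibly partial) profiles.

    Profiles are processed in descending order of typed-series count (ties
    by input order), so complete profiles seed clusters first.  Each
    profile joins the compatible cluster sharing the most typed-and-equal
    series; ties go to the earliest-created cluster; with no compatible
    cluster it founds a new one.  A profile compatible with several
    mutually incompatible clusters joins only its best match and the
    ambiguity is logged.
    """
    order = sorted(range(len(haps)), key=lambda i: -haps[i].project(panel).n_typed)
    clusters: list[dict[str, float]] = []  # consensus: union of typed calls
    members: list[list[str]] = []
    for i in order:
        h = haps[i].project(panel)
        calls = h.calls
        best, best_shared = None, -1
        n_compatible = 0
        for ci, consensus in enumerate(clusters):
            shared = _compatible(calls, consensus)
            if shared is None:
                continue
            n_compatible += 1
            if shared > best_shared:
                best, best_shared = ci, shared
        if best is None:
            clusters.append({s: v for s, v in calls.items() if v is not None})
            members.append([h.sample_id])
        else:
            if n_compatible > 1:
                logger.info(
                    "%s is compatible with %d clusters; joined best match",
                    h.sample_id,
                    n_compatible,
                )
            for s, v in calls.items():
                if v is not None:
                    clusters[best].setdefault(s, v)
            members[best].append(h.sample_id)
    spectrum = Counter(len(m) for m in members)
    return HaplotypeSpectrum(dict(spectrum), members)


def haplotype_diversity(
    spectrum: HaplotypeSpectrum, per_locus_gd: dict[str, float | None] | None = None
) -> DiversityResult:
    """HD, HMP and DC from an occurrence spectrum (n ≥ 2 required)."""
    n = spectrum.n
    if n < 2:
        logger.warning("haplotype diversity undefined: n=%d < 2", n)
        return DiversityResult(
            float("nan"), float("nan"), float("nan"), n, spectrum.n_distinct
        )
    hmp = sum(c * (k / n) ** 2 for k, c in spectrum.occurrence_counts.items())
    hd = n * (1.0 - hmp) / (n - 1)
    dc = spectrum.n_distinct / n
    return DiversityResult(hd, hmp, dc, n, spectrum.n_distinct, per_locus_gd or {})


@dataclass
class PanelComparison:
    """Diversity under a full panel vs a projection onto a subset panel."""

    full: DiversityResult
    subset: DiversityResult
    full_spectrum: HaplotypeSpectrum
    subset_spectrum: HaplotypeSpectrum
    gd_group_means: dict[str, float]


def _mean(values: list[float]) -> float:
    return sum(values) / len(values)


def group_gd_means(
    per_locus_gd: dict[str, float | None],
    panel_full: PanelDefinition,
    panel_subset: PanelDefinition,
) -> dict[str, float]:
    """Mean per-locus GD by series group: the core subset panel, the
    additional series beyond it, and the rapidly mutating series."""
    core = set(panel_subset.series)
    rm = set(panel_full.rm_series)
    groups = {
        "core": [per_locus_gd.get(s) for s in panel_full.series if s in core],
        "additional": [per_locus_gd.get(s) for s in panel_full.series if s not in core],
        "rm": [per_locus_gd.get(s) for s in panel_full.series if s in rm],
    }
    return {
        name: _mean([v for v in vals if v is not None])
        for name, vals in groups.items()
        if any(v is not None for v in vals)
    }


def panel_comparison(
    haps: list[Haplotype],
    panel_full: PanelDefinition,
    panel_subset: PanelDefinition,
) -> PanelComparison:
    """Recompute the spectrum and indexes after projecting onto a subset
    panel, with per-locus GD grouped as core / additional / rapidly
    mutating series and group means."""
    if not panel_subset.is_subset_of(panel_full):
        raise ValueError(
            f"panel {panel_subset.name} is not a subset of {panel_full.name}"
        )
    gd_full = gene_diversity_table(haps, panel_full)
    spectrum_full = cluster_haplotypes(haps, panel_full)
    res_full = haplotype_diversity(spectrum_full, gd_full)

    projected = [h.project(panel_subset) for h in haps]
    spectrum_sub = cluster_haplotypes(projected, panel_subset)
    res_sub = haplotype_diversity(
        spectrum_sub, {s: gd_full[s] for s in panel_subset.series}
    )

    means = group_gd_means(gd_full, panel_full, panel_subset)
    return PanelComparison(res_full, res_sub, spectrum_full, spectrum_sub, means)
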