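"""Two-population differentiation via two-level AMOVA.

The analysis of molecular variance partitions squared pairwise distances
into among- and within-population components.  With categorical labels
and the 0/1 distance the Φ-statistic is a frequency-based F_ST; with the
squared repeat-count distance between Y-STR haplotypes it is R_ST.
Significance comes from permuting individuals across populations, with
the observed statistic included in the permutation set:
p = (b + 1)/(m + 1), b the number of permuted statistics ≥ observed.

Variance components follow the standard two-level AMOVA sums of squares:

    SSD_total  = Σ_{i<j} d²_ij / N
    SSD_within = Σ_pop Σ_{i<j ∈ pop} d²_ij / n_pop
    σ²_w = SSD_within / (N − P)
    σ²_a = (SSD_among/(P − 1) − σ²_w) / n',   n' = (N − Σ n_p²/N)/(P − 1)
    Φ_ST = σ²_a / (σ²_a + σ²_w)

Negative components are reported as computed, not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotypes import Haplotype
from .panels import PanelDefinition

__all__ = ["StructureResult", "amova_fst", "amova_rst", "phi_st_from_distances"]


@dataclass
class StructureResult:
    statistic: str  # "FST" or "RST"
    value: float
    p_value: float
    sigma2_among: float
    sigma2_within: float
    n_permutations: int
    seed: int | None


def _phi_st(d2: np.ndarray, pops: np.ndarray) -> tuple[float, float, float]:
    """Φ_ST and variance components from a squared-distance matrix."""
    n_total = len(pops)
    labels, counts = np.unique(pops, return_counts=True)
    n_pops = len(labels)
    iu = np.triu_indices(n_total, k=1)
    ssd_total = d2[iu].sum() / n_total
    ssd_within = 0.0
    for lab, n_p in zip(labels, counts):
        idx = np.flatnonzero(pops == lab)
        sub = d2[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(n_p, k=1)].sum() / n_p
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = n_total - n_pops
    sigma2_w = ssd_within / df_within
    n_prime = (n_total - (counts**2).sum() / n_total) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_prime
    denom = sigma2_a + sigma2_w
    phi = sigma2_a / denom if denom != 0 else 0.0
    return phi, sigma2_a, sigma2_w


def phi_st_from_distances(
    d2: np.ndarray,
    pops,
    statistic: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> StructureResult:
    """AMOVA Φ_ST with a permutation p-value on a squared-distance matrix."""
    pops = np.asarray(pops)
    labels, counts = np.unique(pops, return_counts=True)
    if len(labels) != 2:
        raise ValueError(f"exactly two populations required, got {len(labels)}")
    if counts.min() < 2:
        raise ValueError("each population needs at least two individuals")
    observed, s2a, s2w = _phi_st(d2, pops)
    rng = np.random.default_rng(seed)
    b = 0
    perm = pops.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        stat, _, _ = _phi_st(d2, perm)
        if stat >= observed - 1e-12:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return StructureResult(statistic, observed, p, s2a, s2w, n_permutations, seed)


def amova_fst(
    group_a,
    group_b,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> StructureResult:
    """Frequency-based F_ST from two lists of categorical labels.

    Labels are typically predicted haplogroups (or haplotype-cluster
    identities); the pairwise distance is 0 for equal labels, 1 otherwise.
    """
    labels = list(group_a) + list(group_b)
    pops = ["A"] * len(group_a) + ["B"] * len(group_b)
    arr = np.asarray(labels, dtype=object)
    d2 = (arr[:, None] != arr[None, :]).astype(float)
    return phi_st_from_distances(d2, pops, "FST", n_permutations, seed)


def _squared_step_distance(
    a: Haplotype, b: Haplotype, panel: PanelDefinition, rescale_missing: bool
) -> float:
    total, shared = 0.0, 0
    for s in panel.series:
        va, vb = a.calls.get(s), b.calls.get(s)
        if va is None or vb is None:
            continue
        total += (vb - va) ** 2
        shared += 1
    if shared == 0:
        raise ValueError(
            f"pair ({a.sample_id}, {b.sample_id}) shares no typed series"
        )
    if rescale_missing and shared < panel.size:
        total *= panel.size / shared
    return total


def amova_rst(
    group_a: list[Haplotype],
    group_b: list[Haplotype],
    panel: PanelDefinition,
    n_permutations: int = 10_000,
    seed: int | None = None,
    rescale_missing: bool = True,
) -> StructureResult:
    """R_ST from two haplotype sets using squared repeat differences.

    Missing loci are dropped pairwise; with ``rescale_missing`` each
    distance is rescaled by panel size / shared size so pairs with unequal
    missingness stay comparable.
    """
    haps = list(group_a) + list(group_b)
    pops = ["A"] * len(group_a) + ["B"] * len(group_b)
    n = len(haps)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = _squared_step_distance(
                haps[i], haps[j], panel, rescale_missing
            )
    return phi_st_from_distances(d2, pops, "RST", n_permutations, seed)
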