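"""Continuity verdicts: does an ancient–modern pair's TMRCA fit the
chronological window of the ancient burials?

A pair is *flagged* when the decisive credible interval of the posterior
over years separating the pair overlaps (closed intervals, endpoint
contact counts) the window of years before present in which the ancient
individuals lived.  An ancient individual shows continuity when at least
one of its modern partners is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tmrca import TmrcaPosterior

__all__ = ["ContinuityConfig", "ContinuityResult", "assess_pair", "continuity_matrix"]


@dataclass(frozen=True)
class ContinuityConfig:
    """Verdict settings.

    ``window`` is [min_years, max_years] before present; the default
    300–500 years spans roughly 9–15 generations at 33 years each.
    ``decisive_ci_level`` selects which credible interval drives the
    verdict (the stricter 50% interval by default).
    """

    window: tuple[float, float] = (300.0, 500.0)
    decisive_ci_level: float = 0.50
    generation_time: float = 33.0

    def __post_init__(self):
        lo, hi = self.window
        if not 0 < lo < hi:
            raise ValueError(f"invalid window {self.window}")


@dataclass
class PairVerdict:
    ancient_id: str
    modern_id: str
    ci_years: dict[float, tuple[float, float]]
    verdict: bool


@dataclass
class ContinuityResult:
    pairs: list[PairVerdict]
    per_ancient: dict[str, int]  # ancient id → flagged modern partners

    @property
    def n_continuous(self) -> int:
        return sum(1 for c in self.per_ancient.values() if c > 0)

    def flagged_pairs(self) -> list[tuple[str, str]]:
        return [(p.ancient_id, p.modern_id) for p in self.pairs if p.verdict]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            row = {
                "ancient_id": p.ancient_id,
                "modern_id": p.modern_id,
                "verdict": p.verdict,
            }
            for level, (lo, hi) in sorted(p.ci_years.items()):
                row[f"ci{int(round(level * 100))}_low"] = lo
                row[f"ci{int(round(level * 100))}_high"] = hi
            rows.append(row)
        return pd.DataFrame(rows)


def _overlaps(ci: tuple[float, float], window: tuple[float, float]) -> bool:
    return ci[0] <= window[1] and ci[1] >= window[0]


def assess_pair(
    years_posterior: TmrcaPosterior,
    config: ContinuityConfig = ContinuityConfig(),
    ancient_id: str = "",
    modern_id: str = "",
) -> PairVerdict:
    """Closed-interval overlap of the decisive CI with the window.

    ``years_posterior`` must already be on the years-separating scale
    (total generations × generation time).
    """
    if config.decisive_ci_level not in years_posterior.ci:
        raise KeyError(
            f"posterior lacks the {config.decisive_ci_level:.0%} interval"
        )
    verdict = _overlaps(years_posterior.ci[config.decisive_ci_level], config.window)
    return PairVerdict(ancient_id, modern_id, dict(years_posterior.ci), verdict)


def continuity_matrix(
    pair_posteriors: list[tuple[str, str, TmrcaPosterior]],
    config: ContinuityConfig = ContinuityConfig(),
) -> ContinuityResult:
    """Verdicts for every ancient × modern pair.

    ``pair_posteriors`` holds (ancient_id, modern_id, years posterior)
    triples.  The per-ancient flag is the OR over its modern partners; the
    summary counts flagged partners per ancient individual.
    """
    verdicts = [
        assess_pair(post, config, ancient_id=a, modern_id=m)
        for a, m, post in pair_posteriors
    ]
    per_ancient: dict[str, int] = {}
    for v in verdicts:
        per_ancient[v.ancient_id] = per_ancient.get(v.ancient_id, 0) + int(v.verdict)
    return ContinuityResult(verdicts, per_ancient)
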