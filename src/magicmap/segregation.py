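"""Mendelian segregation goodness-of-fit tests (Pearson chi-square)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class SegregationResult:
    observed: tuple[int, ...]
    ratio: tuple[float, ...]
    statistic: float
    df: int
    pvalue: float
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        """"ns" when the fit is not rejected at alpha, else "significant"."""
        return "ns" if self.pvalue > self.alpha else "significant"


def chi_square_segregation(
    observed: Sequence[float],
    ratio: Sequence[float],
    alpha: float = 0.05,
    yates: bool = False,
) -> SegregationResult:
    """Pearson chi-square of observed class counts against an expected ratio.

    No continuity correction by default; ``yates=True`` applies the standard
    ``(|O-E| - 0.5)`` correction (floored at zero).
    """
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("need at least two observed classes")
    if obs.size != rat.size:
        raise ValueError(
            f"{obs.size} observed classes but {rat.size} ratio terms"
        )
    if np.any(obs < 0):
        raise ValueError("observed counts must be >= 0")
    if np.any(rat <= 0):
        raise ValueError("ratio terms must be > 0")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")

    expected = total * rat / rat.sum()
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    df = obs.size - 1
    pvalue = float(stats.chi2.sf(statistic, df))
    return SegregationResult(
        tuple(int(o) if float(o).is_integer() else float(o) for o in obs),
        tuple(rat), statistic, df, pvalue, alpha,
    )


def fit_ratio_set(
    observed: Sequence[float],
    ratios: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> tuple[tuple[float, ...], dict[tuple[float, ...], SegregationResult]]:
    """Evaluate several candidate ratios; best fit = maximal p-value.

    Ties break toward fewer classes, then toward earlier list position.
    """
    if not ratios:
        raise ValueError("need at least one candidate ratio")
    results: dict[tuple[float, ...], SegregationResult] = {}
    for r in ratios:
        res = chi_square_segregation(observed, r, alpha=alpha)
        results[tuple(float(x) for x in r)] = res
    best = min(
        enumerate(results.items()),
        key=lambda kv: (-kv[1][1].pvalue, len(kv[1][0]), kv[0]),
    )[1][0]
    return best, results
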