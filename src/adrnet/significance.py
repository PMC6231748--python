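"""Selection of ADRs significantly associated with the disease.

The only reference population available for a disease-ADR path score is
the distribution of path scores itself, so each ADR is tested with a
one-sided leave-one-out outlier t test: score ``s_i`` is compared with
the mean of the remaining ``m - 1`` scores,

    t_i = (s_i - mean(s_-i)) / (sd(s_-i) * sqrt(1 + 1/(m - 1)))

and referred to a t distribution with ``m - 2`` degrees of freedom
(the hold-out sd uses ``m - 2`` denominator degrees of freedom).  An ADR
is significant when the upper-tail p value falls below ``alpha``.  If the
hold-out scores have zero spread the statistic degenerates: the limit
p value is 0 when ``s_i`` exceeds the hold-out mean, 1 below it, and 0.5
at equality — so an all-equal score vector marks nothing significant.

Alternatively a user-supplied reference mean turns the procedure into a
set of one-sample z-like comparisons against that mean (``null_mean``),
and a Benjamini-Hochberg flag applies step-up FDR control; both are off
by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import DiseaseAdrScore


@dataclass(frozen=True)
class SignificanceResult:
    adr: str
    score: float
    t_statistic: float
    p_value: float
    significant: bool


def _loo_t(values: np.ndarray, i: int) -> tuple[float, float]:
    """Leave-one-out t statistic and one-sided p for element ``i``."""
    m = values.size
    rest = np.delete(values, i)
    mean = rest.mean()
    sd = rest.std(ddof=1)
    diff = values[i] - mean
    if sd == 0.0:
        if diff > 0:
            return math.inf, 0.0
        if diff < 0:
            return -math.inf, 1.0
        return 0.0, 0.5
    t = diff / (sd * math.sqrt(1.0 + 1.0 / (m - 1)))
    return t, float(stats.t.sf(t, df=m - 2))


def select_significant(
    scores: Sequence[DiseaseAdrScore],
    alpha: float = 0.05,
    null_mean: float | None = None,
    fdr: bool = False,
) -> list[SignificanceResult]:
    """Test each disease-ADR score and flag the significant ADRs.

    Requires at least 3 scored ADRs (the leave-one-out test needs m >= 3).
    Results are sorted by descending score.  With ``fdr=True`` the p values
    are Benjamini-Hochberg adjusted before thresholding at ``alpha``.
    """
    m = len(scores)
    if m < 3:
        raise ValueError(f"need at least 3 scored ADRs, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    values = np.array([s.score for s in scores], dtype=float)
    stats_p: list[tuple[float, float]] = []
    for i in range(m):
        if null_mean is None:
            stats_p.append(_loo_t(values, i))
        else:
            rest = np.delete(values, i)
            sd = rest.std(ddof=1)
            if sd == 0.0:
                diff = values[i] - null_mean
                stats_p.append(
                    (math.inf, 0.0) if diff > 0
                    else (-math.inf, 1.0) if diff < 0
                    else (0.0, 0.5)
                )
            else:
                t = (values[i] - null_mean) / (sd * math.sqrt(1.0 + 1.0 / (m - 1)))
                stats_p.append((t, float(stats.t.sf(t, df=m - 2))))
    p_values = np.array([p for _, p in stats_p])
    if fdr:
        p_adj = _benjamini_hochberg(p_values)
    else:
        p_adj = p_values
    results = [
        SignificanceResult(
            adr=s.adr,
            score=float(values[i]),
            t_statistic=stats_p[i][0],
            p_value=float(p_values[i]),
            significant=bool(p_adj[i] < alpha),
        )
        for i, s in enumerate(scores)
    ]
    results.sort(key=lambda r: (-r.score, r.adr))
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p values (monotone, capped at 1)."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def write_significance_tsv(results: Iterable[SignificanceResult], path: str | Path) -> None:
    rows = [(r.adr, r.score, r.t_statistic, r.p_value, r.significant) for r in results]
    pd.DataFrame(
        rows, columns=["adr", "score", "t_statistic", "p_value", "significant"]
    ).to_csv(path, sep="\t", index=False)
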