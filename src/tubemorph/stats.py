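"""Group summaries and rank-sum comparisons.

Two-group comparisons use the Mann-Whitney U test, two-sided, with the
exact null distribution whenever the smaller group has at most 8 values
and there are no ties, and the tie-corrected normal approximation
otherwise. The unit of replication for count-based metrics is the embryo:
per-cell flags are first aggregated to a per-embryo positive percentage,
then summarised as mean +/- s.e.m. across embryos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["GroupSummary", "mann_whitney_u", "fraction_positive"]


@dataclass
class GroupSummary:
    """Per-embryo values with their group mean, s.e.m. and n."""

    per_embryo: pd.Series
    mean: float
    sem: float
    n: int


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U statistic (for group_a) and two-sided p-value.

    Ranks use midranks for ties. The p-value comes from exact enumeration
    when min(n_a, n_b) <= 8 and the pooled sample has no ties, and from the
    tie-corrected normal approximation with continuity correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fraction_positive(flags, embryo_ids, gfp_flags=None) -> GroupSummary:
    """Per-embryo positive percentage among GFP+ cells, then mean +/- s.e.m.

    ``flags`` are per-cell marker calls; ``embryo_ids`` assigns each cell to
    an embryo; ``gfp_flags`` restricts the denominator to GFP+ cells (all
    cells by default). Embryos without any GFP+ cell are excluded with a
    warning.
    """
    flags = np.asarray(flags, dtype=bool)
    embryo_ids = np.asarray(embryo_ids)
    if flags.shape != embryo_ids.shape:
        raise ValueError("flags and embryo_ids must have the same length")
    gfp = np.ones_like(flags, dtype=bool) if gfp_flags is None else np.asarray(gfp_flags, dtype=bool)

    values = {}
    for embryo in pd.unique(embryo_ids):
        sel = (embryo_ids == embryo) & gfp
        if not sel.any():
            warnings.warn(f"embryo {embryo!r} has no GFP+ cells; excluded", stacklevel=2)
            continue
        values[embryo] = 100.0 * float(np.mean(flags[sel]))
    if not values:
        raise ValueError("no embryo has GFP+ cells")
    per_embryo = pd.Series(values, name="pct_positive")
    n = len(per_embryo)
    sem = float(per_embryo.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return GroupSummary(per_embryo=per_embryo, mean=float(per_embryo.mean()), sem=sem, n=n)
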