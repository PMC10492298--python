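"""Reference subsets of denoised comparisons, graded by effect strength.

A family of nested subsets S_t keeps every comparison whose denoised odds
ratio is at least t, so downstream evaluations can be run separately for
strong and weak trial-supported effects. An ablated variant ranks nothing and
instead keeps comparisons that a two-sided Fisher exact test calls
significant — the construction this method is meant to improve on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .contingency import ContingencyTable
from .eb_core import DenoisedEffect


@dataclass(frozen=True)
class ReferenceSubset:
    """A threshold (odds-ratio scale, or a 'fisher_p<=a' marker) plus member ids."""

    threshold: float | str
    member_ids: frozenset[str]


def rank_by_effect(effects: Sequence[DenoisedEffect]) -> list[DenoisedEffect]:
    """Descending by denoised odds ratio; ties broken by comparison id."""
    return sorted(effects, key=lambda e: (-e.or_eb, e.record.comparison_id))


def subset_at_threshold(effects: Sequence[DenoisedEffect], t: float) -> ReferenceSubset:
    """S_t: comparisons with denoised odds ratio >= t (inclusive)."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    return ReferenceSubset(
        threshold=t,
        member_ids=frozenset(e.record.comparison_id for e in effects if e.or_eb >= t),
    )


def fisher_exact_pvalue(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (point-probability method), in (0, 1]."""
    _, p = fisher_exact(
        [[table.x_a, table.x_b], [table.y_a, table.y_b]], alternative="two-sided"
    )
    return min(float(p), 1.0)


def fisher_exact_subset(
    effects: Sequence[DenoisedEffect], alpha: float = 0.05
) -> ReferenceSubset:
    """Comparisons significant under the Fisher exact test at level alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    members = frozenset(
        e.record.comparison_id
        for e in effects
        if fisher_exact_pvalue(e.record.table) <= alpha
    )
    return ReferenceSubset(threshold=f"fisher_p<={alpha:g}", member_ids=members)


def write_subset_tsv(subset: ReferenceSubset, path: str | Path) -> None:
    df = pd.DataFrame(
        {"comparison_id": sorted(subset.member_ids), "threshold": str(subset.threshold)}
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_subset_tsv(path: str | Path) -> ReferenceSubset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df) == 0:
        return ReferenceSubset(threshold=math.nan, member_ids=frozenset())
    raw = str(df["threshold"].iloc[0])
    try:
        threshold: float | str = float(raw)
    except ValueError:
        threshold = raw
    return ReferenceSubset(threshold=threshold, member_ids=frozenset(df["comparison_id"]))
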