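"""Score non-experimental method outputs against trial-derived reference subsets.

A method under evaluation maps each comparison to a p-value and a predicted
effect direction. Because every reference record is oriented so that its
(corrected) sample odds ratio is >= 1, the reference direction is always
"drug A has the higher adverse-event rate"; a method result is *concordant*
when it is significant and predicts the same. Two headline metrics per subset:

* concordant sign rate (CSR): among the subset's comparisons the method calls
  significant, the fraction with concordant direction — a reliability measure;
* recovery: the fraction of the whole subset that the method flags significant
  *and* concordant — a power measure.

Both are swept over the odds-ratio threshold t that defines the subsets S_t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .eb_core import DenoisedEffect
from .reference_set import ReferenceSubset, subset_at_threshold

A_HIGHER = "A_higher"
B_HIGHER = "B_higher"

#: reference direction for every oriented comparison (sample OR >= 1 forces it)
REFERENCE_DIRECTION = A_HIGHER

DEFAULT_ALPHA = 0.05
DEFAULT_THRESHOLDS = [round(1.0 + 0.05 * k, 2) for k in range(61)]  # 1.00 .. 4.00


@dataclass(frozen=True)
class MethodResult:
    """One method output: comparison id, p-value, predicted effect direction."""

    comparison_id: str
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.direction not in (A_HIGHER, B_HIGHER):
            raise ValueError(f"direction must be {A_HIGHER!r} or {B_HIGHER!r}")


@dataclass(frozen=True)
class EvaluationCurve:
    """CSR and recovery as functions of the odds-ratio threshold."""

    thresholds: tuple[float, ...]
    csr: tuple[float, ...]  # nan where the significant-in-subset denominator is 0
    recovery: tuple[float, ...]
    n_significant: tuple[int, ...]
    n_subset: tuple[int, ...]


def _check_unique(results: Sequence[MethodResult]) -> None:
    ids = [r.comparison_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate comparison_id in method results: {dupes[:5]}")


def significant_results(
    results: Sequence[MethodResult], alpha: float = DEFAULT_ALPHA
) -> set[str]:
    """Ids of results with p-value <= alpha (inclusive)."""
    _check_unique(results)
    return {r.comparison_id for r in results if r.p_value <= alpha}


def concordant_sign_rate(
    subset: ReferenceSubset,
    results: Sequence[MethodResult],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Fraction of significant in-subset results agreeing with the reference
    direction; nan when no in-subset result is significant."""
    _check_unique(results)
    in_play = [
        r
        for r in results
        if r.comparison_id in subset.member_ids and r.p_value <= alpha
    ]
    if not in_play:
        return math.nan
    concordant = sum(1 for r in in_play if r.direction == REFERENCE_DIRECTION)
    return concordant / len(in_play)


def recovery_fraction(
    subset: ReferenceSubset,
    results: Sequence[MethodResult],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Share of the subset recovered: significant with concordant direction."""
    if not subset.member_ids:
        raise ValueError("recovery is undefined for an empty subset")
    _check_unique(results)
    recovered = sum(
        1
        for r in results
        if r.comparison_id in subset.member_ids
        and r.p_value <= alpha
        and r.direction == REFERENCE_DIRECTION
    )
    return recovered / len(subset.member_ids)


def fraction_significant(
    results: Sequence[MethodResult], alpha: float = DEFAULT_ALPHA
) -> float:
    """Share of all method results that are statistically significant."""
    if not results:
        raise ValueError("fraction_significant requires at least one result")
    return len(significant_results(results, alpha)) / len(results)


def evaluation_curve(
    effects: Sequence[DenoisedEffect],
    results: Sequence[MethodResult],
    thresholds: Sequence[float] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> EvaluationCurve:
    """CSR/recovery sweep over ascending odds-ratio thresholds."""
    thresholds = list(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    _check_unique(results)
    sig = significant_results(results, alpha)
    csr, rec, n_sig, n_sub = [], [], [], []
    for t in thresholds:
        subset = subset_at_threshold(effects, t)
        in_play = subset.member_ids & sig
        n_sub.append(len(subset.member_ids))
        n_sig.append(len(in_play))
        csr.append(concordant_sign_rate(subset, results, alpha))
        if subset.member_ids:
            rec.append(recovery_fraction(subset, results, alpha))
        else:
            rec.append(math.nan)
    return EvaluationCurve(
        thresholds=tuple(thresholds),
        csr=tuple(csr),
        recovery=tuple(rec),
        n_significant=tuple(n_sig),
        n_subset=tuple(n_sub),
    )


def per_comparison_report(
    subset: ReferenceSubset,
    results_by_method: Mapping[str, Sequence[MethodResult]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One row per subset comparison: each method's p-value, direction, status.

    Status is 'concordant' or 'discordant' only for significant results,
    'not_significant' otherwise, and 'absent' when the method reported nothing
    for that comparison.
    """
    rows = []
    indexed = {}
    for name, results in results_by_method.items():
        _check_unique(results)
        indexed[name] = {r.comparison_id: r for r in results}
    for cid in sorted(subset.member_ids):
        row: dict[str, object] = {"comparison_id": cid}
        for name in results_by_method:
            res = indexed[name].get(cid)
            if res is None:
                row[f"{name}_p_value"] = math.nan
                row[f"{name}_direction"] = ""
                row[f"{name}_status"] = "absent"
                continue
            row[f"{name}_p_value"] = res.p_value
            row[f"{name}_direction"] = res.direction
            if res.p_value > alpha:
                row[f"{name}_status"] = "not_significant"
            elif res.direction == REFERENCE_DIRECTION:
                row[f"{name}_status"] = "concordant"
            else:
                row[f"{name}_status"] = "discordant"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

_DIR_TO_TSV = {A_HIGHER: "A", B_HIGHER: "B"}
_DIR_FROM_TSV = {"A": A_HIGHER, "B": B_HIGHER}


def read_method_results_tsv(path: str | Path) -> list[MethodResult]:
    df = pd.read_csv(path, sep="\t", dtype={"comparison_id": str, "direction": str})
    out = []
    for _, row in df.iterrows():
        direction = _DIR_FROM_TSV.get(str(row["direction"]).strip())
        if direction is None:
            raise ValueError(f"direction must be 'A' or 'B', got {row['direction']!r}")
        out.append(
            MethodResult(
                comparison_id=str(row["comparison_id"]),
                p_value=float(row["p_value"]),
                direction=direction,
            )
        )
    return out


def write_method_results_tsv(results: Sequence[MethodResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "comparison_id": [r.comparison_id for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [_DIR_TO_TSV[r.direction] for r in results],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def curve_to_frame(curve: EvaluationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "n_subset": curve.n_subset,
            "n_significant": curve.n_significant,
            "csr": curve.csr,
            "recovery": curve.recovery,
        }
    )


def write_curve_tsv(curve: EvaluationCurve, path: str | Path) -> None:
    curve_to_frame(curve).to_csv(path, sep="\t", index=False, lineterminator="\n")
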