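"""Drug-vs-drug adverse-event contingency tables: building, pooling, orientation.

Each comparison is a 2x2 table

    =============================  =======  =======
    .                              drug A   drug B
    patients with the event        x_a      x_b
    patients without the event     y_a      y_b
    =============================  =======  =======

formed from two single-ingredient trial arms sharing an ICD10-coded adverse
event. Arms of the same ingredient within a trial (dosage arms) are merged by
summation; comparisons with identical (drug pair, adverse event) keys across
trials are pooled cell-wise. Because an active-comparator design has no
natural baseline arm, every pooled comparison is finally oriented so its
continuity-corrected sample odds ratio is >= 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .trial_ingest import IngredientArm

#: continuity correction used for ordering/display of sample odds ratios only;
#: likelihood computations always use the raw counts.
ORIENTATION_CONTINUITY = 0.5


@dataclass(frozen=True)
class ContingencyTable:
    """Event / non-event counts for the two drugs of one comparison."""

    x_a: int
    y_a: int
    x_b: int
    y_b: int

    def __post_init__(self) -> None:
        if min(self.x_a, self.y_a, self.x_b, self.y_b) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.x_a + self.y_a < 1 or self.x_b + self.y_b < 1:
            raise ValueError("each drug column needs at least one patient")

    @property
    def n_a(self) -> int:
        return self.x_a + self.y_a

    @property
    def n_b(self) -> int:
        return self.x_b + self.y_b

    @property
    def m(self) -> int:
        """Total number of events (the conditioning margin)."""
        return self.x_a + self.x_b

    def swapped(self) -> "ContingencyTable":
        """The same comparison with the drug columns exchanged."""
        return ContingencyTable(x_a=self.x_b, y_a=self.y_b, x_b=self.x_a, y_b=self.y_a)


@dataclass(frozen=True)
class ComparisonRecord:
    """One drug-A/drug-B/adverse-event comparison with its pooled table."""

    comparison_id: str
    drug_a: str
    drug_b: str
    ae: str
    nct_ids: tuple[str, ...]
    table: ContingencyTable

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError("a comparison requires two distinct drugs")


def make_comparison_id(drug_x: str, drug_y: str, ae: str) -> str:
    """Deterministic join key: AE code plus the sorted drug pair."""
    lo, hi = sorted((drug_x, drug_y))
    return f"{ae}|{lo}|{hi}"


# ---------------------------------------------------------------------------
# Building comparisons from ingredient arms
# ---------------------------------------------------------------------------


def merge_dose_arms(arms: Sequence[IngredientArm]) -> list[IngredientArm]:
    """Merge same-ingredient arms of one trial by summing all counts."""
    if arms and len({a.nct_id for a in arms}) != 1:
        raise ValueError("merge_dose_arms expects arms from a single trial")
    merged: dict[str, IngredientArm] = {}
    order: list[str] = []
    for arm in arms:
        if arm.ingredient not in merged:
            merged[arm.ingredient] = arm
            order.append(arm.ingredient)
        else:
            prev = merged[arm.ingredient]
            counts = dict(prev.ae_counts)
            for code, (aff, risk) in arm.ae_counts.items():
                p_aff, p_risk = counts.get(code, (0, 0))
                counts[code] = (p_aff + aff, p_risk + risk)
            merged[arm.ingredient] = IngredientArm(
                nct_id=prev.nct_id,
                ingredient=prev.ingredient,
                n_participants=prev.n_participants + arm.n_participants,
                ae_counts=counts,
            )
    return [merged[k] for k in order]


def build_comparisons(arms: Sequence[IngredientArm]) -> list[ComparisonRecord]:
    """Form one comparison per unordered arm pair per shared adverse event.

    ``arms`` must already be dose-merged for their trial. Table cells are
    x = affected and y = at_risk - affected from each arm's AE entry.
    """
    records: list[ComparisonRecord] = []
    for arm_a, arm_b in itertools.combinations(arms, 2):
        if arm_a.ingredient == arm_b.ingredient:
            raise ValueError("arms must be dose-merged before building comparisons")
        shared = sorted(set(arm_a.ae_counts) & set(arm_b.ae_counts))
        for code in shared:
            aff_a, risk_a = arm_a.ae_counts[code]
            aff_b, risk_b = arm_b.ae_counts[code]
            if risk_a < 1 or risk_b < 1:
                continue
            records.append(
                ComparisonRecord(
                    comparison_id=make_comparison_id(arm_a.ingredient, arm_b.ingredient, code),
                    drug_a=arm_a.ingredient,
                    drug_b=arm_b.ingredient,
                    ae=code,
                    nct_ids=(arm_a.nct_id,),
                    table=ContingencyTable(
                        x_a=aff_a, y_a=risk_a - aff_a, x_b=aff_b, y_b=risk_b - aff_b
                    ),
                )
            )
    return records


def aggregate_trials(records: Iterable[ComparisonRecord]) -> list[ComparisonRecord]:
    """Pool comparisons with identical (drug pair, adverse event) keys.

    Counts are summed cell-wise with each input's columns first aligned to the
    lexicographically sorted drug order, so the result is invariant to input
    order and to any pre-orientation of the inputs. Contributing registry ids
    are unioned and sorted.
    """
    groups: dict[str, list[ComparisonRecord]] = {}
    for rec in records:
        groups.setdefault(rec.comparison_id, []).append(rec)
    out: list[ComparisonRecord] = []
    for cid in sorted(groups):
        members = groups[cid]
        lo, hi = sorted((members[0].drug_a, members[0].drug_b))
        x_a = y_a = x_b = y_b = 0
        ncts: set[str] = set()
        for rec in members:
            t = rec.table if rec.drug_a == lo else rec.table.swapped()
            x_a, y_a, x_b, y_b = x_a + t.x_a, y_a + t.y_a, x_b + t.x_b, y_b + t.y_b
            ncts.update(rec.nct_ids)
        out.append(
            ComparisonRecord(
                comparison_id=cid,
                drug_a=lo,
                drug_b=hi,
                ae=members[0].ae,
                nct_ids=tuple(sorted(ncts)),
                table=ContingencyTable(x_a=x_a, y_a=y_a, x_b=x_b, y_b=y_b),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sample odds ratio and orientation
# ---------------------------------------------------------------------------


def sample_odds_ratio(table: ContingencyTable, continuity: float = 0.0) -> float:
    """(x_a+c)(y_b+c) / ((x_b+c)(y_a+c)); inf/0 allowed when c = 0."""
    if continuity < 0:
        raise ValueError("continuity must be >= 0")
    c = continuity
    num = (table.x_a + c) * (table.y_b + c)
    den = (table.x_b + c) * (table.y_a + c)
    if den == 0:
        return 0.0 if num == 0 else math.inf
    return num / den


def orient(record: ComparisonRecord) -> ComparisonRecord:
    """Orient a comparison so its corrected sample odds ratio is >= 1.

    Uses continuity correction 0.5 so zero cells never force an undefined
    ordering statistic. Exact ties (odds ratio 1) put the lexicographically
    smaller drug code in the drug-A slot. Idempotent.
    """
    ratio = sample_odds_ratio(record.table, continuity=ORIENTATION_CONTINUITY)
    if ratio < 1 or (ratio == 1 and record.drug_a > record.drug_b):
        return replace(
            record,
            drug_a=record.drug_b,
            drug_b=record.drug_a,
            table=record.table.swapped(),
        )
    return record


def comparisons_from_trials(
    arms_by_trial: Iterable[Sequence[IngredientArm]],
) -> list[ComparisonRecord]:
    """Dose-merge, pair, pool across trials, and orient — the full table pipeline."""
    per_trial: list[ComparisonRecord] = []
    for arms in arms_by_trial:
        per_trial.extend(build_comparisons(merge_dose_arms(arms)))
    return [orient(rec) for rec in aggregate_trials(per_trial)]


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_COLUMNS = ["comparison_id", "ae_icd10", "drug_a", "drug_b", "nct_ids", "x_a", "y_a", "x_b", "y_b"]


def comparisons_to_frame(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison_id": r.comparison_id,
                "ae_icd10": r.ae,
                "drug_a": r.drug_a,
                "drug_b": r.drug_b,
                "nct_ids": ";".join(r.nct_ids),
                "x_a": r.table.x_a,
                "y_a": r.table.y_a,
                "x_b": r.table.x_b,
                "y_b": r.table.y_b,
            }
            for r in records
        ],
        columns=_COLUMNS,
    )


def write_comparisons_tsv(records: Sequence[ComparisonRecord], path: str | Path) -> None:
    comparisons_to_frame(records).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_comparisons_tsv(path: str | Path) -> list[ComparisonRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"comparison_id": str, "ae_icd10": str,
                                            "drug_a": str, "drug_b": str, "nct_ids": str})
    records = []
    for _, row in df.iterrows():
        ncts = tuple(str(row["nct_ids"]).split(";")) if pd.notna(row["nct_ids"]) else ()
        records.append(
            ComparisonRecord(
                comparison_id=str(row["comparison_id"]),
                drug_a=str(row["drug_a"]),
                drug_b=str(row["drug_b"]),
                ae=str(row["ae_icd10"]),
                nct_ids=ncts,
                table=ContingencyTable(
                    x_a=int(row["x_a"]), y_a=int(row["y_a"]),
                    x_b=int(row["x_b"]), y_b=int(row["y_b"]),
                ),
            )
        )
    return records
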