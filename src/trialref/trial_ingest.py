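"""Parse normalized clinical-trial result records and apply quality/mapping filters.

Trial result records arrive as a normalized JSON array (one object per
registered trial) carrying allocation and masking metadata, intervention arms
with enrollment counts, and per-arm adverse-event rows. This module turns them
into per-arm, single-ingredient adverse-event counts keyed by ICD10 code,
applying the filters of an active-comparator extraction pipeline:

* a quality filter keeping only randomized trials with participant blinding,
* removal of treatment arms with fewer than ``min_n`` (default 100) patients,
* arm-label to drug-ingredient mapping via token overlap against a lexicon,
  rejecting combination treatments (``+`` in the label, or multi-ingredient
  lexicon entries) and weak matches (< 50% of the label's tokens),
* adverse-event term to ICD10 mapping via exact case-normalized lookup.

Arms or adverse events that fail mapping are dropped and tallied in an
:class:`IngestLog` so a run can report how much each filter discarded.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("trialref")

ALLOCATIONS = ("randomized", "non_randomized", "unspecified")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


class SchemaError(ValueError):
    """A trial record violates the documented JSON schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdverseEventEntry:
    """One adverse-event row of a trial arm: term, affected and at-risk counts."""

    term: str
    affected: int
    at_risk: int


@dataclass(frozen=True)
class ArmReport:
    """One intervention arm: free-text label, enrollment, adverse-event rows."""

    label: str
    n_participants: int
    ae_entries: tuple[AdverseEventEntry, ...]


@dataclass(frozen=True)
class TrialRecord:
    """One registered trial: id, allocation, masking roles, arms."""

    nct_id: str
    allocation: str
    masking_roles: frozenset[str]
    arms: tuple[ArmReport, ...]


@dataclass(frozen=True)
class IngredientArm:
    """A trial arm resolved to a single drug ingredient with ICD10-coded AE counts."""

    nct_id: str
    ingredient: str
    n_participants: int
    ae_counts: Mapping[str, tuple[int, int]]  # icd10 -> (affected, at_risk)


class RejectionReason(str, Enum):
    """Why an arm label could not be mapped to a single ingredient."""

    PLUS_SIGN = "plus_sign"
    LOW_OVERLAP = "low_overlap"
    MULTI_INGREDIENT = "multi_ingredient"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class LexiconEntry:
    """One drug-name lexicon row: ingredient code and its ingredient count."""

    ingredient_code: str
    n_ingredients: int


@dataclass
class IngestLog:
    """Counters of trials/arms/AE terms dropped per filter during extraction."""

    trials_failed_quality: int = 0
    arms_below_min_n: int = 0
    arm_rejections: Counter = field(default_factory=Counter)  # reason -> count
    unmapped_ae_terms: Counter = field(default_factory=Counter)  # term -> count
    capped_ae_codes: int = 0

    def summary(self) -> str:
        parts = [
            f"trials failing quality filter: {self.trials_failed_quality}",
            f"arms below size threshold: {self.arms_below_min_n}",
        ]
        for reason in RejectionReason:
            parts.append(f"arms rejected ({reason.value}): {self.arm_rejections[reason.value]}")
        parts.append(f"unmapped AE term occurrences: {sum(self.unmapped_ae_terms.values())}")
        parts.append(f"AE codes capped at at-risk: {self.capped_ae_codes}")
        return "; ".join(parts)


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------


def _require(cond: bool, record: str, fieldname: str, msg: str) -> None:
    if not cond:
        raise SchemaError(f"record {record!r}, field {fieldname!r}: {msg}")


def _record_from_obj(obj: object, index: int) -> TrialRecord:
    label = f"#{index}"
    _require(isinstance(obj, dict), label, "", "record must be a JSON object")
    assert isinstance(obj, dict)
    nct_id = obj.get("nct_id")
    _require(isinstance(nct_id, str) and nct_id != "", label, "nct_id", "nonempty string required")
    assert isinstance(nct_id, str)
    allocation = obj.get("allocation")
    _require(allocation in ALLOCATIONS, nct_id, "allocation", f"must be one of {ALLOCATIONS}")
    roles = obj.get("masking_roles")
    _require(
        isinstance(roles, list) and all(isinstance(r, str) for r in roles),
        nct_id, "masking_roles", "must be a list of strings",
    )
    arms_obj = obj.get("arms")
    _require(isinstance(arms_obj, list), nct_id, "arms", "must be a list")
    arms = []
    for arm in arms_obj:  # type: ignore[union-attr]
        _require(isinstance(arm, dict), nct_id, "arms", "each arm must be an object")
        arm_label = arm.get("label")
        _require(isinstance(arm_label, str), nct_id, "arms.label", "string required")
        n = arm.get("n_participants")
        _require(isinstance(n, int) and not isinstance(n, bool) and n >= 0,
                 nct_id, "arms.n_participants", "nonnegative integer required")
        entries = []
        for ae in arm.get("adverse_events", []):
            _require(isinstance(ae, dict), nct_id, "arms.adverse_events", "each entry must be an object")
            term = ae.get("term")
            _require(isinstance(term, str), nct_id, "adverse_events.term", "string required")
            affected, at_risk = ae.get("affected"), ae.get("at_risk")
            for key, val in (("affected", affected), ("at_risk", at_risk)):
                _require(isinstance(val, int) and not isinstance(val, bool) and val >= 0,
                         nct_id, f"adverse_events.{key}", "nonnegative integer required")
            _require(affected <= at_risk, nct_id, "adverse_events", "affected must be <= at_risk")
            entries.append(AdverseEventEntry(term=term, affected=affected, at_risk=at_risk))
        arms.append(ArmReport(label=arm_label, n_participants=n, ae_entries=tuple(entries)))
    return TrialRecord(
        nct_id=nct_id,
        allocation=allocation,  # type: ignore[arg-type]
        masking_roles=frozenset(roles),  # type: ignore[arg-type]
        arms=tuple(arms),
    )


def load_trial_records(path: str | Path) -> list[TrialRecord]:
    """Load and validate a JSON array of trial records, preserving order.

    Raises :class:`json.JSONDecodeError` (which names the byte offset) for
    malformed JSON and :class:`SchemaError` naming the offending record and
    field for schema violations. Duplicate ``nct_id`` values are rejected.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise SchemaError("record '<root>', field '': top-level JSON value must be an array")
    records = [_record_from_obj(obj, i) for i, obj in enumerate(data)]
    seen: set[str] = set()
    for rec in records:
        _require(rec.nct_id not in seen, rec.nct_id, "nct_id", "duplicate registry id")
        seen.add(rec.nct_id)
    return records


def _record_to_obj(record: TrialRecord) -> dict:
    return {
        "nct_id": record.nct_id,
        "allocation": record.allocation,
        "masking_roles": sorted(record.masking_roles),
        "arms": [
            {
                "label": arm.label,
                "n_participants": arm.n_participants,
                "adverse_events": [
                    {"term": ae.term, "affected": ae.affected, "at_risk": ae.at_risk}
                    for ae in arm.ae_entries
                ],
            }
            for arm in record.arms
        ],
    }


def write_trial_records(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Serialize trial records to the JSON dialect read by :func:`load_trial_records`."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([_record_to_obj(r) for r in records], fh, indent=1)
        fh.write("\n")


def load_lexicon(path: str | Path) -> dict[str, LexiconEntry]:
    """Read a drug-name lexicon TSV with columns name, ingredient_code, n_ingredients."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "ingredient_code": str})
    return {
        str(row["name"]): LexiconEntry(str(row["ingredient_code"]), int(row["n_ingredients"]))
        for _, row in df.iterrows()
    }


def load_ae_map(path: str | Path) -> dict[str, str]:
    """Read an adverse-event-term to ICD10 mapping TSV with columns term, icd10."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {str(row["term"]): str(row["icd10"]) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def passes_quality_filter(record: TrialRecord) -> bool:
    """True iff the trial is randomized and uses participant blinding."""
    return record.allocation == "randomized" and "participant" in record.masking_roles


def filter_small_arms(record: TrialRecord, min_n: int = 100) -> TrialRecord:
    """Drop arms enrolling fewer than ``min_n`` participants."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    return replace(record, arms=tuple(a for a in record.arms if a.n_participants >= min_n))


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric token runs of a label."""
    return _TOKEN_RE.findall(text.lower())


def map_arm_to_ingredient(
    label: str, lexicon: Mapping[str, LexiconEntry]
) -> str | RejectionReason:
    """Resolve an arm label to a single ingredient code, or a rejection reason.

    Labels containing ``+`` are rejected outright (combination treatments).
    Otherwise the lexicon name maximizing the fraction of the *label's* token
    set covered is selected; the match is accepted only if that fraction is at
    least 0.5 (inclusive) and the entry maps to a single ingredient. Ties on
    the fraction are broken by lexicographic lexicon-name order so the result
    is deterministic.
    """
    if not lexicon:
        raise ValueError("lexicon must be nonempty")
    if "+" in label:
        return RejectionReason.PLUS_SIGN
    label_tokens = set(tokenize(label))
    if not label_tokens:
        return RejectionReason.NO_MATCH
    best_frac, best_entry = 0.0, None
    for name in sorted(lexicon):
        overlap = len(label_tokens & set(tokenize(name)))
        frac = overlap / len(label_tokens)
        if frac > best_frac:
            best_frac, best_entry = frac, lexicon[name]
    if best_entry is None:
        return RejectionReason.NO_MATCH
    if best_frac < 0.5:
        return RejectionReason.LOW_OVERLAP
    if best_entry.n_ingredients != 1:
        return RejectionReason.MULTI_INGREDIENT
    return best_entry.ingredient_code


def map_ae_term(term: str, ae_map: Mapping[str, str]) -> str | None:
    """Exact case-normalized lookup of an adverse-event term; None when unmapped."""
    normalized = {k.strip().lower(): v for k, v in ae_map.items()}
    return normalized.get(term.strip().lower())


def extract_ingredient_arms(
    record: TrialRecord,
    lexicon: Mapping[str, LexiconEntry],
    ae_map: Mapping[str, str],
    apply_quality_filter: bool = True,
    min_n: int = 100,
    log: IngestLog | None = None,
) -> list[IngredientArm]:
    """Run the full per-trial filter pipeline and emit ingredient-coded arms.

    Returns an empty list when the quality filter is enabled and fails
    (disable it with ``apply_quality_filter=False`` for the ablated pipeline).
    Small arms are removed first, then labels mapped (rejected arms dropped),
    then AE terms mapped to ICD10; unmapped terms are dropped. When several
    terms in one arm map to the same ICD10 code, affected and at-risk counts
    are summed and affected is capped at at-risk.
    """
    log = log if log is not None else IngestLog()
    if apply_quality_filter and not passes_quality_filter(record):
        log.trials_failed_quality += 1
        return []
    kept = filter_small_arms(record, min_n=min_n)
    log.arms_below_min_n += len(record.arms) - len(kept.arms)
    out: list[IngredientArm] = []
    ae_normalized = {k.strip().lower(): v for k, v in ae_map.items()}
    for arm in kept.arms:
        mapped = map_arm_to_ingredient(arm.label, lexicon)
        if isinstance(mapped, RejectionReason):
            log.arm_rejections[mapped.value] += 1
            continue
        counts: dict[str, list[int]] = {}
        for ae in arm.ae_entries:
            code = ae_normalized.get(ae.term.strip().lower())
            if code is None:
                log.unmapped_ae_terms[ae.term] += 1
                continue
            acc = counts.setdefault(code, [0, 0])
            acc[0] += ae.affected
            acc[1] += ae.at_risk
        final: dict[str, tuple[int, int]] = {}
        for code, (affected, at_risk) in counts.items():
            if affected > at_risk:
                log.capped_ae_codes += 1
                logger.warning(
                    "trial %s arm %r: affected > at_risk for %s after merging; capping",
                    record.nct_id, arm.label, code,
                )
                affected = at_risk
            final[code] = (affected, at_risk)
        out.append(
            IngredientArm(
                nct_id=record.nct_id,
                ingredient=mapped,
                n_participants=arm.n_participants,
                ae_counts=final,
            )
        )
    return out
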