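"""Seeded synthetic fixtures and simulations for every stage of the pipeline.

Three generators, all driven by a single root seed with fixed substream
derivation (numpy ``SeedSequence(root, spawn_key=(k,))``; PCG64 bit
generator), so outputs are bitwise reproducible:

* trial-record fixtures exercising every ingest rule (quality filter, small
  arms, token matching, plus signs, multi-ingredient entries, dose and
  cross-trial aggregation), with hand-enumerated expected outcomes;
* contingency tables drawn from a known symmetric spike-and-slab prior over
  log odds ratios, via two binomial arms — under this design the conditional
  law of a table given its margins is exactly the noncentral hypergeometric
  likelihood the estimator assumes, so parameter recovery is a faithful test;
* non-experimental method outputs with controllable power and systematic bias.

The defaults (5000 comparisons, prior 0.8*d0 + 0.1*d(+log4) + 0.1*d(-log4),
arm sizes 200-2000, event base rates 0.01-0.3) are the simulation conditions
used by the recovery checks; they mimic trial-report scale data where most
drug pairs have no differential adverse-event effect and a minority carry a
four-fold odds ratio either way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .contingency import ComparisonRecord, ContingencyTable, make_comparison_id, orient
from .evaluation import A_HIGHER, B_HIGHER, MethodResult
from .trial_ingest import (
    AdverseEventEntry,
    ArmReport,
    LexiconEntry,
    TrialRecord,
)

LOG4 = math.log(4.0)

#: substream indices under the root seed
_SUB_PRIOR, _SUB_TABLES, _SUB_METHOD = 0, 1, 2


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for a table simulation: size, prior, arm sizes, base rates."""

    m_comparisons: int = 5000
    prior_spec: tuple[tuple[float, float], ...] = (
        (0.0, 0.8),
        (LOG4, 0.1),
        (-LOG4, 0.1),
    )
    arm_size_range: tuple[int, int] = (200, 2000)
    base_rate_range: tuple[float, float] = (0.01, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        atoms = [a for a, _ in self.prior_spec]
        weights = {a: w for a, w in self.prior_spec}
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("prior weights must sum to 1")
        for a in atoms:
            if abs(weights.get(a, 0.0) - weights.get(-a, 0.0)) > 1e-12:
                raise ValueError("prior must be symmetric about 0")
        if self.arm_size_range[0] < 1 or self.arm_size_range[0] > self.arm_size_range[1]:
            raise ValueError("invalid arm size range")
        lo, hi = self.base_rate_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("base rates must lie strictly inside (0, 1)")


def _rng(seed: int, substream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(substream,)))
    )


# ---------------------------------------------------------------------------
# Tables from a known prior
# ---------------------------------------------------------------------------


def sample_prior_effects(spec: SimulationSpec) -> np.ndarray:
    """I.i.d. log-odds-ratio draws from the spec's discrete prior."""
    rng = _rng(spec.seed, _SUB_PRIOR)
    atoms = np.array([a for a, _ in spec.prior_spec])
    weights = np.array([w for _, w in spec.prior_spec])
    idx = rng.choice(atoms.size, size=spec.m_comparisons, p=weights / weights.sum())
    return atoms[idx]


def simulate_comparison(
    omega: float,
    n_a: int,
    n_b: int,
    base_rate: float,
    seed: int,
    index: int = 0,
) -> ComparisonRecord:
    """One two-binomial comparison: B events at the base rate, A at a log-odds
    offset ``omega``. The returned record is NOT pre-oriented."""
    if n_a < 1 or n_b < 1:
        raise ValueError("arm sizes must be >= 1")
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    rng = _rng(seed, _SUB_TABLES)
    logit = math.log(base_rate / (1.0 - base_rate)) + omega
    p_a = 1.0 / (1.0 + math.exp(-logit))
    x_a = int(rng.binomial(n_a, p_a))
    x_b = int(rng.binomial(n_b, base_rate))
    ae = f"AE{index:05d}"
    return ComparisonRecord(
        comparison_id=make_comparison_id("DRG_A", "DRG_B", ae),
        drug_a="DRG_A",
        drug_b="DRG_B",
        ae=ae,
        nct_ids=(f"SIM{index:07d}",),
        table=ContingencyTable(x_a=x_a, y_a=n_a - x_a, x_b=x_b, y_b=n_b - x_b),
    )


def simulate_tables(spec: SimulationSpec) -> tuple[np.ndarray, list[ComparisonRecord]]:
    """Draw effects from the prior and one unoriented table per effect.

    Returns (true log odds ratios, comparison records), index-aligned.
    """
    omegas = sample_prior_effects(spec)
    rng = _rng(spec.seed, _SUB_TABLES)
    lo_n, hi_n = spec.arm_size_range
    lo_p, hi_p = spec.base_rate_range
    n_a = rng.integers(lo_n, hi_n + 1, size=spec.m_comparisons)
    n_b = rng.integers(lo_n, hi_n + 1, size=spec.m_comparisons)
    base = rng.uniform(lo_p, hi_p, size=spec.m_comparisons)
    logit_b = np.log(base / (1.0 - base))
    p_a = 1.0 / (1.0 + np.exp(-(logit_b + omegas)))
    x_a = rng.binomial(n_a, p_a)
    x_b = rng.binomial(n_b, base)
    records = []
    for i in range(spec.m_comparisons):
        ae = f"AE{i:05d}"
        records.append(
            ComparisonRecord(
                comparison_id=make_comparison_id("DRG_A", "DRG_B", ae),
                drug_a="DRG_A",
                drug_b="DRG_B",
                ae=ae,
                nct_ids=(f"SIM{i:07d}",),
                table=ContingencyTable(
                    x_a=int(x_a[i]), y_a=int(n_a[i] - x_a[i]),
                    x_b=int(x_b[i]), y_b=int(n_b[i] - x_b[i]),
                ),
            )
        )
    return omegas, records


def orient_with_truth(
    records: Sequence[ComparisonRecord], omegas: Sequence[float]
) -> tuple[list[ComparisonRecord], np.ndarray]:
    """Orient records and flip the sign of each true effect that was swapped."""
    if len(records) != len(omegas):
        raise ValueError("records and omegas must be index-aligned")
    oriented, adjusted = [], []
    for rec, omega in zip(records, omegas):
        new = orient(rec)
        oriented.append(new)
        adjusted.append(omega if new.drug_a == rec.drug_a else -omega)
    return oriented, np.asarray(adjusted, dtype=float)


# ---------------------------------------------------------------------------
# Simulated non-experimental method outputs
# ---------------------------------------------------------------------------


def simulate_method_results(
    effects: Sequence[tuple[str, float]],
    power_n: int,
    bias: float,
    seed: int,
    base_rate: float = 0.1,
) -> list[MethodResult]:
    """Simulate a method's output for each (comparison_id, true log OR) pair.

    For each comparison an independent observational 2x2 is drawn with
    ``power_n`` subjects per arm and log odds ratio ``true omega + bias``;
    the p-value comes from the two-sided normal approximation to the
    0.5-corrected sample log odds ratio and the direction from its sign.
    ``bias = 0`` models an unconfounded method; ``|bias| > 0`` systematic
    confounding.
    """
    if power_n < 1:
        raise ValueError("power_n must be >= 1")
    rng = _rng(seed, _SUB_METHOD)
    out = []
    logit_b = math.log(base_rate / (1.0 - base_rate))
    for cid, omega in effects:
        p_a = 1.0 / (1.0 + math.exp(-(logit_b + omega + bias)))
        x_a = rng.binomial(power_n, p_a)
        x_b = rng.binomial(power_n, base_rate)
        cells = np.array(
            [x_a, power_n - x_a, x_b, power_n - x_b], dtype=float
        ) + 0.5
        log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
        se = math.sqrt(np.sum(1.0 / cells))
        p = 2.0 * float(norm.sf(abs(log_or) / se))
        out.append(
            MethodResult(
                comparison_id=cid,
                p_value=min(p, 1.0),
                direction=A_HIGHER if log_or > 0 else B_HIGHER,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ingest fixtures (hand-enumerated expectations recorded below)
# ---------------------------------------------------------------------------

#: comparisons surviving the full fixture pipeline, counted by hand:
#: quality filter ON  -> {nausea sita/glip, hypoglycaemia sita/glip,
#:                        hiccups nicotine/bupropion}            = 3
#: quality filter OFF -> the same three keys (with extra pooled trials)
#:                        plus dry-mouth nicotine/bupropion      = 4
FIXTURE_EXPECTED_COMPARISONS_FILTERED = 3
FIXTURE_EXPECTED_COMPARISONS_UNFILTERED = 4


def fixture_lexicon() -> dict[str, LexiconEntry]:
    """Drug-name lexicon matching the fixture trials (one multi-ingredient row)."""
    return {
        "sitagliptin": LexiconEntry("A10BH01", 1),
        "glipizide": LexiconEntry("A10BB07", 1),
        "nicotine": LexiconEntry("N07BA01", 1),
        "bupropion": LexiconEntry("N06AX12", 1),
        "aspirin dipyridamole": LexiconEntry("B01AC30", 2),
    }


def fixture_ae_map() -> dict[str, str]:
    return {
        "nausea": "R11.0",
        "feeling sick": "R11.0",  # second term on the same ICD10 code
        "hypoglycaemia": "E16.2",
        "hiccups": "R06.6",
        "dry mouth": "K11.7",
    }


def generate_fixture_trials(seed: int = 0) -> list[TrialRecord]:
    """Deterministic trial records exercising every ingest rule.

    The content is constant (the seed argument is accepted for interface
    uniformity; fixtures are byte-identical across runs regardless). Covered
    cases: a non-randomized trial, an open-label trial, a 99-participant arm,
    a '+'-labelled arm, a multi-ingredient label, a low-token-overlap label,
    an unmapped adverse-event term, duplicate terms mapping to one ICD10
    code, two trials sharing a drug pair and adverse event, and
    duplicate-dose arms within one trial.
    """

    def arm(label: str, n: int, *aes: tuple[str, int, int]) -> ArmReport:
        return ArmReport(
            label=label,
            n_participants=n,
            ae_entries=tuple(AdverseEventEntry(t, a, r) for t, a, r in aes),
        )

    return [
        TrialRecord(
            nct_id="NCT90000001",
            allocation="randomized",
            masking_roles=frozenset({"participant", "investigator"}),
            arms=(
                arm("Sitagliptin phosphate", 300,
                    ("Nausea", 9, 300), ("Hypoglycaemia", 4, 300),
                    ("Weird syndrome", 2, 300)),
                arm("Glipizide", 300,
                    ("Nausea", 12, 300), ("Feeling sick", 3, 300),
                    ("Hypoglycaemia", 30, 300)),
            ),
        ),
        TrialRecord(
            nct_id="NCT90000002",
            allocation="randomized",
            masking_roles=frozenset({"participant"}),
            arms=(
                arm("Sitagliptin", 150, ("Nausea", 5, 150)),
                arm("Glipizide", 150, ("Nausea", 8, 150)),
            ),
        ),
        TrialRecord(  # fails quality filter: not randomized
            nct_id="NCT90000003",
            allocation="non_randomized",
            masking_roles=frozenset({"participant"}),
            arms=(
                arm("Nicotine", 200, ("Hiccups", 10, 200)),
                arm("Bupropion", 200, ("Hiccups", 1, 200)),
            ),
        ),
        TrialRecord(  # fails quality filter: open label
            nct_id="NCT90000004",
            allocation="randomized",
            masking_roles=frozenset(),
            arms=(
                arm("Nicotine", 180, ("Hiccups", 8, 180), ("Dry mouth", 12, 180)),
                arm("Bupropion", 180, ("Hiccups", 2, 180), ("Dry mouth", 3, 180)),
            ),
        ),
        TrialRecord(  # low-token-overlap arm label; lone surviving arm pairs with nothing
            nct_id="NCT90000005",
            allocation="randomized",
            masking_roles=frozenset({"participant", "investigator"}),
            arms=(
                arm("Nicotine patch 21 mg daily", 250, ("Hiccups", 5, 250)),
                arm("Bupropion", 250, ("Hiccups", 3, 250)),
            ),
        ),
        TrialRecord(  # plus-sign and multi-ingredient rejections
            nct_id="NCT90000006",
            allocation="randomized",
            masking_roles=frozenset({"participant"}),
            arms=(
                arm("Aspirin + Dipyridamole", 400, ("Nausea", 11, 400)),
                arm("Aspirin Dipyridamole", 400, ("Nausea", 13, 400)),
                arm("Glipizide", 400, ("Nausea", 20, 400)),
            ),
        ),
        TrialRecord(  # small arm dropped; duplicate-dose nicotine arms merged
            nct_id="NCT90000007",
            allocation="randomized",
            masking_roles=frozenset({"participant"}),
            arms=(
                arm("Nicotine", 99, ("Hiccups", 4, 99)),
                arm("Nicotine", 120, ("Hiccups", 6, 120)),
                arm("Nicotine gum", 150, ("Hiccups", 7, 150)),
                arm("Bupropion", 200, ("Hiccups", 1, 200)),
            ),
        ),
    ]


# ---------------------------------------------------------------------------
# Config and TSV plumbing
# ---------------------------------------------------------------------------


def write_lexicon_tsv(lexicon: dict[str, LexiconEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": list(lexicon),
            "ingredient_code": [e.ingredient_code for e in lexicon.values()],
            "n_ingredients": [e.n_ingredients for e in lexicon.values()],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_ae_map_tsv(ae_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"term": list(ae_map), "icd10": list(ae_map.values())}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def spec_from_config(path: str | Path) -> SimulationSpec:
    """Parse a flat key=value config file into a :class:`SimulationSpec`.

    Recognized keys: m_comparisons, seed, arm_size_min, arm_size_max,
    base_rate_min, base_rate_max, prior (comma-separated ``atom:weight``).
    Missing keys keep their defaults.
    """
    values: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    defaults = SimulationSpec()
    prior = defaults.prior_spec
    if "prior" in values:
        prior = tuple(
            (float(a), float(w))
            for a, _, w in (item.partition(":") for item in values["prior"].split(","))
        )
    return SimulationSpec(
        m_comparisons=int(values.get("m_comparisons", defaults.m_comparisons)),
        prior_spec=prior,
        arm_size_range=(
            int(values.get("arm_size_min", defaults.arm_size_range[0])),
            int(values.get("arm_size_max", defaults.arm_size_range[1])),
        ),
        base_rate_range=(
            float(values.get("base_rate_min", defaults.base_rate_range[0])),
            float(values.get("base_rate_max", defaults.base_rate_range[1])),
        ),
        seed=int(values.get("seed", defaults.seed)),
    )
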