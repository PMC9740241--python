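"""Decision-impact audit of a femur-level pilot cohort.

Each record carries the physician's binary risk estimate, the score-based
category, the delivered treatment, six-month outcomes, report delivery delay
and whether the score was used.  ``summarize`` reproduces the pilot
tabulations: the physician-vs-score cross-tab, discrepancy count (a moderate
score always counts as discrepant with a binary physician estimate), the
adapted-treatment counts, outcome percentages (death at patient level),
delivery-time distribution and usage percentage.  Percentages are rounded to
the nearest integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CohortError",
    "CohortRecord",
    "AuditSummary",
    "load_cohort",
    "summarize",
    "bundled_cohort_path",
]

PHYSICIAN_RISKS = ("low", "high")
BOS_RISKS = ("low", "moderate", "high")
TREATMENTS = ("none", "rt_single", "rt_multiple", "elective_surgery")
DELIVERY_DAYS = (0, 1, 2)

COLUMNS = [
    "patient_id",
    "femur_id",
    "physician_risk",
    "bos_risk",
    "treatment",
    "fractured_6mo",
    "died_6mo",
    "delivery_days",
    "bos_used",
]


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    femur_id: str
    physician_risk: str
    bos_risk: str
    treatment: str
    fractured_6mo: bool
    died_6mo: bool
    delivery_days: int
    bos_used: bool


@dataclass
class AuditSummary:
    n_femurs: int
    n_patients: int
    crosstab: dict  # (physician, bos) -> {"n": ..., "treatments": {...}, "fractures": ...}
    discrepancy_count: int
    bos_totals: dict
    physician_totals: dict
    fracture_count: int
    fracture_pct: int
    death_count: int
    death_pct: int
    delivery_counts: dict
    same_day_pct: int
    used_count: int
    used_pct: int
    adapted_probable: int
    adapted_maybe: int
    adapted_probable_plus_maybe: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["crosstab"] = {f"{k[0]}|{k[1]}": v for k, v in self.crosstab.items()}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_markdown(self) -> str:
        lines = [
            "| physician | score risk | n | fractures | none | single RT | multiple RT | surgery |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for (p, b), cell in sorted(self.crosstab.items()):
            t = cell["treatments"]
            lines.append(
                f"| {p} | {b} | {cell['n']} | {cell['fractures']} | "
                f"{t['none']} | {t['rt_single']} | {t['rt_multiple']} | {t['elective_surgery']} |"
            )
        lines += [
            "",
            f"- femurs: {self.n_femurs} (patients: {self.n_patients})",
            f"- discrepant risk estimates: {self.discrepancy_count}",
            f"- score categories high/moderate/low: "
            f"{self.bos_totals['high']}/{self.bos_totals['moderate']}/{self.bos_totals['low']}",
            f"- treatment adapted (probable rule): {self.adapted_probable}"
            f" (probable+maybe: {self.adapted_probable_plus_maybe})",
            f"- fractures: {self.fracture_count} ({self.fracture_pct}%)",
            f"- deaths (patient level): {self.death_count} ({self.death_pct}%)",
            f"- delivery same day: {self.same_day_pct}%",
            f"- score used: {self.used_pct}%",
        ]
        return "\n".join(lines)


def bundled_cohort_path() -> Path:
    """Path of the packaged pilot-cohort fixture CSV."""
    return Path(resources.files("bosfem").joinpath("data/table2_cohort.csv"))


def load_cohort(path: str | Path) -> list[CohortRecord]:
    """Load and validate a cohort CSV.  Raises with the offending row number
    on any domain violation or duplicated femur id."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []  # an empty file is a valid empty cohort
    if df.empty and len(df.columns) <= 1:
        return []
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"cohort CSV missing columns: {sorted(missing)}")

    records: list[CohortRecord] = []
    seen_femurs: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        r = row._asdict()
        if r["physician_risk"] not in PHYSICIAN_RISKS:
            raise CohortError(f"row {i}: invalid physician_risk {r['physician_risk']!r}")
        if r["bos_risk"] not in BOS_RISKS:
            raise CohortError(f"row {i}: invalid bos_risk {r['bos_risk']!r}")
        if r["treatment"] not in TREATMENTS:
            raise CohortError(f"row {i}: invalid treatment {r['treatment']!r}")
        try:
            delivery = int(r["delivery_days"])
        except ValueError:
            raise CohortError(f"row {i}: invalid delivery_days {r['delivery_days']!r}") from None
        if delivery not in DELIVERY_DAYS:
            raise CohortError(f"row {i}: delivery_days must be one of {DELIVERY_DAYS}")
        if r["femur_id"] in seen_femurs:
            raise CohortError(f"row {i}: duplicate femur id {r['femur_id']!r}")
        seen_femurs.add(r["femur_id"])
        records.append(
            CohortRecord(
                patient_id=r["patient_id"],
                femur_id=r["femur_id"],
                physician_risk=r["physician_risk"],
                bos_risk=r["bos_risk"],
                treatment=r["treatment"],
                fractured_6mo=_parse_bool(r["fractured_6mo"], i, "fractured_6mo"),
                died_6mo=_parse_bool(r["died_6mo"], i, "died_6mo"),
                delivery_days=delivery,
                bos_used=_parse_bool(r["bos_used"], i, "bos_used"),
            )
        )
    return records


def _parse_bool(v: str, row: int, col: str) -> bool:
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise CohortError(f"row {row}: invalid boolean {v!r} in {col}")


def _pct(num: int, den: int) -> int:
    return int(round(100.0 * num / den)) if den else 0


def summarize(cohort: list[CohortRecord]) -> AuditSummary:
    """Descriptive tabulations over a validated cohort.

    Rules: discrepancy = physician estimate differs from the score category,
    with moderate always discrepant against the binary estimate; adapted
    (probable) = physician low AND score moderate/high AND treatment was
    multiple-fraction radiotherapy or elective surgery; adapted (maybe) =
    physician high with a moderate score.
    """
    n = len(cohort)
    crosstab: dict = {}
    for p in PHYSICIAN_RISKS:
        for b in BOS_RISKS:
            crosstab[(p, b)] = {
                "n": 0,
                "fractures": 0,
                "treatments": {t: 0 for t in TREATMENTS},
            }
    for r in cohort:
        cell = crosstab[(r.physician_risk, r.bos_risk)]
        cell["n"] += 1
        cell["fractures"] += int(r.fractured_6mo)
        cell["treatments"][r.treatment] += 1

    discrepancy = sum(1 for r in cohort if r.physician_risk != r.bos_risk)
    bos_totals = {b: sum(1 for r in cohort if r.bos_risk == b) for b in BOS_RISKS}
    phys_totals = {p: sum(1 for r in cohort if r.physician_risk == p) for p in PHYSICIAN_RISKS}

    fracture_count = sum(r.fractured_6mo for r in cohort)
    patients = {r.patient_id for r in cohort}
    died_patients = {r.patient_id for r in cohort if r.died_6mo}
    delivery_counts = {d: sum(1 for r in cohort if r.delivery_days == d) for d in DELIVERY_DAYS}
    used_count = sum(r.bos_used for r in cohort)

    adapted_probable = sum(
        1
        for r in cohort
        if r.physician_risk == "low"
        and r.bos_risk in ("moderate", "high")
        and r.treatment in ("rt_multiple", "elective_surgery")
    )
    adapted_maybe = sum(
        1 for r in cohort if r.physician_risk == "high" and r.bos_risk == "moderate"
    )

    return AuditSummary(
        n_femurs=n,
        n_patients=len(patients),
        crosstab=crosstab,
        discrepancy_count=discrepancy,
        bos_totals=bos_totals,
        physician_totals=phys_totals,
        fracture_count=int(fracture_count),
        fracture_pct=_pct(int(fracture_count), n),
        death_count=len(died_patients),
        death_pct=_pct(len(died_patients), len(patients)),
        delivery_counts=delivery_counts,
        same_day_pct=_pct(delivery_counts[0], n),
        used_count=int(used_count),
        used_pct=_pct(int(used_count), n),
        adapted_probable=adapted_probable,
        adapted_maybe=adapted_maybe,
        adapted_probable_plus_maybe=adapted_probable + adapted_maybe,
    )
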