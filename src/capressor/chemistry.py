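"""Blood-chemistry aggregation and testing across experimental rounds.

The packaged fixture transcribes the per-animal arterial pH and ionized
calcium (iCa, mmol/L) panels of three swine cohorts across a baseline round
and up to five post-injury rounds.  Records are grouped as baseline /
round 1 / "other rounds" (round >= 2).  For the other-rounds group two
poolings are supported:

``per_animal`` (default)
    each animal contributes the average of its round-2+ values, and the
    group statistics run over those animal means — the aggregation the
    source analysis used ("average remaining rounds" per experiment);
``pooled``
    every round-2+ record enters individually.

Both are reported by :func:`table3_report`, which also flags where the
pooled recomputation disagrees with the published summary table.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ChemistryRecord",
    "ChemistrySummary",
    "AnovaResult",
    "load_chemistry",
    "packaged_records",
    "records_to_frame",
    "aggregate",
    "one_way_anova",
    "ica_anova",
    "table3_report",
]

ROUND_BASELINE = "baseline"
MAX_ROUNDS = {1: 5, 2: 4, 3: 4}
ANALYTES = ("pH", "iCa")
GROUPS = ("baseline", "round1", "other_rounds")

#: published summary-table values the report compares against (2-dp print)
PUBLISHED_TABLE3 = {
    "baseline": {"n": 24, "pH": (7.46, 0.07), "iCa": (1.28, 0.09)},
    "round1": {"n": 20, "pH": (7.33, 0.11), "iCa": (1.23, 0.08)},
    "other_rounds": {"n": 43, "pH": (7.34, 0.08), "iCa": (1.19, 0.12)},
}


@dataclasses.dataclass(frozen=True)
class ChemistryRecord:
    """One animal-round blood-gas panel."""

    cohort: int
    animal: int
    round: str  # "baseline" or "1".."5"
    pH: float | None
    iCa: float | None
    bolus_ca_count: int | None = None
    epi_count: int | None = None
    missing: bool = False
    suspect: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in MAX_ROUNDS:
            raise ValueError(f"unknown cohort {self.cohort}")
        if self.round != ROUND_BASELINE:
            r = int(self.round)
            if not 1 <= r <= MAX_ROUNDS[self.cohort]:
                raise ValueError(
                    f"round {self.round} invalid for cohort {self.cohort} "
                    f"(max {MAX_ROUNDS[self.cohort]})"
                )
        if not self.missing:
            if self.iCa is not None and self.iCa <= 0:
                raise ValueError(f"iCa must be > 0, got {self.iCa}")

    @property
    def group(self) -> str:
        if self.round == ROUND_BASELINE:
            return "baseline"
        return "round1" if int(self.round) == 1 else "other_rounds"


@dataclasses.dataclass
class ChemistrySummary:
    """Mean and sample SD per analyte for one group.

    ``n_experiments`` counts non-missing records in the group (the unit the
    published headers use); ``n_units`` is the number of values the
    statistics actually run over (equal to ``n_experiments`` for pooled
    aggregation, the number of animals for per-animal averaging).
    """

    group: str
    n_experiments: int
    n_units: int
    mean: dict[str, float]
    sd: dict[str, float]


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def load_chemistry(path: str | Path) -> list[ChemistryRecord]:
    """Load a tidy chemistry CSV (comment lines start with ``#``).

    The literal cell value ``missing`` marks lost data; such records are
    flagged and excluded from aggregation.  Rounds an animal did not survive
    to simply have no row.
    """
    frame = pd.read_csv(path, comment="#", dtype=str).fillna("")
    required = {"cohort", "animal", "round", "pH", "iCa"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}, got {list(frame.columns)}")
    records: list[ChemistryRecord] = []
    for idx, row in frame.iterrows():
        missing = row["pH"].strip().lower() == "missing" or row["iCa"].strip().lower() == "missing"

        def _num(cell: str) -> float | None:
            cell = cell.strip()
            if cell == "" or cell.lower() == "missing":
                return None
            return float(cell)

        def _count(col: str) -> int | None:
            if col not in frame.columns:
                return None
            cell = str(row[col]).strip()
            return int(cell) if cell not in ("", "nan") else None

        try:
            rec = ChemistryRecord(
                cohort=int(row["cohort"]),
                animal=int(row["animal"]),
                round=str(row["round"]).strip(),
                pH=_num(row["pH"]),
                iCa=_num(row["iCa"]),
                bolus_ca_count=_count("bolus_ca_count"),
                epi_count=_count("epi_count"),
                missing=missing,
                suspect=bool(int(row["suspect"])) if str(row.get("suspect", "")).strip() else False,
                note=str(row.get("note", "")).strip(),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return records


def packaged_records(cohorts: tuple[int, ...] = (1, 2)) -> list[ChemistryRecord]:
    """Records from the packaged fixture, restricted to ``cohorts``."""
    with resources.as_file(resources.files("capressor.data") / "blood_chemistry.csv") as p:
        records = load_chemistry(p)
    return [r for r in records if r.cohort in cohorts]


def records_to_frame(records: list[ChemistryRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def _group_values(
    records: list[ChemistryRecord], group: str, analyte: str, pooling: str
) -> np.ndarray:
    """Values entering the statistics for one group/analyte."""
    recs = [r for r in records if r.group == group and not r.missing and getattr(r, analyte) is not None]
    if group != "other_rounds" or pooling == "pooled":
        return np.array([getattr(r, analyte) for r in recs], dtype=float)
    if pooling != "per_animal":
        raise ValueError(f"unknown pooling {pooling!r}")
    by_animal: dict[tuple[int, int], list[float]] = {}
    for r in recs:
        by_animal.setdefault((r.cohort, r.animal), []).append(float(getattr(r, analyte)))
    return np.array([np.mean(v) for _, v in sorted(by_animal.items())], dtype=float)


def aggregate(
    records: list[ChemistryRecord],
    pooling: str = "per_animal",
) -> list[ChemistrySummary]:
    """Group summaries (baseline / round 1 / other rounds) over non-missing
    records.  ``pooling`` applies to the other-rounds group only."""
    if not records:
        raise ValueError("aggregate needs a nonempty record set")
    out = []
    for group in GROUPS:
        n_exp = sum(
            1
            for r in records
            if r.group == group and not r.missing and (r.pH is not None or r.iCa is not None)
        )
        mean: dict[str, float] = {}
        sd: dict[str, float] = {}
        n_units = 0
        for analyte in ANALYTES:
            vals = _group_values(records, group, analyte, pooling)
            n_units = max(n_units, len(vals))
            if len(vals) == 0:
                mean[analyte] = float("nan")
                sd[analyte] = float("nan")
            else:
                mean[analyte] = float(np.mean(vals))
                sd[analyte] = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        out.append(ChemistrySummary(group, n_exp, n_units, mean, sd))
    return out


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA over >= 2 groups of n >= 2."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    F, p = sstats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return AnovaResult(float(F), k - 1, n - k, float(p))


def ica_anova(
    records: list[ChemistryRecord] | None = None,
    pooling: str = "per_animal",
) -> AnovaResult:
    """One-way ANOVA of ionized calcium across baseline / round 1 / other
    rounds (packaged cohorts 1-2 fixture by default)."""
    records = records if records is not None else packaged_records((1, 2))
    groups = [_group_values(records, g, "iCa", pooling) for g in GROUPS]
    return one_way_anova(groups)


def table3_report(records: list[ChemistryRecord] | None = None) -> dict:
    """Recompute the published cohort-1/2 summary table both ways and flag
    disagreements with the printed values at 2-dp rounding."""
    records = records if records is not None else packaged_records((1, 2))
    report: dict = {"groups": {}, "discrepancies": []}
    summaries = {p: {s.group: s for s in aggregate(records, pooling=p)} for p in ("per_animal", "pooled")}
    for group in GROUPS:
        entry: dict = {"n_experiments": summaries["per_animal"][group].n_experiments}
        for analyte in ANALYTES:
            for pooling in ("per_animal", "pooled"):
                s = summaries[pooling][group]
                entry[f"{analyte}_{pooling}_mean"] = round(s.mean[analyte], 2)
                entry[f"{analyte}_{pooling}_sd"] = round(s.sd[analyte], 2)
            published_mean, published_sd = PUBLISHED_TABLE3[group][analyte]
            entry[f"{analyte}_published"] = [published_mean, published_sd]
            for pooling in ("per_animal", "pooled"):
                got = (entry[f"{analyte}_{pooling}_mean"], entry[f"{analyte}_{pooling}_sd"])
                if got != (published_mean, published_sd):
                    report["discrepancies"].append(
                        {
                            "group": group,
                            "analyte": analyte,
                            "pooling": pooling,
                            "recomputed": list(got),
                            "published": [published_mean, published_sd],
                        }
                    )
        report["groups"][group] = entry
    for pooling in ("per_animal", "pooled"):
        a = ica_anova(records, pooling=pooling)
        report[f"ica_anova_{pooling}"] = {
            "F": a.F,
            "df_between": a.df_between,
            "df_within": a.df_within,
            "p": a.p,
        }
    return report
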