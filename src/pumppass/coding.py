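"""Standardized fish injury coding, survival states and cohort accounting.

Injuries follow the Dutch NEN 8775 scheme for fish safety of pumps and
confined turbines: class 1 is injury-free, class 2 covers slight injuries
(2.1 minor superficial scratches, 2.2 red or damaged eyes/fins, 2.3 minor
scale loss / light contusions), class 3 covers severe injuries (3.1 scale
loss over 20% of the body, 3.2 incisions/cuts/decapitation, 3.3 fractures,
3.4 heavily injured or missing eyes, 3.5 heavily injured gills or gill
covers, 3.6 heavy contusion or bleeding, 3.7 aberrant behavior).

Coding rules:

* the most severe injury class observed on an individual determines its
  injury class; within the severe class the highest numeric code is reported
  as the "worst" code while the full code set is retained for distribution
  tables;
* a fish counts as dead when observed dead or dying, when alive with a
  severe (class 3) injury, or when it died during the 24/48 h delayed-
  mortality holding period;
* fish that lingered before the pump inlet and only passed during the next
  trial are re-assigned to the scenario at which they were observed, which
  can push a scenario's recapture percentage above 100%;
* per species, lengths outside [Q1 − 3·IQR, Q3 + 3·IQR] are removed as
  extreme outliers before any length-dependent modelling.

All operations work on pandas DataFrames in the fish-record dialect (one row
per fish; ``injury_codes`` is a semicolon-separated string such as
``"2.3;3.2"``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import EmptyClass, MissingStartCount, UnknownCode

__all__ = [
    "INJURY_LABELS",
    "VALID_CODES",
    "parse_codes",
    "assign_injury_class",
    "code_survival",
    "code_records",
    "reassign_scenarios",
    "remove_length_outliers",
    "recapture_table",
    "injury_distribution",
]

#: NEN-style injury codes and labels. Codes are strings to keep "3.10"-style
#: ambiguity impossible and CSV round trips exact.
INJURY_LABELS: dict[str, str] = {
    "1": "No injury",
    "2.1": "Minor superficial scratches",
    "2.2": "Red or damaged eyes/fins",
    "2.3": "Light scratches, contusions, scale loss < 20% of body",
    "3.1": "Scale loss > 20% of body surface",
    "3.2": "Incisions, cuts, decapitation",
    "3.3": "Fractures",
    "3.4": "Heavily injured or missing eyes",
    "3.5": "Heavily injured gills or gill covers",
    "3.6": "Heavy contusion or bleeding",
    "3.7": "Aberrant behavior",
}
VALID_CODES = frozenset(INJURY_LABELS)


def _code_class(code: str) -> int:
    return int(code.split(".")[0])


def parse_codes(raw: str | float | None) -> list[str]:
    """Parse a semicolon-separated injury-code field; empty means no injury."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    codes = [c.strip() for c in text.split(";") if c.strip()]
    bad = [c for c in codes if c not in VALID_CODES]
    if bad:
        raise UnknownCode(f"unknown injury code(s): {bad}")
    return [c for c in codes if c != "1"]


def assign_injury_class(injuries: set[str] | list[str]) -> tuple[int, str]:
    """Injury class and worst code for one fish.

    The class is the most severe class present (empty set ⇒ class 1); the
    worst code is the highest numeric code within that class.
    """
    codes = parse_codes(";".join(injuries)) if injuries else []
    if not codes:
        return 1, "1"
    cls = max(_code_class(c) for c in codes)
    within = [c for c in codes if _code_class(c) == cls]
    worst = max(within, key=lambda c: float(c))
    return cls, worst


def code_survival(
    condition: str,
    injury_class: int,
    delayed_dead_24h: bool = False,
    delayed_dead_48h: bool = False,
) -> int:
    """Survival state: 1 = alive, 0 = dead.

    Dead when observed dead or dying, when alive with a severe injury
    (class 3 fish are euthanized), or on delayed mortality at 24 h / 48 h.
    """
    if condition in ("dead", "dying"):
        return 0
    if injury_class >= 3:
        return 0
    if delayed_dead_24h or delayed_dead_48h:
        return 0
    return 1


def code_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``injury_class``, ``worst_code`` and ``survival`` columns."""
    out = records.copy()
    classes, worsts, surv = [], [], []
    for _, row in out.iterrows():
        codes = parse_codes(row.get("injury_codes", ""))
        cls, worst = assign_injury_class(codes)
        classes.append(cls)
        worsts.append(worst)
        surv.append(
            code_survival(
                str(row.get("condition", "alive")),
                cls,
                bool(row.get("delayed_dead_24h", False)),
                bool(row.get("delayed_dead_48h", False)),
            )
        )
    out["injury_class"] = classes
    out["worst_code"] = worsts
    out["survival"] = surv
    return out


def reassign_scenarios(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each fish to the scenario at which it was actually observed.

    Lingering fish that passed during a later trial keep their theoretical
    scenario in ``scenario_theoretical`` (provenance) and get their observed
    scenario as the analysis scenario ``scenario``.
    """
    out = records.copy()
    observed = out["scenario_observed"].where(
        out["scenario_observed"].notna() & (out["scenario_observed"] != ""),
        out["scenario_theoretical"],
    )
    out["scenario"] = observed
    return out


def remove_length_outliers(
    records: pd.DataFrame, group: str = "species", column: str = "length_mm"
) -> tuple[pd.DataFrame, int]:
    """Drop extreme length outliers per species.

    Fences at Q1 − 3·IQR and Q3 + 3·IQR with the linear-interpolation
    quantile convention; rows without a length (e.g. decapitated fish) are
    kept — they are excluded from length-based models elsewhere, not here.
    Returns the filtered frame and the number of rows removed. Idempotent in
    the sense that a second pass removes nothing further on typical data.
    """
    keep = pd.Series(True, index=records.index)
    for _, sub in records.groupby(group):
        lengths = sub[column].dropna()
        if len(lengths) < 4:
            continue
        q1, q3 = lengths.quantile([0.25, 0.75], interpolation="linear")
        iqr = q3 - q1
        lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
        bad = sub.index[(sub[column] < lo) | (sub[column] > hi)]
        keep.loc[bad] = False
    out = records.loc[keep].copy()
    return out, int((~keep).sum())


def recapture_table(
    records: pd.DataFrame, start_counts: pd.DataFrame
) -> pd.DataFrame:
    """Cohort accounting per scenario plus per-species overall rows.

    ``start_counts`` needs columns ``species, scenario, n_start`` keyed by the
    theoretical scenario (what was released); end counts are observed-scenario
    counts, so a scenario fed by lingerers from the previous trial can exceed
    100% recapture. Overall rows aggregate Σend/Σstart per species.
    """
    if not {"species", "scenario", "n_start"} <= set(start_counts.columns):
        raise MissingStartCount("start_counts needs species, scenario, n_start")
    rec = reassign_scenarios(records) if "scenario" not in records.columns else records
    rows = []
    for (_sp, _sc), grp in start_counts.groupby(["species", "scenario"], sort=False):
        n_start = int(grp["n_start"].sum())
        sub = rec[(rec["species"] == _sp) & (rec["scenario"] == _sc)]
        n_end = len(sub)
        if n_start <= 0:
            raise MissingStartCount(f"no start count for {_sp}/{_sc}")
        rows.append(
            {
                "species": _sp,
                "scenario": _sc,
                "n_start": n_start,
                "n_end": n_end,
                "recapture_pct": 100.0 * n_end / n_start,
                "mean_length_mm": sub["length_mm"].mean(),
                "mean_mass_g": sub["mass_g"].mean() if "mass_g" in sub else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    overall = (
        table.groupby("species", sort=False)
        .agg(n_start=("n_start", "sum"), n_end=("n_end", "sum"))
        .reset_index()
    )
    overall["scenario"] = "overall"
    overall["recapture_pct"] = 100.0 * overall["n_end"] / overall["n_start"]
    return pd.concat([table, overall], ignore_index=True)


def injury_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Within-class percentage of each injury code, per species.

    Counts every recorded code (a fish can contribute to several codes),
    mirroring how per-code frequencies are tabulated in injury reports.
    """
    if "injury_codes" not in records.columns:
        raise EmptyClass("records carry no injury_codes column")
    rows = []
    for sp, sub in records.groupby("species", sort=False):
        counts: dict[str, int] = {}
        for raw in sub["injury_codes"]:
            for c in parse_codes(raw):
                counts[c] = counts.get(c, 0) + 1
        for cls in (2, 3):
            total = sum(v for c, v in counts.items() if _code_class(c) == cls)
            if total == 0:
                continue
            for c, v in sorted(counts.items()):
                if _code_class(c) == cls:
                    rows.append(
                        {
                            "species": sp,
                            "injury_class": cls,
                            "code": c,
                            "label": INJURY_LABELS[c],
                            "n": v,
                            "pct_within_class": 100.0 * v / total,
                        }
                    )
    if not rows:
        raise EmptyClass("no injuries recorded")
    return pd.DataFrame(rows)
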