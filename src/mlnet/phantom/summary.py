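"""Cohort characteristic tables: per-group counts, percentages and
between-cohort Kruskal-Wallis p-values."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["cohort_table", "summarize_cohort", "CohortSummary"]

_VARIABLES = {
    "sex": ["F", "M"],
    "cT": ["1-2", "3", "4"],
    "cN": [0, 1, 2],
    "cr": [0, 1],
    "emvi": [1, 0],
}
_LEVEL_NAMES = {
    "sex": {"F": "Female", "M": "Male"},
    "cr": {0: "non-CR", 1: "CR"},
    "emvi": {1: "EMVI+", 0: "EMVI-"},
}
_CODES = {
    "sex": {"F": 0, "M": 1},
    "cT": {"1-2": 0, "3": 1, "4": 2},
}


def cohort_table(cases) -> pd.DataFrame:
    """Flatten CaseRecords (or pass a sidecar-schema DataFrame through)."""
    if isinstance(cases, pd.DataFrame):
        return cases.copy()
    rows = [
        {
            "patient_id": c.patient_id,
            "centre_id": c.centre_id,
            "emvi": c.emvi_label,
            "cr": c.cr_label,
            "age": c.age,
            "sex": c.sex,
            "cT": c.cT,
            "cN": c.cN,
        }
        for c in cases
    ]
    return pd.DataFrame(rows)


@dataclass
class CohortSummary:
    """Long-format summary: one row per (variable, level, group)."""

    table: pd.DataFrame
    totals: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)

    def count(self, variable: str, level, group: str) -> int:
        sel = self.table[
            (self.table["variable"] == variable)
            & (self.table["level"] == str(level))
            & (self.table["group"] == group)
        ]
        if sel.empty:
            raise KeyError((variable, level, group))
        return int(sel["count"].iloc[0])

    def percent(self, variable: str, level, group: str) -> int:
        sel = self.table[
            (self.table["variable"] == variable)
            & (self.table["level"] == str(level))
            & (self.table["group"] == group)
        ]
        if sel.empty:
            raise KeyError((variable, level, group))
        return int(sel["percent"].iloc[0])

    def total(self, group: str) -> int:
        return self.totals[group]

    def to_text(self) -> str:
        lines = []
        groups = list(self.totals)
        for variable in self.table["variable"].unique():
            lines.append(variable)
            sub = self.table[self.table["variable"] == variable]
            for level in sub["level"].unique():
                cells = []
                for g in groups:
                    row = sub[(sub["level"] == level) & (sub["group"] == g)]
                    cells.append(
                        f"{int(row['count'].iloc[0])} ({int(row['percent'].iloc[0])}%)"
                        if not row.empty
                        else "-"
                    )
                p = self.p_values.get(variable)
                ptxt = f"  p={p:.2f}" if p is not None and level == sub["level"].iloc[0] else ""
                lines.append(f"  {level}: " + "  ".join(cells) + ptxt)
        lines.append("Total: " + "  ".join(f"{g}={n}" for g, n in self.totals.items()))
        return "\n".join(lines)


def summarize_cohort(cohorts: dict, compare: tuple[str, str] | None = None) -> CohortSummary:
    """Summarise one or more named cohorts.

    ``cohorts`` maps group name -> list of CaseRecord or sidecar DataFrame.
    ``compare`` names two groups whose variables are compared with the
    Kruskal-Wallis test (defaults to the first and last group when there are
    at least two).
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    tables = {name: cohort_table(c) for name, c in cohorts.items()}
    for name, df in tables.items():
        if df.empty:
            raise ValueError(f"cohort {name!r} is empty")

    rows = []
    totals = {}
    for name, df in tables.items():
        n = len(df)
        totals[name] = n
        for variable, levels in _VARIABLES.items():
            for level in levels:
                count = int((df[variable] == level).sum())
                label = _LEVEL_NAMES.get(variable, {}).get(level, str(level))
                rows.append(
                    {
                        "variable": variable,
                        "level": label,
                        "group": name,
                        "count": count,
                        "percent": int(round(100.0 * count / n)),
                    }
                )
        rows.append(
            {
                "variable": "age",
                "level": "median (range)",
                "group": name,
                "count": n,
                "percent": 100,
                "display": f"{df['age'].median():.0f} "
                f"({df['age'].min():.0f}-{df['age'].max():.0f})",
            }
        )
    table = pd.DataFrame(rows)

    p_values: dict[str, float] = {}
    names = list(tables)
    if compare is None and len(names) >= 2:
        compare = (names[0], names[-1])
    if compare is not None:
        from ..evalstats import kruskal_wallis

        a, b = tables[compare[0]], tables[compare[1]]
        for variable in ["age", "sex", "cT", "cN", "cr", "emvi"]:
            codes = _CODES.get(variable)
            xa = a[variable].map(codes) if codes else a[variable]
            xb = b[variable].map(codes) if codes else b[variable]
            _, p = kruskal_wallis([np.asarray(xa, float), np.asarray(xb, float)])
            p_values[variable] = float(p)

    return CohortSummary(table=table, totals=totals, p_values=p_values)
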