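"""Group filtering and one-way ANOVA on pattern morphometry.

Replicate containers from the same colony are one group; differences among
colonies in perimeter and area are tested with ordinary fixed-effects one-way
ANOVA, separately per group size and per measure.  Containers where at most
half the workers survived are excluded first: heavy mortality diverts
building material into burying corpses and contaminates the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MEASURES = ("perim_total", "area_mm2", "perim_edge", "perim_away")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.F, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p}


def filter_by_survival(records: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Keep records with survival strictly above the cutoff (0.5 is excluded)."""
    return records[records["survival_rate"] > cutoff].copy()


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of ``values`` across group labels.

    F = MS_between / MS_within with df = (k-1, n-k); p from the upper tail of
    the F distribution.  Unbalanced groups are fine; fewer than two groups or
    zero residual degrees of freedom are errors.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = pd.unique(groups)
    k, n = len(labels), len(values)
    if k < 2:
        raise ValueError(f"need at least 2 groups, got {k}")
    if n - k < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    samples = [values[groups == g] for g in labels]
    if all(np.ptp(s) == 0 for s in samples if len(s) > 1):
        # zero within-group variance: F is 0/0 or infinite; refuse rather
        # than return a misleading number
        if np.ptp(values) == 0:
            raise ValueError("all observations identical; F undefined")
    f, p = sps.f_oneway(*samples)
    return AnovaResult(F=float(f), df_between=k - 1, df_within=n - k,
                       p=float(p))


def anova_table(records: pd.DataFrame, measures=MEASURES,
                survival_cutoff: float | None = 0.5) -> pd.DataFrame:
    """The study's test battery: one ANOVA per group size × measure.

    ``records`` needs columns colony, group_size, the measures, and
    survival_rate (unless ``survival_cutoff`` is None).  Returns one row per
    test with F, dfs and p.
    """
    df = records
    if survival_cutoff is not None:
        df = filter_by_survival(df, survival_cutoff)
    rows = []
    for gs, sub in df.groupby("group_size"):
        for m in measures:
            if m not in sub.columns:
                continue
            res = one_way_anova(sub[m].to_numpy(), sub["colony"].to_numpy())
            rows.append({"group_size": gs, "measure": m, "n": len(sub),
                         **res.to_dict()})
    return pd.DataFrame(rows)


_COLUMN_SYNONYMS = {
    "colony": ("colony", "colony_code", "colony_id", "col"),
    "group_size": ("group_size", "groupsize", "n_workers", "workers", "group"),
    "survival_rate": ("survival_rate", "survival", "surv_rate", "survivalrate"),
    "area_mm2": ("area_mm2", "area", "areas"),
    "perim_total": ("perim_total", "perimeter", "perimeters", "perimeter_total",
                    "total_perimeter"),
    "perim_edge": ("perim_edge", "perimeter_edge", "edge_perimeter",
                   "perimeter_along_edge", "along_edge"),
    "perim_away": ("perim_away", "perimeter_away", "away_perimeter",
                   "perimeter_away_from_edge", "away_from_edge"),
}


def _normalise(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum() or ch == "_")


def read_group_records(path) -> pd.DataFrame:
    """Read a group-records table from CSV or a spreadsheet, defensively.

    Column names are matched case-insensitively against common synonyms and
    renamed to the canonical set (colony, group_size, survival_rate, area_mm2,
    perim_total, perim_edge, perim_away).  For a workbook, the first sheet
    containing a colony column is used.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        sheets = pd.read_excel(path, sheet_name=None)
        frames = list(sheets.values())
    else:
        frames = [pd.read_csv(path)]
    for frame in frames:
        renamed = _rename_columns(frame)
        if "colony" in renamed.columns:
            return renamed
    raise ValueError(f"no sheet in {path!r} has a recognisable colony column")


def _rename_columns(frame: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in frame.columns:
        norm = _normalise(col)
        for canonical, synonyms in _COLUMN_SYNONYMS.items():
            if norm == canonical or norm in synonyms:
                mapping[col] = canonical
                break
    return frame.rename(columns=mapping)
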