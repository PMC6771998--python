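"""Group statistics: normality screen, three-condition comparisons, and
the PCI/GA correlation screen.

The study design measured every subject under three belt-speed
conditions but compared conditions with a one-way ANOVA on independent
groups, followed by Bonferroni-corrected pairwise t-tests.  That stated
procedure is the default here; a repeated-measures variant (within-
subject ANOVA + paired t-tests) is available behind ``repeated=True``
and is explicitly non-default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
CONDITIONS = ("usual", "fast", "slow")
PAIRS = (("usual", "fast"), ("usual", "slow"), ("slow", "fast"))

#: Covariates screened against PCI and GA, and display labels.
COVARIATES = ("gait_speed", "height", "bmi", "cadence", "swing_time", "step_length")
OUTCOMES = ("pci", "ga")
LABELS = {
    "gait_speed": "Gait speed (m/s)",
    "cadence": "Cadence (steps/min)",
    "step_length": "Step length (m)",
    "swing_time": "Swing time (s)",
    "pci": "Phase coordination index (%)",
    "ga": "Gait asymmetry (%)",
    "height": "Height (m)",
    "bmi": "BMI (kg/m2)",
}


class StatsError(ValueError):
    """Invalid input to the statistics pipeline."""


def _groups(records: pd.DataFrame, variable: str) -> dict[str, np.ndarray]:
    if variable not in records.columns:
        raise StatsError(f"variable {variable!r} not in records")
    out = {}
    for cond in CONDITIONS:
        vals = records.loc[records["condition"] == cond, variable].dropna().to_numpy()
        out[cond] = vals
    return out


def normality_screen(
    records: pd.DataFrame, variables: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Shapiro-Wilk p per variable per condition (reported, never gating).

    Cells with fewer than 3 values or zero variance are NaN (the test is
    undefined there).
    """
    if variables is None:
        variables = tuple(v for v in LABELS if v in records.columns)
    rows = {}
    for var in variables:
        groups = _groups(records, var)
        ps = {}
        for cond, vals in groups.items():
            if len(vals) < 3 or np.ptp(vals) == 0:
                ps[cond] = np.nan
            else:
                ps[cond] = sps.shapiro(vals).pvalue
        rows[var] = ps
    return pd.DataFrame(rows).T[list(CONDITIONS)]


@dataclass
class ComparisonRow:
    """One variable's three-condition comparison."""

    variable: str
    mean: dict  # condition -> mean
    sd: dict  # condition -> SD
    n: dict  # condition -> group size
    f_stat: float
    p_value: float
    pairwise_raw: dict  # (cond_a, cond_b) -> raw p
    pairwise_adjusted: dict  # (cond_a, cond_b) -> Bonferroni p (x3, capped at 1)


def compare_conditions(
    records: pd.DataFrame,
    variable: str,
    repeated: bool = False,
    subject_col: str = "subject_id",
) -> ComparisonRow:
    """One-way ANOVA across the three conditions plus Bonferroni post hocs.

    Default: independent-groups ANOVA and pooled-variance two-sample
    t-tests, each pairwise p multiplied by 3 and capped at 1.  With
    ``repeated=True`` (non-default), a within-subject ANOVA and paired
    t-tests are used instead; this requires complete subject x condition
    data.
    """
    groups = _groups(records, variable)
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise StatsError(f"condition {cond!r} has fewer than 2 values")

    if repeated:
        from statsmodels.stats.anova import AnovaRM

        wide = records.pivot(index=subject_col, columns="condition", values=variable)
        if wide.isna().any().any():
            raise StatsError("repeated-measures ANOVA needs complete data")
        long = wide.reset_index().melt(
            id_vars=subject_col, var_name="condition", value_name=variable
        )
        fit = AnovaRM(long, depvar=variable, subject=subject_col, within=["condition"]).fit()
        f_stat = float(fit.anova_table["F Value"].iloc[0])
        p_value = float(fit.anova_table["Pr > F"].iloc[0])
        raw = {
            pair: float(sps.ttest_rel(wide[pair[0]], wide[pair[1]]).pvalue)
            for pair in PAIRS
        }
    else:
        f_stat, p_value = sps.f_oneway(*(groups[c] for c in CONDITIONS))
        raw = {
            pair: float(sps.ttest_ind(groups[pair[0]], groups[pair[1]]).pvalue)
            for pair in PAIRS
        }

    adjusted = {pair: min(1.0, 3.0 * p) for pair, p in raw.items()}
    return ComparisonRow(
        variable=variable,
        mean={c: float(np.mean(v)) for c, v in groups.items()},
        sd={c: float(np.std(v, ddof=1)) for c, v in groups.items()},
        n={c: len(v) for c, v in groups.items()},
        f_stat=float(f_stat),
        p_value=float(p_value),
        pairwise_raw=raw,
        pairwise_adjusted=adjusted,
    )


def correlation_screen(
    records: pd.DataFrame,
    condition: str,
    outcomes: tuple[str, ...] = OUTCOMES,
    covariates: tuple[str, ...] = COVARIATES,
) -> pd.DataFrame:
    """Pearson r and two-sided p of each outcome vs each covariate within
    one condition.  Zero-variance pairs give NaN (undefined)."""
    sub = records[records["condition"] == condition]
    if len(sub) < 3:
        raise StatsError(f"need at least 3 records in condition {condition!r}")
    rows = []
    for cov in covariates:
        row: dict = {"covariate": cov}
        for out in outcomes:
            x = sub[cov].to_numpy(dtype=float)
            y = sub[out].to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            x, y = x[keep], y[keep]
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                row[f"{out}_r"], row[f"{out}_p"] = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
                row[f"{out}_r"], row[f"{out}_p"] = float(r), float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


def build_table1(
    records: pd.DataFrame,
    variables: tuple[str, ...] = (
        "gait_speed",
        "cadence",
        "step_length",
        "swing_time",
        "pci",
        "ga",
    ),
    repeated: bool = False,
) -> pd.DataFrame:
    """Group mean +/- SD per condition with the ANOVA p column."""
    rows = []
    for var in variables:
        cmp_row = compare_conditions(records, var, repeated=repeated)
        row: dict = {"variable": var}
        for cond in CONDITIONS:
            row[f"{cond}_mean"] = cmp_row.mean[cond]
            row[f"{cond}_sd"] = cmp_row.sd[cond]
        row["anova_f"] = cmp_row.f_stat
        row["anova_p"] = cmp_row.p_value
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def build_table2(
    records: pd.DataFrame,
    variables: tuple[str, ...] = ("pci", "ga"),
    repeated: bool = False,
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise p-values per variable."""
    rows = []
    for var in variables:
        cmp_row = compare_conditions(records, var, repeated=repeated)
        row = {"variable": var}
        for pair in PAIRS:
            row[f"{pair[0]}_vs_{pair[1]}_p"] = cmp_row.pairwise_adjusted[pair]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def build_table3(records: pd.DataFrame) -> pd.DataFrame:
    """Correlation screen over all three conditions, wide layout."""
    parts = []
    for cond in CONDITIONS:
        part = correlation_screen(records, cond)
        part.columns = [f"{cond}_{c}" for c in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1)


# --------------------------------------------------------------------------
# supplementary-spreadsheet reader
# --------------------------------------------------------------------------

#: Canonical record fields the reader must supply.
REQUIRED_FIELDS = ("subject_id", "condition") + COVARIATES + OUTCOMES


def read_supplementary(
    path,
    column_map: dict,
    sheet: str | int = 0,
) -> pd.DataFrame:
    """Read a per-subject spreadsheet into the canonical record layout.

    ``column_map`` is user-configurable because the spreadsheet's internal
    layout is not standardized: ``{"columns": {canonical: sheet column},
    "condition_values": {sheet value: canonical condition}, "sheet": name}``.
    """
    sheet = column_map.get("sheet", sheet)
    raw = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    colmap = column_map.get("columns", {})
    missing = [c for c in REQUIRED_FIELDS if colmap.get(c, c) not in raw.columns]
    if missing:
        raise StatsError(f"spreadsheet lacks mapped columns for: {missing}")
    out = pd.DataFrame(
        {canon: raw[colmap.get(canon, canon)] for canon in REQUIRED_FIELDS}
    )
    cond_values = column_map.get("condition_values", {})
    if cond_values:
        out["condition"] = out["condition"].map(lambda v: cond_values.get(v, v))
    bad = set(out["condition"]) - set(CONDITIONS)
    if bad:
        raise StatsError(f"unmapped condition values: {sorted(bad)}")
    return out


# --------------------------------------------------------------------------
# formatting helpers (human-facing tables; fixed decimals by design)
# --------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_table1(table: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=table.index)
    for cond in CONDITIONS:
        out[cond] = [
            f"{m:.2f} ± {s:.2f}"
            for m, s in zip(table[f"{cond}_mean"], table[f"{cond}_sd"])
        ]
    out["p-value"] = [_fmt_p(p) for p in table["anova_p"]]
    out.index = [LABELS.get(v, v) for v in table.index]
    return out
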