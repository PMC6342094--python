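"""Isoline fitness analysis pipeline.

Individual-level fitness records (one row per assayed fly: line, sex,
block, raw fitness) are Z-standardized within each sex-by-block cell, so
that offspring counts (females) and competitive paternity shares (males)
land on one comparable scale and block effects are absorbed.  Line means of
the standardized values then estimate each genotype's sex-specific fitness,
and the Pearson correlation between male and female line means is the
intersexual correlation for fitness, r_mf.

The pipeline supports the suspect-line workflow used when some lines are
thought to be distorted by cytoplasmic incompatibility: exclude the lines,
re-standardize the remaining records from scratch (subsetting old z-scores
would be wrong — the cell means and SDs change), re-estimate r_mf, and
compare the two regression slopes.  An OLS F test for the sex-by-line
interaction checks for genetic variation in the sex difference; block is
fitted as a fixed categorical factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .stats import CorrelationResult, SlopeComparison, compare_slopes, pearson_rmf

__all__ = [
    "standardize",
    "flag_outliers",
    "line_sex_means",
    "estimate_rmf",
    "interaction_f_test",
    "ci_bias_report",
    "CIBiasReport",
]

REQUIRED_COLUMNS = ("line_id", "sex", "block", "fitness_raw")
SEX_CODES = ("M", "F")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    bad_sex = set(records["sex"].unique()) - set(SEX_CODES)
    if bad_sex:
        raise ValueError(f"unknown sex codes {sorted(bad_sex)}; expected M/F")


def standardize(records: pd.DataFrame) -> pd.DataFrame:
    """Z-transform raw fitness within each sex-by-block cell.

    Adds a ``fitness_z`` column: ``(x - cell mean) / cell SD`` with the
    sample (n-1) SD.  Raw values are retained.  Every cell must have at
    least two records and nonzero spread.
    """
    _check_records(records)
    out = records.copy()
    grouped = out.groupby(["sex", "block"], observed=True)["fitness_raw"]
    for (sex, block), values in grouped:
        if len(values) < 2:
            raise ValueError(
                f"cell (sex={sex}, block={block}) has {len(values)} record(s); "
                "need at least 2 to standardize"
            )
        if float(values.std(ddof=1)) == 0.0:
            raise ValueError(
                f"cell (sex={sex}, block={block}) has zero standard deviation"
            )
    out["fitness_z"] = grouped.transform(lambda v: (v - v.mean()) / v.std(ddof=1))
    return out


def flag_outliers(records: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Return the records whose |z| exceeds ``k``.

    Flagging only: nothing is removed.  Exclusion is an explicit caller
    decision (pass the flagged lines/rows to the relevant operation), so any
    outlier handling is visible in the analysis record.
    """
    if "fitness_z" not in records.columns:
        raise ValueError("records are not standardized; run standardize() first")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    return records.loc[records["fitness_z"].abs() > k]


def line_sex_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean standardized fitness per line and sex, pooled across blocks.

    Returns one row per line: ``line_id, mean_male_z, mean_female_z,
    n_male, n_female``, sorted by line id.  Every line must have records of
    both sexes.
    """
    if "fitness_z" not in records.columns:
        raise ValueError("records are not standardized; run standardize() first")
    g = records.groupby(["line_id", "sex"], observed=True)["fitness_z"]
    means = g.mean().unstack("sex")
    counts = g.size().unstack("sex", fill_value=0)
    for sex in SEX_CODES:
        if sex not in means.columns:
            means[sex] = np.nan
            counts[sex] = 0
        missing = counts.index[counts[sex] == 0].tolist()
        if missing:
            raise ValueError(f"lines missing sex {sex}: {missing}")
    table = pd.DataFrame(
        {
            "line_id": means.index,
            "mean_male_z": means["M"].to_numpy(),
            "mean_female_z": means["F"].to_numpy(),
            "n_male": counts["M"].to_numpy(),
            "n_female": counts["F"].to_numpy(),
        }
    ).sort_values("line_id", ignore_index=True)
    return table


def estimate_rmf(
    records: pd.DataFrame, exclude_lines: tuple[str, ...] | list[str] = ()
) -> CorrelationResult:
    """Estimate r_mf from raw records, optionally excluding suspect lines.

    Excluded lines' records are dropped *before* standardization: the
    remaining data are re-standardized from scratch, aggregated to line
    means, and correlated.  At least 3 lines must remain.
    """
    _check_records(records)
    excl = set(exclude_lines)
    kept = records.loc[~records["line_id"].isin(excl)]
    n_lines = kept["line_id"].nunique()
    if n_lines < 3:
        raise ValueError(
            f"only {n_lines} line(s) remain after exclusion; need at least 3"
        )
    means = line_sex_means(standardize(kept))
    return pearson_rmf(means["mean_male_z"], means["mean_female_z"])


def _categorical_dummies(values: pd.Series) -> np.ndarray:
    """Drop-first treatment coding for one categorical factor."""
    d = pd.get_dummies(values.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def interaction_f_test(records: pd.DataFrame) -> tuple[float, int, int, float]:
    """F test for the sex-by-line interaction on standardized fitness.

    Fits OLS of ``fitness_z`` on sex, line and block (all categorical,
    fixed effects) with and without the sex:line interaction and compares
    residual sums of squares.  Returns ``(F, df1, df2, p)`` where df1 is
    the interaction's degrees of freedom and df2 the full model's residual
    degrees of freedom.

    A significant interaction means lines differ in their sex effect —
    i.e., male and female fitness rank orders cross.
    """
    if "fitness_z" not in records.columns:
        raise ValueError("records are not standardized; run standardize() first")
    _check_records(records)
    lines = records["line_id"].unique()
    sexes = records["sex"].unique()
    if len(lines) < 2 or len(sexes) < 2 or records["block"].nunique() < 1:
        raise ValueError("need >= 2 lines and both sexes")
    cells = records.groupby(["sex", "line_id"], observed=True).size()
    expected = {(s, l) for s in sexes for l in lines}
    empty = sorted(expected - set(cells.index))
    if empty:
        raise ValueError(f"empty (sex, line) cells: {empty}")

    y = records["fitness_z"].to_numpy(dtype=float)
    n = len(y)
    sex_d = _categorical_dummies(records["sex"])
    line_d = _categorical_dummies(records["line_id"])
    block_d = _categorical_dummies(records["block"])
    inter_d = np.einsum("ij,ik->ijk", sex_d, line_d).reshape(n, -1)

    ones = np.ones((n, 1))
    X_red = np.hstack([ones, sex_d, line_d, block_d])
    X_full = np.hstack([X_red, inter_d])

    fit_red = sm.OLS(y, X_red).fit()
    fit_full = sm.OLS(y, X_full).fit()
    rank_red = int(np.linalg.matrix_rank(X_red))
    rank_full = int(np.linalg.matrix_rank(X_full))
    df1 = rank_full - rank_red
    df2 = n - rank_full
    if df1 < 1 or df2 < 1:
        raise ValueError("interaction test has no degrees of freedom")
    rss_red = float(fit_red.ssr)
    rss_full = float(fit_full.ssr)
    F = (rss_red - rss_full) / df1 / (rss_full / df2)
    p = float(sps.f.sf(F, df1, df2))
    return F, df1, df2, p


@dataclass(frozen=True)
class CIBiasReport:
    """Bundle of the with/without-suspect-lines comparison.

    ``leave_one_out`` maps each line id to the r_mf estimated with that line
    excluded (re-standardized), exposing per-line leverage.  ``line_ranks``
    gives each line's fitness rank within sex (1 = highest mean), whose
    crossing structure the sex-by-line interaction tests.
    """

    suspect_lines: tuple[str, ...]
    rmf_all: CorrelationResult
    rmf_excluded: CorrelationResult
    slope_comparison: SlopeComparison
    leave_one_out: dict[str, float] = field(repr=False)
    line_ranks: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        def corr(c: CorrelationResult) -> dict:
            return {
                "r": c.r,
                "t_stat": c.t_stat,
                "df": c.df,
                "p_two_tailed": c.p_two_tailed,
                "slope": c.slope,
                "slope_se": c.slope_se,
                "n": c.n,
            }

        sc = self.slope_comparison
        return {
            "suspect_lines": list(self.suspect_lines),
            "rmf_all": corr(self.rmf_all),
            "rmf_excluded": corr(self.rmf_excluded),
            "slope_comparison": {
                "b1": sc.b1,
                "b2": sc.b2,
                "se1": sc.se1,
                "se2": sc.se2,
                "t_stat": sc.t_stat,
                "df": sc.df,
                "p_two_tailed": sc.p_two_tailed,
            },
            "leave_one_out": dict(self.leave_one_out),
            "line_ranks": self.line_ranks.to_dict(orient="records"),
        }


def ci_bias_report(
    records: pd.DataFrame, suspect_lines: tuple[str, ...] | list[str]
) -> CIBiasReport:
    """Quantify how much suspect (CI-affected) lines drive the r_mf estimate.

    Estimates r_mf with and without the suspect lines (re-standardizing
    after exclusion), compares the two regression slopes, computes
    leave-one-line-out r values, and tabulates sex-specific line ranks.
    """
    _check_records(records)
    all_lines = sorted(records["line_id"].unique())
    unknown = sorted(set(suspect_lines) - set(all_lines))
    if unknown:
        raise ValueError(f"suspect lines not present in the data: {unknown}")

    rmf_all = estimate_rmf(records)
    rmf_excl = estimate_rmf(records, exclude_lines=tuple(suspect_lines))
    comparison = compare_slopes(
        rmf_all.slope, rmf_all.slope_se, rmf_all.n,
        rmf_excl.slope, rmf_excl.slope_se, rmf_excl.n,
    )
    loo = {
        lid: estimate_rmf(records, exclude_lines=(lid,)).r for lid in all_lines
    }
    means = line_sex_means(standardize(records))
    ranks = pd.DataFrame(
        {
            "line_id": means["line_id"],
            "male_rank": means["mean_male_z"]
            .rank(ascending=False, method="first")
            .astype(int),
            "female_rank": means["mean_female_z"]
            .rank(ascending=False, method="first")
            .astype(int),
        }
    )
    return CIBiasReport(
        suspect_lines=tuple(suspect_lines),
        rmf_all=rmf_all,
        rmf_excluded=rmf_excl,
        slope_comparison=comparison,
        leave_one_out=loo,
        line_ranks=ranks,
    )
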