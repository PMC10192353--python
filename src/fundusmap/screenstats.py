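"""Screen characterization statistics.

Genome-saturation accounting, Tukey-fence (IQR) outlier exclusion, pooled
two-group Student t comparisons with dual with/without-outlier reporting,
age-trend linear regression, percent change, and lipid-class balance ratios
(TAG/(TAG+DAG), TAG/DAG, CE/(Chl+CE)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("central", "paracentral", "midperipheral", "peripheral")
QUADRANTS = ("superior", "inferior", "nasal", "temporal")

DAMAGING_CLASSES = ("probably_null", "probably_damaging")

#: default gene-universe size for the saturation metric: the approximate
#: number of mouse protein-coding genes
DEFAULT_GENE_UNIVERSE = 20_000


@dataclass(frozen=True)
class MeasurementGroup:
    """A labelled vector of per-sample measurements (cell counts, µm, g...)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("a measurement group needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement values must be finite")


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    R2: float
    F: float
    p: float


def _quartiles(values: np.ndarray, convention: str) -> tuple[float, float]:
    if convention == "linear":
        return float(np.quantile(values, 0.25)), float(np.quantile(values, 0.75))
    if convention == "tukey":
        # Tukey hinges: medians of the lower/upper halves (median included
        # in both halves when n is odd)
        v = np.sort(values)
        n = len(v)
        half = (n + 1) // 2
        return float(np.median(v[:half])), float(np.median(v[n - half:]))
    raise ValueError(f"unknown quartile convention {convention!r}")


def iqr_outliers(
    values: Sequence[float], convention: str = "linear"
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Tukey-fence outlier split: values outside [Q1-1.5*IQR, Q3+1.5*IQR].

    Returns (kept, removed, (lower, upper)).  Removal is strict: only values
    strictly outside the fences are removed.  Q1/Q3 use linear interpolation
    between order statistics by default (``convention='tukey'`` switches to
    Tukey hinges).  With fewer than 4 values no exclusion is attempted.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute IQR bounds of an empty vector")
    if arr.size < 4:
        warnings.warn("fewer than 4 values: IQR exclusion skipped, all kept")
        return arr.copy(), np.array([]), (-np.inf, np.inf)
    q1, q3 = _quartiles(arr, convention)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outside = (arr < lo) | (arr > hi)
    return arr[~outside], arr[outside], (lo, hi)


def two_group_t(a: MeasurementGroup, b: MeasurementGroup, equal_var: bool = True):
    """Two-tailed unpaired Student t test (pooled variance by default).

    Returns (t, df, p).  ``equal_var=False`` gives the Welch form.
    """
    if len(a.values) < 2 or len(b.values) < 2:
        raise ValueError("each group needs at least 2 values for a t test")
    res = stats.ttest_ind(a.values, b.values, equal_var=equal_var)
    df = len(a.values) + len(b.values) - 2 if equal_var else float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def region_comparison(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region two-group comparison of field counts, with and without outliers.

    ``table`` has columns genotype_group, region, quadrant, field_count and
    exactly two genotype groups overall.  For each region present in both
    groups the report carries per-group n and means, p including all fields
    (``p_all``), p after IQR exclusion within each group
    (``p_outliers_removed``), and the removed values.  Regions observed in
    only one group are skipped with a warning.
    """
    required = {"genotype_group", "region", "quadrant", "field_count"}
    if not required.issubset(table.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    bad_regions = set(table["region"]) - set(REGIONS)
    if bad_regions:
        raise ValueError(f"unknown region labels: {sorted(bad_regions)}")
    bad_quads = set(table["quadrant"]) - set(QUADRANTS)
    if bad_quads:
        raise ValueError(f"unknown quadrant labels: {sorted(bad_quads)}")
    groups = sorted(table["genotype_group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 genotype groups, found {groups}")
    ga, gb = groups

    rows = []
    for region in REGIONS:
        sub = table[table["region"] == region]
        if len(sub) == 0:
            continue
        va = sub.loc[sub["genotype_group"] == ga, "field_count"].to_numpy(dtype=float)
        vb = sub.loc[sub["genotype_group"] == gb, "field_count"].to_numpy(dtype=float)
        if len(va) == 0 or len(vb) == 0:
            warnings.warn(f"region {region!r} present in only one group; skipped")
            continue
        _, _, p_all = two_group_t(
            MeasurementGroup(ga, tuple(va)), MeasurementGroup(gb, tuple(vb))
        )
        ka, ra, _ = iqr_outliers(va)
        kb, rb, _ = iqr_outliers(vb)
        _, _, p_rm = two_group_t(
            MeasurementGroup(ga, tuple(ka)), MeasurementGroup(gb, tuple(kb))
        )
        rows.append(
            {
                "region": region,
                f"n_{ga}": len(va),
                f"n_{gb}": len(vb),
                f"mean_{ga}": float(va.mean()),
                f"mean_{gb}": float(vb.mean()),
                "p_all": p_all,
                "p_outliers_removed": p_rm,
                "removed": list(ra) + list(rb),
            }
        )
    return pd.DataFrame.from_records(rows)


def trend_regression(x: Sequence[float], y: Sequence[float]) -> TrendFit:
    """OLS trend of a measure against age: slope, R2, and the F test.

    F = R2 / (1 - R2) * (n - 2) with p from F(1, n-2); for simple
    regression this equals the squared slope t statistic.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 points for a trend fit")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; trend undefined")
    if np.ptp(ya) == 0:
        return TrendFit(0.0, float(ya[0]), 0.0, 0.0, 1.0)
    fit = stats.linregress(xa, ya)
    r2 = float(fit.rvalue**2)
    if r2 >= 1.0:
        return TrendFit(float(fit.slope), float(fit.intercept), 1.0, float("inf"), 1e-300)
    f = r2 / (1.0 - r2) * (n - 2)
    p = float(stats.f.sf(f, 1, n - 2)) if f > 0 else 1.0
    p = min(max(p, 1e-300), 1.0)
    return TrendFit(float(fit.slope), float(fit.intercept), r2, float(f), p)


def percent_change(
    reference_mean: float, alternative_mean: float, round_to_int: bool = False
) -> float:
    """Signed percent change of ``alternative_mean`` relative to ``reference_mean``.

    Negative means a decrease.  Integer rounding, when requested, rounds
    half away from zero.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    pct = 100.0 * (alternative_mean - reference_mean) / reference_mean
    if round_to_int:
        # half away from zero, not banker's rounding
        return float(np.sign(pct) * np.floor(abs(pct) + 0.5))
    return pct


def lipid_ratios(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lipid-class balance ratios per sample plus per-tissue group tests.

    ``samples`` has columns sample_id, tissue, group, TAG, DAG, Chl, CE
    (normalized ion abundances).  Returns (per-sample ratio table, group
    comparison table).  Ratios: TAG/(TAG+DAG), TAG/DAG, CE/(Chl+CE).
    TAG/DAG is NaN with a warning when DAG is zero.
    """
    required = {"sample_id", "tissue", "TAG", "DAG", "Chl", "CE"}
    if not required.issubset(samples.columns):
        raise ValueError(f"lipid table must have columns {sorted(required)}")
    for col in ("TAG", "DAG", "Chl", "CE"):
        if (samples[col] < 0).any():
            raise ValueError(f"negative abundance in column {col}")

    out = samples.copy()
    tag, dag = out["TAG"].to_numpy(float), out["DAG"].to_numpy(float)
    chl, ce = out["Chl"].to_numpy(float), out["CE"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["TAG_over_TAG_plus_DAG"] = np.where(tag + dag > 0, tag / (tag + dag), np.nan)
        out["TAG_over_DAG"] = np.where(dag > 0, tag / dag, np.nan)
        out["CE_over_Chl_plus_CE"] = np.where(chl + ce > 0, ce / (chl + ce), np.nan)
    if (dag == 0).any():
        warnings.warn("DAG = 0 in some samples; TAG/DAG reported as NaN there")

    comparisons = []
    if "group" in out.columns:
        for tissue in sorted(out["tissue"].unique()):
            sub = out[out["tissue"] == tissue]
            groups = sorted(sub["group"].unique())
            if len(groups) != 2:
                continue
            for ratio in ("TAG_over_TAG_plus_DAG", "TAG_over_DAG", "CE_over_Chl_plus_CE"):
                va = sub.loc[sub["group"] == groups[0], ratio].dropna()
                vb = sub.loc[sub["group"] == groups[1], ratio].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                t, df, p = two_group_t(
                    MeasurementGroup(groups[0], tuple(va)),
                    MeasurementGroup(groups[1], tuple(vb)),
                )
                comparisons.append(
                    {"tissue": tissue, "ratio": ratio, "t": t, "df": df, "p": p}
                )
    return out, pd.DataFrame.from_records(comparisons)


def saturation(
    gene_records: pd.DataFrame, gene_universe_size: int = DEFAULT_GENE_UNIVERSE
) -> float:
    """Genome-saturation fraction of the screen.

    A gene counts as examined when it carries at least one mutation with a
    probable-null or probable-damaging prediction AND at least 2 mice
    homozygous (VAR) for such a mutation were screened.  The fraction is the
    number of distinct qualifying genes over the gene-universe size.
    """
    required = {"gene", "effect_class", "n_VAR_mice_screened"}
    if not required.issubset(gene_records.columns):
        raise ValueError(f"gene records must have columns {sorted(required)}")
    if gene_universe_size < 1:
        raise ValueError("gene universe size must be positive")
    if len(gene_records) == 0:
        return 0.0
    qualifying = gene_records[
        gene_records["effect_class"].isin(DAMAGING_CLASSES)
        & (gene_records["n_VAR_mice_screened"] >= 2)
    ]
    n_genes = qualifying["gene"].nunique()
    if n_genes > gene_universe_size:
        raise ValueError("gene universe smaller than the number of qualifying genes")
    return n_genes / gene_universe_size
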