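"""Strict TSV readers and writers for the screen's table formats.

All tables are UTF-8, tab-separated, Unix newlines, with fixed headers.
Genotype cells must be exactly ``REF``, ``HET`` or ``VAR`` (uppercase); no
missing calls are accepted, mirroring a design in which every mouse is
pre-genotyped at every pedigree site before phenotyping.  Numeric p-value
columns are written in full-precision scientific notation so files
round-trip bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fundusmap.pedigree import EFFECT_CLASSES, GENOTYPE_CALLS

#: schema_name -> (fixed leading columns, dtype per column)
SCHEMAS = {
    "genotypes": ["mouse_id", "generation", "sex", "dam_id"],  # + one col per site
    "mutations": ["site_id", "chromosome", "position_bp", "gene", "effect_class"],
    "phenotypes": ["mouse_id", "age_months", "od_score", "os_score", "mouse_score"],
    "exam_counts": ["mouse_id", "eye", "q_superior", "q_inferior", "q_nasal", "q_temporal", "age_months"],
    "manhattan": [
        "site_id", "chromosome", "position_bp", "gene", "best_model",
        "p_recessive", "p_semidominant", "p_dominant",
        "best_p", "neglog10p", "n_VAR", "n", "status",
    ],
    "region_counts": ["genotype_group", "region", "quadrant", "field_count"],
    "lipids": ["sample_id", "tissue", "group", "TAG", "DAG", "Chl", "CE"],
    "gene_records": ["gene", "effect_class", "n_VAR_mice_screened"],
    "candidates": ["site_id", "above_threshold", "margin_logs", "is_candidate"],
}

_INT_COLS = {
    "position_bp", "od_score", "os_score", "mouse_score", "field_count",
    "n_VAR_mice_screened", "n_VAR", "n",
    "q_superior", "q_inferior", "q_nasal", "q_temporal",
}
_FLOAT_COLS = {
    "age_months", "TAG", "DAG", "Chl", "CE",
    "p_recessive", "p_semidominant", "p_dominant", "best_p", "neglog10p",
    "margin_logs",
}


class DataError(ValueError):
    """A table violated its schema (bad header, token or cell type)."""


def _check_genotype_cells(df: pd.DataFrame, site_cols: list[str]) -> None:
    for col in site_cols:
        vals = df[col].astype(str)
        bad = ~vals.isin(GENOTYPE_CALLS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"bad genotype token {vals.iloc[row]!r} in column {col!r}, "
                f"data row {row + 1} (expected REF/HET/VAR)"
            )


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate one of the screen's TSV formats."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; know {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = SCHEMAS[schema_name]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing columns {missing} for schema {schema_name!r}")
    extra = [c for c in df.columns if c not in fixed]
    if schema_name == "genotypes":
        if not extra:
            raise DataError(f"{path.name}: genotype table has no site columns")
        _check_genotype_cells(df, extra)
    elif extra:
        raise DataError(f"{path.name}: unexpected columns {extra} for schema {schema_name!r}")

    if schema_name == "mutations":
        bad = ~df["effect_class"].isin(EFFECT_CLASSES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path.name}: bad effect_class {df['effect_class'].iloc[row]!r} "
                f"in data row {row + 1}"
            )

    for col in df.columns:
        try:
            if col in _INT_COLS:
                df[col] = df[col].astype(np.int64)
            elif col in _FLOAT_COLS:
                # blank cells are legitimate NaNs (e.g. degenerate-model p's)
                df[col] = df[col].replace("", "nan").astype(float)
        except ValueError as exc:
            raise DataError(f"{path.name}: non-numeric value in column {col!r}: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as canonical TSV (UTF-8, \\n, %.17g floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.17g")
    return path
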