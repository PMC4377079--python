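"""Readers and writers for delimited summary, individual-level and multi-study data.

All formats are plain delimited text (comma or tab, sniffed from the header
line), with ``#`` comment lines and ``.`` decimal points:

* summary data: columns ``variant, beta_x, se_x, beta_y, se_y``;
* individual-level data: columns ``x, y, g1..gK`` with genotypes in {0,1,2};
* multi-study data (long format): columns
  ``study, variant, beta_x, se_x, beta_y, se_y`` with missing cells absent.

Validation errors name the offending row and column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .data import IndividualData, SummarySet, VariantAssociation
from .hierarchy import MultiStudySummary

__all__ = [
    "read_summary",
    "write_summary",
    "read_individual",
    "read_multistudy",
    "write_table",
]

_SUMMARY_COLS = ["variant", "beta_x", "se_x", "beta_y", "se_y"]


def _read_delimited(path, required: list[str]) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table, skipping # comments."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep=sep, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {c!r}, row {int(bad[0]) + 1}"
            )
        df[c] = vals.astype(float)


def read_summary(path, rho: float = 0.0) -> SummarySet:
    """Read per-variant summarized associations into a :class:`SummarySet`.

    Row order is preserved; duplicate variant labels and non-positive SEs are
    rejected with the offending row named.
    """
    df = _read_delimited(path, _SUMMARY_COLS)
    _require_numeric(df, _SUMMARY_COLS[1:], path)
    for c in ("se_x", "se_y"):
        bad = df.index[df[c] <= 0]
        if len(bad):
            raise ValueError(
                f"{path}: non-positive {c} in row {int(bad[0]) + 1}"
            )
    labels = df["variant"].astype(str)
    if labels.duplicated().any():
        dup = labels[labels.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate variant label {dup!r}")
    variants = tuple(
        VariantAssociation(r.variant, r.beta_x, r.se_x, r.beta_y, r.se_y)
        for r in df.itertuples()
    )
    return SummarySet(variants, rho=rho)


def write_summary(s: SummarySet, path, sep: str = ",") -> None:
    """Write a SummarySet back to delimited text (round-trips with read_summary)."""
    df = pd.DataFrame({
        "variant": [v.label for v in s],
        "beta_x": s.beta_x, "se_x": s.se_x,
        "beta_y": s.beta_y, "se_y": s.se_y,
    })
    df.to_csv(path, sep=sep, index=False)


def read_individual(path) -> IndividualData:
    """Read individual-level data: columns x, y, g1..gK."""
    df = _read_delimited(path, ["x", "y"])
    gcols = [c for c in df.columns if c not in ("x", "y")]
    if not gcols:
        raise ValueError(f"{path}: no genotype columns (expected g1..gK)")
    _require_numeric(df, ["x", "y"] + gcols, path)
    g = df[gcols].to_numpy(float)
    bad = ~np.isin(g, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: genotype value {g[i, j]} not in {{0,1,2}} "
            f"(column {gcols[j]!r}, row {i + 1})"
        )
    return IndividualData(genotypes=g, x=df["x"].to_numpy(), y=df["y"].to_numpy())


def read_multistudy(path) -> MultiStudySummary:
    """Read long-format multi-study summary data."""
    cols = ["study", "variant", "beta_x", "se_x", "beta_y", "se_y"]
    df = _read_delimited(path, cols)
    _require_numeric(df, cols[2:], path)
    df["study"] = df["study"].astype(str)
    df["variant"] = df["variant"].astype(str)
    return MultiStudySummary(df[cols])


def write_table(df: pd.DataFrame, path_or_stream, sep: str = "\t",
                metadata: dict | None = None) -> None:
    """Write a results table as delimited text with # metadata header lines."""
    close = False
    if isinstance(path_or_stream, (str, Path)):
        stream = open(path_or_stream, "w")
        close = True
    else:
        stream = path_or_stream
    try:
        for key, val in (metadata or {}).items():
            stream.write(f"# {key}={val}\n")
        df.to_csv(stream, sep=sep, index=False)
    finally:
        if close:
            stream.close()
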