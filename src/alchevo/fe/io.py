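"""Readers and writers for plain-text free-energy inputs and reports.

Supported formats:

* GROMACS-style ``dhdl.xvg``: lines beginning with ``#`` or ``@`` are
  metadata/comments, followed by whitespace-separated numeric columns
  (typically time then one or more dH/dlambda columns).  The column-to-lambda
  mapping is supplied by the caller.
* Work tables: two-column TSV ``direction<TAB>work`` with direction
  ``forward`` or ``reverse`` (works in kJ/mol).
* Per-lambda summary TSV (lambda, mean, stderr, n).
* A binding-affinity report TSV shaped like a components-by-isoforms table
  with a totals row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cycle import BindingCycle
from .series import LambdaSeries, WorkSampleSet

__all__ = [
    "read_xvg",
    "lambda_series_from_xvg",
    "write_lambda_summary",
    "read_lambda_summary",
    "write_work_table",
    "read_work_table",
    "write_cycle_report",
]


def read_xvg(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an xvg-dialect file; returns (metadata lines, numeric array).

    Lines starting with ``#`` (comments) or ``@`` (plot metadata) are
    collected verbatim; all remaining lines must be whitespace-separated
    numbers with a consistent column count.
    """
    meta: list[str] = []
    rows: list[list[float]] = []
    ncols = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@")):
            meta.append(stripped)
            continue
        fields = stripped.split()
        try:
            row = [float(x) for x in fields]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric data line") from exc
        if ncols is None:
            ncols = len(row)
        elif len(row) != ncols:
            raise ValueError(
                f"{path}:{lineno}: expected {ncols} columns, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return meta, np.asarray(rows)


def lambda_series_from_xvg(
    path: str | Path,
    column_lambdas: Mapping[int, float],
    temperature: float,
    leg_label: str = "",
) -> LambdaSeries:
    """Build a `LambdaSeries` from one multi-column dhdl.xvg file.

    `column_lambdas` maps 0-based column indices (column 0 is usually time)
    to the lambda value each dH/dlambda column was sampled at.
    """
    _, data = read_xvg(path)
    items = sorted(column_lambdas.items(), key=lambda kv: kv[1])
    for col, _ in items:
        if not 0 <= col < data.shape[1]:
            raise ValueError(f"column {col} out of range for {path}")
    lambdas = [lam for _, lam in items]
    samples = [data[:, col] for col, _ in items]
    return LambdaSeries(lambdas, samples, temperature=temperature, leg_label=leg_label)


def write_lambda_summary(series: LambdaSeries, path: str | Path) -> None:
    """Write per-lambda means/stderrs/counts as TSV."""
    df = pd.DataFrame(
        {
            "lambda": series.lambda_values,
            "mean_dhdl": series.means(),
            "stderr_dhdl": series.stderrs(),
            "n_samples": [s.size for s in series.dhdl_samples],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_lambda_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_work_table(works: WorkSampleSet, path: str | Path) -> None:
    """Write forward/reverse works as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("direction\twork_kJ_mol\n")
        for w in works.forward_works:
            fh.write(f"forward\t{w:.10g}\n")
        for w in works.reverse_works:
            fh.write(f"reverse\t{w:.10g}\n")


def read_work_table(
    path: str | Path,
    temperature: float,
    state_labels: Sequence[str] = ("A", "B"),
) -> WorkSampleSet:
    """Read a two-column TSV of (direction, work kJ/mol) rows."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "direction" not in cols:
        raise ValueError(f"{path}: missing 'direction' column")
    work_col = next((c for c in df.columns if c.lower().startswith("work")), None)
    if work_col is None:
        raise ValueError(f"{path}: missing work column")
    direction = df[cols["direction"]].str.lower()
    unknown = sorted(set(direction) - {"forward", "reverse"})
    if unknown:
        raise ValueError(f"{path}: unknown directions {unknown}")
    return WorkSampleSet(
        df.loc[direction == "forward", work_col].to_numpy(),
        df.loc[direction == "reverse", work_col].to_numpy(),
        temperature=temperature,
        state_labels=state_labels,
    )


def write_cycle_report(
    cycles: Sequence[BindingCycle],
    path: str | Path,
    component_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Write a components-by-systems TSV with restraint/volume and totals rows.

    Each column is one assembled cycle (labelled by `BindingCycle.label`);
    rows are the component legs, the two analytic terms, and the total.
    Returns the report as a DataFrame as well.
    """
    if not cycles:
        raise ValueError("no cycles to report")
    if component_order is None:
        component_order = [leg.name for leg in cycles[0].legs]
    table: dict[str, list[float | None]] = {}
    index = list(component_order) + ["restraint release", "volume correction", "total"]
    for cyc in cycles:
        by_name = {leg.name: leg.estimate.value for leg in cyc.legs}
        col: list[float | None] = [by_name.get(name) for name in component_order]
        col += [cyc.restraint_release_dG, cyc.volume_correction_dG, cyc.total_dG]
        table[cyc.label or f"cycle{len(table) + 1}"] = col
    df = pd.DataFrame(table, index=index)
    df.to_csv(path, sep="\t", float_format="%.4f", index_label="component")
    return df
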