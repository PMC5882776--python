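"""Tidy-CSV readers/writers and tabular pipeline stages.

The interchange schema is long-format delimited text with columns
``treatment_id, analyte, replicate, time_d, concentration, unit``.  The
unit column is mandatory: mM and µM series coexist in one file (inorganic
analytes in mM, chlorophenols in µM) and are never guessed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from pcpredox.congeners import Congener, order_by_first_detection, infer_pathway
from pcpredox.eeq import (
    DEFAULT_COEFFICIENTS,
    EeqCoefficients,
    EeqLedger,
    build_ledger,
    eeq_added,
    pathway_eeq,
)
from pcpredox.errors import SchemaError
from pcpredox.kinetics import (
    TimeSeries,
    fit_logistic,
    to_decrement,
)
from pcpredox.microcosm import MicrocosmConfig, SyntheticDataset, mean_series

__all__ = [
    "TIDY_COLUMNS",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "series_from_frame",
    "fit_table",
    "ledger_from_moles",
    "ledger_table",
    "pathway_report",
    "read_flat_config",
    "write_flat_config",
]

TIDY_COLUMNS = (
    "treatment_id", "analyte", "replicate", "time_d", "concentration", "unit"
)

#: analytes fitted as cumulative decrement (case-insensitive match)
_DECREASING = {"nitrate", "sulfate", "pcp"}


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if df.empty:
        raise SchemaError("input table has no rows")
    bad = df[~np.isfinite(df["concentration"].astype(float))]
    if len(bad):
        raise SchemaError(
            f"non-finite concentrations at rows {bad.index.tolist()[:5]}"
        )


def series_from_frame(df: pd.DataFrame) -> list[TimeSeries]:
    """Split a tidy frame into one :class:`TimeSeries` per
    (treatment, analyte, replicate)."""
    _check_schema(df)
    out = []
    for (trt, analyte, rep), grp in df.groupby(
        ["treatment_id", "analyte", "replicate"], sort=False
    ):
        grp = grp.sort_values("time_d")
        units = grp["unit"].unique()
        if len(units) != 1:
            raise SchemaError(
                f"mixed units {units.tolist()} for {trt}/{analyte}/{rep}"
            )
        out.append(
            TimeSeries(
                treatment_id=str(trt),
                analyte=str(analyte),
                times=grp["time_d"].to_numpy(dtype=float),
                values=grp["concentration"].to_numpy(dtype=float),
                replicate=str(rep),
                unit=str(units[0]),
            )
        )
    return out


def read_timeseries_csv(path) -> list[TimeSeries]:
    """Read the tidy schema from a CSV file."""
    return series_from_frame(pd.read_csv(path))


def write_timeseries_csv(dataset_or_series, path, *, force: bool = False) -> None:
    """Write series (or a :class:`SyntheticDataset`) in the tidy schema."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if isinstance(dataset_or_series, SyntheticDataset):
        df = dataset_or_series.to_frame()
    else:
        rows = [
            (s.treatment_id, s.analyte, s.replicate, t, v, s.unit)
            for s in dataset_or_series
            for t, v in zip(s.times, s.values)
        ]
        df = pd.DataFrame(rows, columns=list(TIDY_COLUMNS))
    df.to_csv(path, index=False)


def fit_table(
    series_list,
    analytes=("sulfate", "fe2", "PCP"),
    *,
    baselines: dict | None = None,
    pool_replicates: bool = False,
) -> pd.DataFrame:
    """Fit the logistic per (treatment, analyte) and tabulate the results.

    Decreasing analytes (nitrate, sulfate, PCP) are transformed to
    cumulative decrement first; Fe(II) is fitted as accumulation.
    Replicates are averaged pointwise by default (``pool_replicates=True``
    instead concatenates them as independent points).

    Returns columns treatment_id, analyte, a, b, k, vmax, t_vmax, r2,
    converged.
    """
    baselines = baselines or {}
    wanted = {a.lower() for a in analytes}
    groups: dict[tuple, list] = {}
    for s in series_list:
        if s.analyte.lower() in wanted:
            groups.setdefault((s.treatment_id, s.analyte), []).append(s)
    rows = []
    for (trt, analyte), reps in sorted(groups.items()):
        if pool_replicates:
            order = np.argsort(np.concatenate([r.times for r in reps]), kind="stable")
            times = np.concatenate([r.times for r in reps])[order]
            values = np.concatenate([r.values for r in reps])[order]
            # pooled grids repeat time points; jitter-free fitting handles
            # ties, but TimeSeries requires strict monotonicity -> fit on
            # the mean instead when ties exist
            if np.any(np.diff(times) <= 0):
                series = mean_series(reps)
            else:
                series = TimeSeries(trt, analyte, times, values, "pooled", reps[0].unit)
        else:
            series = mean_series(reps)
        if analyte.lower() in _DECREASING:
            series = to_decrement(series, baselines.get(analyte))
        fit = fit_logistic(series)
        rows.append(
            (
                trt, analyte,
                fit.params.a, fit.params.b, fit.params.k,
                fit.vmax, fit.t_vmax, fit.r2, fit.converged,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "treatment_id", "analyte", "a", "b", "k",
            "vmax", "t_vmax", "r2", "converged",
        ],
    )


def ledger_from_moles(
    treatment_id: str,
    moles_mmol: dict,
    donor_mM: float,
    volume_L: float,
    coeff: EeqCoefficients = DEFAULT_COEFFICIENTS,
) -> EeqLedger:
    """Build a ledger from per-pathway moles reduced (mmol).

    ``moles_mmol`` keys: ``fe3``, ``no3``, ``so4`` (mmol of acceptor
    reduced) and optionally ``cl_removed`` (mmol of chlorine removed by
    dechlorination).
    """
    per_pathway = {}
    for pathway in ("fe3", "no3", "so4"):
        if pathway in moles_mmol:
            per_pathway[pathway] = pathway_eeq(
                float(moles_mmol[pathway]), pathway, coeff
            )
    if "cl_removed" in moles_mmol:
        cl = float(moles_mmol["cl_removed"])
        if cl < 0:
            raise SchemaError("cl_removed must be >= 0")
        per_pathway["dechlorination"] = cl * coeff.per_chlorine_removed
    added = eeq_added(donor_mM, volume_L, coeff)
    return build_ledger(treatment_id, added, per_pathway)


def ledger_table(ledgers) -> pd.DataFrame:
    """Tabulate ledgers in the style of a published eeq-balance table."""
    rows = [
        (
            led.treatment_id,
            led.added_mmol,
            led.consumed["fe3"],
            led.consumed["no3"],
            led.consumed["so4"],
            led.consumed["dechlorination"],
            led.total_consumed_mmol,
        )
        for led in ledgers
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "treatment_id", "eeq_added", "fe3_reduction", "no3_reduction",
            "so4_reduction", "dechlorination", "eeq_consumed",
        ],
    )


def pathway_report(
    series_list,
    threshold: float = 1.0,
) -> tuple[str, pd.DataFrame]:
    """Infer the dechlorination chain from congener first-detection order.

    Returns (plain-text chain, per-step table).  Congeners are the
    analytes whose names parse as chlorophenols; replicates are averaged
    before thresholding.  An empty chain yields an informative message
    and an empty table.
    """
    groups: dict[str, list] = {}
    for s in series_list:
        try:
            Congener.from_name(s.analyte)
        except Exception:
            continue
        groups.setdefault(s.analyte, []).append(s)
    step_cols = ["parent", "child", "removed_position", "position_class"]
    if not groups:
        return "no congeners detected", pd.DataFrame(columns=step_cols)
    detections = {}
    for name, reps in groups.items():
        m = mean_series(reps)
        detections[name] = (m.times, m.values)
    chain = order_by_first_detection(detections, threshold=threshold)
    if not chain:
        return (
            f"no congeners detected above {threshold:g}",
            pd.DataFrame(columns=step_cols),
        )
    steps = infer_pathway(chain)
    text = " -> ".join(c.name for c in chain)
    table = pd.DataFrame(
        [
            (s.parent.name, s.child.name, s.removed_position, s.position_class)
            for s in steps
        ],
        columns=step_cols,
    )
    return text, table


# --- flat key=value config files -------------------------------------------

_TUPLE_KEYS = {"sampling_days", "chain_rates"}
_INT_KEYS = {"replicates", "seed"}
_STR_KEYS = {"treatment_id"}


def read_flat_config(path) -> MicrocosmConfig:
    """Parse a flat ``key = value`` text file into a simulator config.

    Unknown keys raise; list-valued keys use comma separation, e.g.
    ``sampling_days = 0,3,7,12,17,22,40``.
    """
    valid = set(MicrocosmConfig.__dataclass_fields__)
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in valid:
            raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _STR_KEYS:
            kwargs[key] = value
        elif key in _TUPLE_KEYS:
            kwargs[key] = tuple(float(x) for x in value.split(","))
        elif key in _INT_KEYS:
            try:
                kwargs[key] = int(value)
            except ValueError as exc:
                raise SchemaError(
                    f"{path}:{lineno}: {key} must be an integer, got {value!r}"
                ) from exc
        elif key == "fe_logistic":
            from pcpredox.kinetics import LogisticParams

            a, b, k = (float(x) for x in value.split(","))
            kwargs[key] = LogisticParams(a=a, b=b, k=k)
        else:
            kwargs[key] = float(value)
    return MicrocosmConfig(**kwargs)


def write_flat_config(config: MicrocosmConfig, path, *, force: bool = False) -> None:
    """Write a config (or truth sidecar) as flat ``key = value`` text."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    lines = []
    for key in MicrocosmConfig.__dataclass_fields__:
        value = getattr(config, key)
        if key == "fe_logistic":
            value = f"{value.a},{value.b},{value.k}"
        elif isinstance(value, tuple):
            value = ",".join(f"{x:g}" for x in value)
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")
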