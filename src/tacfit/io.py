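"""CSV/JSON interchange for curves, truth parameters and benchmark reports.

All files are comma-separated UTF-8 with a mandatory header row and ``.``
decimal separator.  Times are hours, FIA values dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .evaluation import BenchmarkReport
from .models import BEF, MEF, ExponentialParams
from .simulate import TACDataset, TACPoints

__all__ = [
    "read_tac_csv",
    "write_dataset_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_report",
    "load_config_file",
]

_TAC_COLUMNS = ("curve_id", "t_h", "fia")


class TACParseError(ValueError):
    """A TAC CSV failed validation; the message names the offending rows."""


def read_tac_csv(path) -> List[TACPoints]:
    """Read curves from a CSV with columns ``curve_id, t_h, fia``.

    Extra columns are ignored, except that ``model_kind`` and ``noisy``
    are picked up when present.  Rows are grouped by curve id and sorted
    by time; violations of the curve invariants raise
    :class:`TACParseError` naming the file rows involved.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TAC_COLUMNS if c not in df.columns]
    if missing:
        raise TACParseError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("t_h", "fia"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()] + 2  # header + 1-based
        if len(bad):
            raise TACParseError(f"{path}: non-numeric {col} in row(s) {list(bad)}")
        df[col] = values
    if df[["t_h", "fia"]].isna().any().any():
        bad = df.index[df[["t_h", "fia"]].isna().any(axis=1)] + 2
        raise TACParseError(f"{path}: empty t_h/fia in row(s) {list(bad)}")

    curves = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("t_h")
        rows = list(grp.index + 2)
        if (grp["fia"] <= 0).any():
            bad = list(grp.index[grp["fia"] <= 0] + 2)
            raise TACParseError(f"{path}: non-positive FIA in row(s) {bad}")
        t = grp["t_h"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise TACParseError(
                f"{path}: duplicate/non-increasing times for curve {cid} (rows {rows})"
            )
        try:
            curves.append(
                TACPoints(
                    times=t,
                    fia=grp["fia"].to_numpy(float),
                    noisy=bool(grp["noisy"].iloc[0]) if "noisy" in grp else False,
                    curve_id=int(cid) if str(cid).isdigit() else None,
                )
            )
        except ValueError as exc:
            raise TACParseError(f"{path}: curve {cid} (rows {rows}): {exc}") from exc
    return curves


def write_dataset_csv(dataset: TACDataset, path) -> None:
    """One row per point: ``curve_id, model_kind, t_h, fia, noisy``."""
    n, npts = len(dataset), dataset.n_points
    df = pd.DataFrame(
        {
            "curve_id": np.repeat(np.arange(n), npts),
            "model_kind": np.repeat([str(k) for k in dataset.kinds], npts),
            "t_h": np.tile(dataset.times, n),
            "fia": dataset.fia.ravel(),
            "noisy": np.repeat(dataset.noisy, n * npts),
        }
    )
    df.to_csv(path, index=False)


def write_truth_csv(dataset: TACDataset, path) -> None:
    """Truth parameters: ``curve_id, kind, A1, lambda1, A2, lambda2``
    (A2/lambda2 left empty for mono-exponential curves)."""
    m = dataset.truth_matrix
    df = pd.DataFrame(
        {
            "curve_id": np.arange(len(dataset)),
            "kind": [str(k) for k in dataset.kinds],
            "A1": m[:, 0],
            "lambda1": m[:, 1],
            "A2": m[:, 2],
            "lambda2": m[:, 3],
        }
    )
    df.to_csv(path, index=False)


def read_truth_csv(path) -> dict:
    """Map curve_id -> ExponentialParams from a truth CSV."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        kind = str(row["kind"])
        if kind == MEF:
            p = ExponentialParams(MEF, (row["A1"],), (row["lambda1"],))
        elif kind == BEF:
            p = ExponentialParams.from_array(
                BEF, (row["A1"], row["lambda1"], row["A2"], row["lambda2"])
            )
        else:
            raise TACParseError(f"{path}: unknown kind {kind!r} for curve {row['curve_id']}")
        out[int(row["curve_id"])] = p
    return out


def write_report(report: BenchmarkReport, directory) -> List[Path]:
    """Write ``ca_vs_n.csv``, ``delta_tau_summary.csv`` and ``config.json``.

    Column order is stable, so re-running an identical experiment produces
    byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    ca_rows = [
        {"n_points": n, "chain": method, "ca_percent": v}
        for (n, method), v in sorted(report.accuracies.items())
    ]
    ca_df = pd.DataFrame(ca_rows, columns=["n_points", "chain", "ca_percent"])
    ca_path = d / "ca_vs_n.csv"
    ca_df.to_csv(ca_path, index=False)

    sum_rows = []
    for s in report.summaries:
        row = asdict(s)
        row["mer_min"], row["mer_max"] = row.pop("mer")
        sum_rows.append(row)
    sum_df = pd.DataFrame(
        sum_rows,
        columns=[
            "n_points", "chain", "median", "q1", "q3",
            "iqr_width", "n_curves", "mer_min", "mer_max",
        ],
    )
    sum_path = d / "delta_tau_summary.csv"
    sum_df.to_csv(sum_path, index=False)

    cfg_path = d / "config.json"
    with open(cfg_path, "w") as fh:
        json.dump(report.to_dict()["config"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [ca_path, sum_path, cfg_path]


def load_config_file(path) -> dict:
    """Load a YAML or JSON experiment configuration file."""
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)
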