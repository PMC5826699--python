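"""CSV table formats and flat key-value run configs.

Detection tables come in two dialects:

* count form  — header ``site,y,n``; one row per site;
* wide form   — header ``site,occ_1,...,occ_J``; cells 0/1, with an empty
  cell marking a missed occasion (it simply reduces ``n_i``).

Both parse to the same (y, n) representation and round-trip losslessly at
that level.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CovariateMatrix, DataError, DetectionHistory

__all__ = [
    "read_detection_table",
    "write_detection_table",
    "read_covariates",
    "write_covariates",
    "write_draws",
    "read_config",
    "write_config",
]


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataError(f"{path}: empty file")
        rows = [row for row in reader if any(cell.strip() for cell in row)]
    return [h.strip() for h in header], rows


def read_detection_table(path) -> DetectionHistory:
    """Parse either detection-table dialect into a DetectionHistory."""
    header, rows = _read_rows(path)
    lower = [h.lower() for h in header]
    if not lower or lower[0] != "site":
        raise DataError(f"{path}: first column must be 'site', got {header[:1]}")
    if lower[1:] == ["y", "n"]:
        return _parse_count_form(path, rows)
    return _parse_wide_form(path, header, rows)


def _parse_count_form(path, rows) -> DetectionHistory:
    sites, ys, ns = [], [], []
    for r, row in enumerate(rows, start=2):
        if len(row) != 3:
            raise DataError(f"{path} row {r}: expected 3 cells, got {len(row)}")
        site, y_s, n_s = (c.strip() for c in row)
        try:
            y, n = int(y_s), int(n_s)
        except ValueError:
            raise DataError(f"{path} row {r} (site {site}): non-integer count")
        if n < 1:
            raise DataError(f"{path} row {r} (site {site}): n must be >= 1")
        if not 0 <= y <= n:
            raise DataError(
                f"{path} row {r} (site {site}): need 0 <= y <= n, got y={y} n={n}"
            )
        sites.append(site)
        ys.append(y)
        ns.append(n)
    if len(set(sites)) != len(sites):
        dupes = sorted({s for s in sites if sites.count(s) > 1})
        raise DataError(f"{path}: duplicate site labels {dupes}")
    return DetectionHistory(np.array(ys), np.array(ns), tuple(sites))


def _parse_wide_form(path, header, rows) -> DetectionHistory:
    occ_cols = header[1:]
    if not occ_cols:
        raise DataError(f"{path}: wide form needs at least one occasion column")
    sites, ys, ns = [], [], []
    for r, row in enumerate(rows, start=2):
        if len(row) != len(header):
            raise DataError(
                f"{path} row {r}: expected {len(header)} cells, got {len(row)}"
            )
        site = row[0].strip()
        y = n = 0
        for col_name, cell in zip(occ_cols, row[1:]):
            cell = cell.strip()
            if cell == "":
                continue  # missed occasion
            if cell not in ("0", "1"):
                raise DataError(
                    f"{path} row {r} (site {site}), column {col_name}: "
                    f"non-binary cell {cell!r}"
                )
            n += 1
            y += int(cell)
        if n == 0:
            raise DataError(
                f"{path} row {r} (site {site}): no surveyed occasions"
            )
        sites.append(site)
        ys.append(y)
        ns.append(n)
    if len(set(sites)) != len(sites):
        dupes = sorted({s for s in sites if sites.count(s) > 1})
        raise DataError(f"{path}: duplicate site labels {dupes}")
    return DetectionHistory(np.array(ys), np.array(ns), tuple(sites))


def write_detection_table(
    data: DetectionHistory, path, form: str = "counts"
) -> None:
    """Write a detection table in either dialect.

    The wide form writes each site's detections as y_i ones followed by
    n_i - y_i zeros (occasion-level order is not retained by the model),
    padding short rows with blanks.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if form == "counts":
            writer.writerow(["site", "y", "n"])
            for s, y, n in zip(data.site_ids, data.y, data.n):
                writer.writerow([s, int(y), int(n)])
        elif form == "wide":
            j_max = int(data.n.max()) if data.n_sites else 0
            writer.writerow(["site"] + [f"occ_{j + 1}" for j in range(j_max)])
            for s, y, n in zip(data.site_ids, data.y, data.n):
                cells = ["1"] * int(y) + ["0"] * int(n - y)
                cells += [""] * (j_max - int(n))
                writer.writerow([s] + cells)
        else:
            raise ValueError(f"unknown form {form!r}: use 'counts' or 'wide'")


def read_covariates(path, data: DetectionHistory | None = None) -> CovariateMatrix:
    """Read a site-by-covariate CSV (first column ``site``).

    If ``data`` is given, rows are checked (and reordered) against its
    site labels.
    """
    frame = pd.read_csv(path)
    if frame.columns[0].strip().lower() != "site":
        raise DataError(f"{path}: first column must be 'site'")
    frame = frame.rename(columns={frame.columns[0]: "site"})
    frame["site"] = frame["site"].astype(str)
    if frame["site"].duplicated().any():
        dupes = sorted(frame.loc[frame["site"].duplicated(), "site"].unique())
        raise DataError(f"{path}: duplicate site labels {dupes}")
    if data is not None:
        missing = set(data.site_ids) - set(frame["site"])
        if missing:
            raise DataError(f"{path}: missing covariate rows for {sorted(missing)}")
        frame = frame.set_index("site").loc[list(data.site_ids)].reset_index()
    names = tuple(frame.columns[1:])
    values = frame[list(names)].to_numpy(dtype=float)
    return CovariateMatrix(values, names)


def write_covariates(x: CovariateMatrix, site_ids, path) -> None:
    frame = pd.DataFrame(x.values, columns=list(x.names))
    frame.insert(0, "site", list(site_ids))
    frame.to_csv(path, index=False)


def write_draws(draws, path) -> None:
    """Long-format CSV export: chain, iteration, parameter, value."""
    draws.to_frame().to_csv(path, index=False)


def write_config(config: dict, path) -> None:
    """Flat ``key=value`` file; values are written with repr-level fidelity."""
    with open(path, "w") as fh:
        for key in sorted(config):
            fh.write(f"{key}={config[key]}\n")


def read_config(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataError(f"{path} line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
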