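"""File formats: tab-delimited time series, parcellation, trial tables,
matrices, long-format result tables, and the run manifest.

All result files are diff-able text (TSV/JSON).  Time-series files follow the
naming convention ``sub-XX_day-D_scan-S.tsv`` with regions as rows, a leading
``region`` column and a header row of volume indices.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import RegionTimeSeries

TIMESERIES_PATTERN = re.compile(r"sub-(?P<subject>[^_]+)_day-(?P<day>\d+)_scan-(?P<scan>\w+)\.tsv")

PARCELLATION_COLUMNS = ("region", "network", "hemisphere")
TRIAL_COLUMNS = ("subject", "day", "block", "trial", "error_deg", "rt_ms")


class FormatError(ValueError):
    pass


def timeseries_filename(ts: RegionTimeSeries) -> str:
    subject = ts.subject.replace("sub-", "")
    return f"sub-{subject}_day-{ts.day}_scan-{ts.scan}.tsv"


def write_timeseries(path: str | Path, ts: RegionTimeSeries) -> None:
    df = pd.DataFrame(ts.values, index=list(ts.region_ids),
                      columns=[str(v) for v in range(ts.n_volumes)])
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_timeseries(path: str | Path) -> RegionTimeSeries:
    path = Path(path)
    m = TIMESERIES_PATTERN.match(path.name)
    if not m:
        raise FormatError(f"file name {path.name!r} does not match sub-XX_day-D_scan-S.tsv")
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "region":
        raise FormatError(f"{path}: first column must be named 'region'")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate region ids {dupes}")
    return RegionTimeSeries(
        values=df.to_numpy(dtype=float),
        subject=f"sub-{m['subject']}",
        day=int(m["day"]),
        scan=m["scan"],
        region_ids=tuple(df.index),
    )


def write_parcellation(path: str | Path, parc: pd.DataFrame) -> None:
    parc.to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_parcellation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    parc = pd.read_csv(path, sep="\t")
    missing = [c for c in PARCELLATION_COLUMNS if c not in parc.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if parc["region"].duplicated().any():
        raise FormatError(f"{path}: duplicate region ids")
    bad_hemi = set(parc["hemisphere"]) - {"L", "R"}
    if bad_hemi:
        raise FormatError(f"{path}: unknown hemisphere labels {sorted(bad_hemi)}")
    return parc


def write_trials(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    trials = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return trials


def write_matrix(path: str | Path, M: np.ndarray, region_ids) -> None:
    df = pd.DataFrame(M, index=list(region_ids), columns=list(region_ids))
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row/column region ids disagree")
    return df.to_numpy(dtype=float), tuple(df.index)


def check_region_consistency(ts_regions, parc: pd.DataFrame) -> None:
    known = set(parc["region"])
    unknown = [r for r in ts_regions if r not in known]
    if unknown:
        raise FormatError(f"region(s) absent from parcellation: {unknown[:5]}")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
    tmp.replace(path)      # atomic on POSIX


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
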