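"""Reading and writing of time-series tables, network maps, and derived artifacts.

Scans are delimited text tables (frames x regions) with a single header row
of region labels.  Comma- or tab-delimited files are distinguished by file
extension (``.tsv``/``.tab`` -> tab, anything else -> comma).  All frame
indices in user-facing output are 1-based; arrays are 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


class MappingError(ValueError):
    """Raised when a scan's regions cannot be mapped onto networks."""


@dataclass
class ScanRecord:
    """One scan: a T x R matrix of BOLD samples plus acquisition metadata."""

    data: np.ndarray
    region_labels: list[str]
    subject_id: str = ""
    session_id: str = ""
    condition: str = ""
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("scan data must be a 2-D frames x regions matrix")
        t, r = self.data.shape
        if t < 2:
            raise FormatError(f"scan needs at least 2 frames, got {t}")
        if r < 2:
            raise FormatError(f"scan needs at least 2 regions, got {r}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise FormatError(
                f"non-finite value at row {bad[0] + 1}, column "
                f"{self.region_labels[bad[1]]!r}"
            )
        self.region_labels = [str(x) for x in self.region_labels]
        if len(self.region_labels) != r:
            raise FormatError("number of region labels must match data columns")
        if len(set(self.region_labels)) != r:
            raise FormatError("region labels must be unique")
        if not self.tr_seconds > 0:
            raise FormatError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class NetworkMap:
    """Mapping from region labels to network labels, with a fixed network order."""

    region_to_network: dict[str, str]
    network_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.network_order:
            seen: list[str] = []
            for net in self.region_to_network.values():
                if net not in seen:
                    seen.append(net)
            self.network_order = seen
        if len(set(self.network_order)) != len(self.network_order):
            raise MappingError("network_order contains duplicates")
        nets = set(self.region_to_network.values())
        if len(self.network_order) < 2:
            raise MappingError("a network map needs at least 2 networks")
        missing = nets - set(self.network_order)
        if missing:
            raise MappingError(f"networks not in network_order: {sorted(missing)}")
        empty = set(self.network_order) - nets
        if empty:
            raise MappingError(f"networks without any region: {sorted(empty)}")

    @property
    def n_networks(self) -> int:
        return len(self.network_order)


def _sep_for(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","


def read_scan(
    path: str | Path,
    *,
    subject_id: str = "",
    session_id: str = "",
    condition: str = "",
    tr_seconds: float = 1.0,
) -> ScanRecord:
    """Read a delimited frames x regions table into a :class:`ScanRecord`.

    The first row is the header of region labels; the body must be fully
    numeric.  A non-numeric or missing cell raises :class:`FormatError`
    naming its 1-based row and column label.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n").rstrip("\r")
    labels = [c.strip() for c in header_line.split(sep)]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate region labels in header: {dupes}")
    df = pd.read_csv(path, sep=sep, skiprows=1, header=None, names=labels, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: table has a header but no data rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(labels):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            cell = raw.iloc[i]
            raise FormatError(
                f"{path}: non-numeric value {cell!r} at row {i + 1}, column {col!r}"
            )
        # float() is correctly rounded; pd.to_numeric can be 1 ULP off
        values[:, j] = raw.to_numpy().astype(np.float64)
    return ScanRecord(
        data=values,
        region_labels=labels,
        subject_id=subject_id,
        session_id=session_id,
        condition=condition,
        tr_seconds=tr_seconds,
    )


def write_scan(scan: ScanRecord, path: str | Path) -> None:
    """Write a scan back to a delimited table (full float precision)."""
    sep = _sep_for(path)
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(scan.data, columns=scan.region_labels).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def read_network_map(path: str | Path) -> NetworkMap:
    """Read a two-column (region_label, network_label) TSV.

    A header row is optional; a first row whose fields look like column
    names (``region``/``network`` variants) is skipped.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno} must have exactly 2 tab-separated fields"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    if pairs and pairs[0][0].lower() in {"region", "region_label", "roi"}:
        pairs = pairs[1:]
    if not pairs:
        raise FormatError(f"{path}: empty network map")
    mapping: dict[str, str] = {}
    for region, net in pairs:
        if region in mapping and mapping[region] != net:
            raise MappingError(f"region {region!r} mapped to multiple networks")
        mapping[region] = net
    return NetworkMap(region_to_network=mapping)


def write_network_map(netmap: NetworkMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region_label\tnetwork_label\n")
        for region, net in netmap.region_to_network.items():
            fh.write(f"{region}\t{net}\n")


def aggregate_networks(scan: ScanRecord, netmap: NetworkMap) -> ScanRecord:
    """Average member-region columns into one column per network.

    Columns of the result follow ``netmap.network_order``; each network
    column is the unweighted mean of its member regions present in the scan.
    """
    unmapped = [r for r in scan.region_labels if r not in netmap.region_to_network]
    if unmapped:
        raise MappingError(f"regions absent from network map: {unmapped}")
    col_of = {label: i for i, label in enumerate(scan.region_labels)}
    members: dict[str, list[int]] = {net: [] for net in netmap.network_order}
    for label in scan.region_labels:
        members[netmap.region_to_network[label]].append(col_of[label])
    missing = [net for net, idx in members.items() if not idx]
    if missing:
        raise MappingError(f"networks with no member region in scan: {missing}")
    data = np.column_stack(
        [scan.data[:, members[net]].mean(axis=1) for net in netmap.network_order]
    )
    return ScanRecord(
        data=data,
        region_labels=list(netmap.network_order),
        subject_id=scan.subject_id,
        session_id=scan.session_id,
        condition=scan.condition,
        tr_seconds=scan.tr_seconds,
    )


def write_patterns(series, labels: list[str], path: str | Path) -> None:
    """Write a binary pattern series as TSV: frame, code, one +/-1 column per unit."""
    n = series.patterns.shape[1]
    if len(labels) != n:
        raise FormatError("label count must match pattern width")
    df = pd.DataFrame(series.patterns, columns=labels)
    df.insert(0, "code", series.codes)
    df.insert(0, "frame", np.arange(1, len(series.codes) + 1))
    df.to_csv(path, sep="\t", index=False)


def read_patterns(path: str | Path):
    """Read a pattern TSV written by :func:`write_patterns`."""
    from .phase import BinaryPatternSeries

    df = pd.read_csv(path, sep="\t")
    unit_cols = [c for c in df.columns if c not in {"frame", "code"}]
    patterns = df[unit_cols].to_numpy(dtype=int)
    series = BinaryPatternSeries.from_patterns(patterns)
    if "code" in df.columns and not np.array_equal(
        series.codes, df["code"].to_numpy(dtype=int)
    ):
        raise FormatError(f"{path}: stored codes disagree with +/-1 columns")
    return series, unit_cols


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
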