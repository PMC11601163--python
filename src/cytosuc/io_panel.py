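"""Event-table I/O and the panel configuration mapping channels to roles.

An :class:`EventTable` is the universal carrier through the pipeline: a
cells x channels float matrix, one sample label per cell, and a transform
state flag (``raw`` -> ``asinh`` -> ``asinh_zscored``).

A :class:`PanelConfig` names which channels are DNA (iridium) stains,
barcoding isotopes, antibody-based surrogate markers, optional extra
surrogate channels, and which markers should be corrected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _fcs
from ._exceptions import ConfigurationError, DataError, ParseError

RAW = "raw"
ASINH = "asinh"
ASINH_ZSCORED = "asinh_zscored"
_STATES = (RAW, ASINH, ASINH_ZSCORED)


@dataclass(frozen=True)
class PanelConfig:
    """Channel-role configuration.

    All named channels must be distinct across roles, and markers to
    correct may not double as DNA or barcoding channels.
    """

    dna_channels: list[str] = field(default_factory=list)
    barcode_channels: list[str] = field(default_factory=list)
    n_top_barcodes: int = 3
    antibody_suc_markers: list[str] = field(default_factory=list)
    extra_suc_markers: list[str] = field(default_factory=list)
    markers_to_correct: list[str] = field(default_factory=list)
    sample_column: str = "sample"
    asinh_cofactor: float = 5.0

    def __post_init__(self) -> None:
        roles = (
            list(self.dna_channels)
            + list(self.barcode_channels)
            + list(self.antibody_suc_markers)
            + list(self.extra_suc_markers)
        )
        if len(roles) != len(set(roles)):
            raise ConfigurationError("channels assigned to more than one SUC role")
        overlap = set(self.markers_to_correct) & (
            set(self.dna_channels) | set(self.barcode_channels)
        )
        if overlap:
            raise ConfigurationError(
                f"markers_to_correct overlap DNA/barcode channels: {sorted(overlap)}"
            )
        if len(set(self.markers_to_correct)) != len(self.markers_to_correct):
            raise ConfigurationError("duplicate names in markers_to_correct")
        if self.n_top_barcodes < 1:
            raise ConfigurationError("n_top_barcodes must be a positive integer")
        if self.barcode_channels and self.n_top_barcodes > len(self.barcode_channels):
            raise ConfigurationError(
                "n_top_barcodes exceeds the number of barcode channels"
            )
        if not self.asinh_cofactor > 0:
            raise ConfigurationError("asinh_cofactor must be positive")

    @property
    def suc_channels(self) -> list[str]:
        """All channels consumed when assembling the surrogate matrix."""
        return (
            list(self.dna_channels)
            + list(self.barcode_channels)
            + list(self.antibody_suc_markers)
            + list(self.extra_suc_markers)
        )

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown panel config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class EventTable:
    """Cells x channels intensity matrix with per-cell sample labels."""

    values: np.ndarray
    channel_names: list[str]
    sample_labels: np.ndarray
    transform_state: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D cells x channels matrix")
        self.channel_names = [str(c) for c in self.channel_names]
        self.sample_labels = np.asarray(self.sample_labels, dtype=object)
        if self.values.shape[1] != len(self.channel_names):
            raise DataError("channel_names length does not match value columns")
        if self.values.shape[0] != len(self.sample_labels):
            raise DataError("sample_labels length does not match number of cells")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise DataError("channel names are not unique")
        if self.transform_state not in _STATES:
            raise DataError(f"unknown transform_state {self.transform_state!r}")
        if self.transform_state == RAW and np.nanmin(self.values, initial=0) < 0:
            raise DataError("raw intensities must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a 1-D copy."""
        return self.values[:, self.index_of(name)].copy()

    def index_of(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not present in table") from None

    def require_channels(self, names) -> None:
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise ConfigurationError(f"channels missing from table: {missing}")

    def copy(self) -> "EventTable":
        return EventTable(
            self.values.copy(),
            list(self.channel_names),
            self.sample_labels.copy(),
            self.transform_state,
        )

    def samples(self) -> list:
        """Unique sample labels in order of first appearance."""
        seen: dict = {}
        for lab in self.sample_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def to_dataframe(self, sample_column: str = "sample") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channel_names)
        df[sample_column] = self.sample_labels
        return df


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_events(path, format: str | None = None, sample_column: str = "sample") -> EventTable:
    """Read an event table from a CSV or FCS file.

    ``format`` defaults to the file extension. CSV requires a header row
    containing ``sample_column``; every other column is a channel.
    """
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        return _read_csv(path, sample_column)
    if fmt == "fcs":
        return _read_fcs(path)
    raise ConfigurationError(f"unknown format {fmt!r}")


def _read_csv(path: Path, sample_column: str) -> EventTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if sample_column not in df.columns:
        raise ConfigurationError(
            f"sample column {sample_column!r} not found in {path.name}"
        )
    labels = df[sample_column].to_numpy(dtype=object)
    channels = [c for c in df.columns if c != sample_column]
    block = df[channels]
    bad = [c for c in channels if not pd.api.types.is_numeric_dtype(block[c])]
    if bad:
        raise ParseError(f"non-numeric values in channel columns: {bad}")
    state = RAW
    meta = _sidecar(path)
    if meta.exists():
        state = json.loads(meta.read_text()).get("transform_state", RAW)
    return EventTable(block.to_numpy(dtype=np.float64), channels, labels, state)


def _read_fcs(path: Path) -> EventTable:
    data, names, kw = _fcs.read_fcs(path)
    state = kw.get(_fcs.KW_TRANSFORM, RAW).strip() or RAW
    if _fcs.LABEL_PARAM in names and _fcs.KW_LABELS in kw:
        idx = names.index(_fcs.LABEL_PARAM)
        mapping = kw[_fcs.KW_LABELS].split("\t")
        codes = data[:, idx].astype(int)
        labels = np.array([mapping[c] for c in codes], dtype=object)
        keep = [i for i in range(data.shape[1]) if i != idx]
        data = data[:, keep]
        names = [names[i] for i in keep]
    else:
        labels = np.array(["all"] * data.shape[0], dtype=object)
    return EventTable(data, names, labels, state)


def write_events(
    table: EventTable, path, format: str | None = None, sample_column: str = "sample"
) -> None:
    """Write an event table as CSV (with a metadata sidecar) or FCS."""
    if table.n_cells == 0:
        raise DataError("refusing to write an empty event table")
    path = Path(path)
    fmt = format or ("fcs" if path.suffix.lower() == ".fcs" else "csv")
    if fmt == "csv":
        table.to_dataframe(sample_column).to_csv(path, index=False)
        _sidecar(path).write_text(
            json.dumps({"transform_state": table.transform_state}, indent=0) + "\n"
        )
    elif fmt == "fcs":
        labels = table.samples()
        code_of = {lab: i for i, lab in enumerate(labels)}
        codes = np.array([code_of[lab] for lab in table.sample_labels], dtype=np.float64)
        data = np.column_stack([table.values, codes])
        _fcs.write_fcs(
            path,
            data,
            table.channel_names + [_fcs.LABEL_PARAM],
            extra_keywords={
                _fcs.KW_TRANSFORM: table.transform_state,
                _fcs.KW_LABELS: "\t".join(str(lab) for lab in labels),
            },
        )
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
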