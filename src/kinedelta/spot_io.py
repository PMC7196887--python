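"""Spot-table I/O, per-cell chromatic correction, and channel pairing.

The unit of data is a long-form table of localized fluorophore spots: one
row per (cell, kinetochore, channel), with 3D coordinates in nanometres in
the microscope frame (z = optical axis), plus raw intensity and local
background. Downstream distance inference consumes per-kinetochore 3D
displacement vectors between a reference and a query channel, after the
per-cell chromatic correction that forces the cell-average inter-channel
displacement to zero on each axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Columns every spot table must provide.
REQUIRED_COLUMNS = (
    "cell_id",
    "kinetochore_id",
    "channel",
    "x_nm",
    "y_nm",
    "z_nm",
)

#: Recognized optional columns (preserved, with semantics).
OPTIONAL_COLUMNS = ("sister_pair_id", "intensity", "background", "excluded")

_COORD_COLUMNS = ("x_nm", "y_nm", "z_nm")


class SpotSchemaError(ValueError):
    """A required column is missing or a field violates the schema."""


class SpotParseError(ValueError):
    """A cell of the CSV could not be parsed as the declared type."""


@dataclass
class SpotTable:
    """Long-form table of localized spots, coordinates in nm.

    Wraps a :class:`pandas.DataFrame` with one row per
    (cell_id, kinetochore_id, channel). Unknown input columns are kept in
    ``metadata["extra_columns"]`` order but remain in ``data`` so round
    trips are lossless.
    """

    data: pd.DataFrame
    units: str = "nm"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units != "nm":
            raise SpotSchemaError(f"units must be 'nm', got {self.units!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SpotSchemaError(f"missing required column(s): {', '.join(missing)}")
        coords = self.data[list(_COORD_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            bad = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
            raise SpotSchemaError(f"non-finite coordinate in row {bad}")
        if "intensity" in self.data.columns:
            inten = pd.to_numeric(self.data["intensity"], errors="coerce")
            if (inten.dropna() < 0).any():
                raise SpotSchemaError("negative intensity")
        dup = self.data.duplicated(subset=["cell_id", "kinetochore_id", "channel"])
        if dup.any():
            raise SpotSchemaError(
                f"duplicate (cell_id, kinetochore_id, channel) at row {int(dup.idxmax())}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return sorted(self.data["channel"].astype(str).unique())

    def included(self) -> pd.DataFrame:
        """Rows not flagged by the optional boolean ``excluded`` column."""
        df = self.data
        if "excluded" in df.columns:
            flag = df["excluded"].fillna(False).astype(bool)
            df = df.loc[~flag]
        return df


@dataclass
class DisplacementSet:
    """Per-kinetochore displacement vectors reference → query channel (nm)."""

    vectors: pd.DataFrame  # columns: cell_id, kinetochore_id, dx, dy, dz
    reference_channel: str
    query_channel: str
    corrected: bool = False
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.vectors)

    def as_array(self) -> np.ndarray:
        """(n, 3) array of displacement vectors."""
        return self.vectors[["dx", "dy", "dz"]].to_numpy(dtype=float)

    def norms(self) -> np.ndarray:
        """Euclidean norms |v| (the raw, positively biased Δ_3D values)."""
        return np.linalg.norm(self.as_array(), axis=1)


def read_spot_table(path, dialect: Mapping | None = None) -> SpotTable:
    """Read a spot CSV (comma-separated, header row) into a SpotTable.

    Parameters
    ----------
    path : str or file-like
        CSV with at least the :data:`REQUIRED_COLUMNS`.
    dialect : mapping, optional
        Extra keyword arguments passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).
    """
    kwargs = {"float_precision": "round_trip", **(dialect or {})}
    df = pd.read_csv(path, **kwargs)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpotSchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in _COORD_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SpotParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col}, row {row}"
            )
        df[col] = coerced
    df["channel"] = df["channel"].astype(str)
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    meta = {"source": str(path), "extra_columns": extra}
    return SpotTable(data=df, metadata=meta)


def write_spot_table(table: SpotTable, path) -> None:
    """Write a SpotTable back to CSV.

    Floats are written with Python's shortest-round-trip repr, so a
    read/write cycle preserves every numeric field bit-exactly.
    """
    table.data.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def chromatic_correct(table: SpotTable, reference_channel: str) -> SpotTable:
    """Per-cell chromatic correction against a reference channel.

    For each cell and each non-reference channel, subtracts the cell-mean
    per-axis displacement (query − reference, over kinetochores where both
    channels are present) from that channel's coordinates, so the
    cell-average intra-kinetochore displacement is exactly zero on each of
    x, y and z. Idempotent. Cells where a channel has no paired reference
    spot are left untouched for that channel, with a warning.
    """
    reference_channel = str(reference_channel)
    df = table.data.copy()
    if reference_channel not in set(df["channel"]):
        raise SpotSchemaError(f"reference channel {reference_channel!r} not in table")

    n_kts = df.groupby("cell_id")["kinetochore_id"].nunique()
    low = n_kts[n_kts < 2]
    if len(low):
        warnings.warn(
            f"{len(low)} cell(s) have < 2 kinetochores; per-cell chromatic "
            "correction will be poorly determined",
            stacklevel=2,
        )

    ref = df[df["channel"] == reference_channel].set_index(
        ["cell_id", "kinetochore_id"]
    )[list(_COORD_COLUMNS)]

    for (cell, channel), idx in df.groupby(["cell_id", "channel"]).groups.items():
        if str(channel) == reference_channel:
            continue
        sub = df.loc[idx].set_index("kinetochore_id")
        try:
            ref_cell = ref.loc[cell]
        except KeyError:
            warnings.warn(
                f"cell {cell!r}: no reference-channel spots; channel {channel!r} skipped",
                stacklevel=2,
            )
            continue
        common = sub.index.intersection(ref_cell.index)
        if len(common) == 0:
            warnings.warn(
                f"cell {cell!r}: channel {channel!r} has no kinetochore paired "
                "with the reference; skipped",
                stacklevel=2,
            )
            continue
        shift = (
            sub.loc[common, list(_COORD_COLUMNS)].to_numpy(dtype=float)
            - ref_cell.loc[common, list(_COORD_COLUMNS)].to_numpy(dtype=float)
        ).mean(axis=0)
        df.loc[idx, list(_COORD_COLUMNS)] = (
            df.loc[idx, list(_COORD_COLUMNS)].to_numpy(dtype=float) - shift
        )

    meta = dict(table.metadata)
    meta["chromatic_corrected"] = {"reference_channel": reference_channel}
    return SpotTable(data=df, units=table.units, metadata=meta)


def pair_displacements(table: SpotTable, ref: str, query: str) -> DisplacementSet:
    """Pair two channels into per-kinetochore displacement vectors ref → query.

    Kinetochores missing either channel (or flagged ``excluded``) are
    dropped; the count of dropped kinetochores is reported on the result.
    Output ordering is stable by (cell_id, kinetochore_id).
    """
    ref, query = str(ref), str(query)
    df = table.included()
    keys = ["cell_id", "kinetochore_id"]
    a = df[df["channel"] == ref].set_index(keys)[list(_COORD_COLUMNS)]
    b = df[df["channel"] == query].set_index(keys)[list(_COORD_COLUMNS)]
    common = a.index.intersection(b.index)
    n_total = len(a.index.union(b.index))
    if len(common) == 0:
        raise ValueError(
            f"no kinetochore has both channels {ref!r} and {query!r}; cannot pair"
        )
    common = common.sort_values()
    delta = b.loc[common].to_numpy(dtype=float) - a.loc[common].to_numpy(dtype=float)
    vec = pd.DataFrame(common.to_frame(index=False))
    vec[["dx", "dy", "dz"]] = delta
    corrected = "chromatic_corrected" in table.metadata
    return DisplacementSet(
        vectors=vec,
        reference_channel=ref,
        query_channel=query,
        corrected=corrected,
        n_dropped=n_total - len(common),
    )


def normalize_intensity(
    table: SpotTable, target: str, reference: str | None = None
) -> pd.DataFrame:
    """Background-subtracted (optionally reference-normalized) intensities.

    value = (I_target − bg_target) / (I_ref − bg_ref) when a reference
    channel is given; the plain background-subtracted signal otherwise.
    Records whose reference net intensity is ≤ 0 are flagged and excluded
    from the returned table (column ``flagged`` on the full table).
    """
    for col in ("intensity", "background"):
        if col not in table.data.columns:
            raise SpotSchemaError(f"missing required column(s): {col}")
    target = str(target)
    keys = ["cell_id", "kinetochore_id"]
    df = table.included()
    tgt = df[df["channel"] == target].set_index(keys)
    net = (tgt["intensity"] - tgt["background"]).rename("normalized_intensity")
    out = net.reset_index()
    out["flagged"] = False
    if reference is not None:
        reference = str(reference)
        refdf = df[df["channel"] == reference].set_index(keys)
        ref_net = refdf["intensity"] - refdf["background"]
        ref_net = ref_net.reindex(net.index)
        out["flagged"] = (ref_net.isna() | (ref_net <= 0)).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            out["normalized_intensity"] = net.to_numpy() / ref_net.to_numpy()
        out = out.loc[~out["flagged"]]
    return out.reset_index(drop=True)
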