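"""On-disk dialects shared by the pipeline.

The canonical *profile table* is a UTF-8 TSV with one row per position:
columns ``condition``, ``cell_id``, ``fragment_id``, ``position_px``,
then one column per channel.  Positions are contiguous per fragment
starting at 0 and no cell may be missing.

``import_external_table`` adapts foreign per-fragment intensity tables
(e.g. spreadsheet sheets exported to TSV/CSV) to this dialect through a
user-supplied column mapping; the delimiter is sniffed and decimal
commas are tolerated.  Fragments with gaps in their position column are
split at the gaps, and zero-variance fragments are flagged, with counts
logged at INFO so imports can be checked against expected n-values.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import AxisProfile

__all__ = [
    "ColumnMap",
    "write_profiles",
    "read_profiles",
    "profiles_to_frame",
    "import_external_table",
    "distance_axis",
]

logger = logging.getLogger(__name__)

_META_COLS = ["condition", "cell_id", "fragment_id", "position_px"]


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from foreign table headers to the profile dialect.

    ``channels`` maps output channel names to source column names.
    ``condition``/``cell``/``fragment`` may be ``None`` if the source
    lacks them, in which case ``fallback_condition`` (e.g. a sheet or
    file name) and synthesized ids are used.  ``position`` may be
    ``None`` when rows are already in order within each fragment.
    """

    channels: dict
    condition: str | None = None
    cell: str | None = None
    fragment: str | None = None
    position: str | None = None
    fallback_condition: str = "unknown"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("column map must name at least one channel column")


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Flatten profiles into the canonical one-row-per-position table."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    channels = profiles[0].channels
    for p in profiles:
        if p.channels != channels:
            raise ValueError("all profiles must share the same channel set")
    rows = []
    for p in profiles:
        block = {
            "condition": p.condition,
            "cell_id": p.cell_id,
            "fragment_id": p.fragment_id,
            "position_px": p.positions_px,
        }
        for ch in channels:
            block[ch] = p.intensities[ch]
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)


def write_profiles(profiles, path) -> None:
    """Write profiles as the canonical TSV dialect."""
    frame = profiles_to_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profiles(path) -> list[AxisProfile]:
    """Read a canonical profile TSV back into :class:`AxisProfile` objects."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    channels = [c for c in frame.columns if c not in _META_COLS]
    if not channels:
        raise ValueError(f"{path}: no channel columns found")
    profiles = []
    for (cond, cell, frag), grp in frame.groupby(
        ["condition", "cell_id", "fragment_id"], sort=False, dropna=False
    ):
        grp = grp.sort_values("position_px")
        pos = grp["position_px"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            raise ValueError(
                f"{path}: fragment {frag!r} positions are not contiguous from 0"
            )
        profiles.append(
            AxisProfile(
                intensities={ch: grp[ch].to_numpy(float) for ch in channels},
                cell_id=str(cell),
                fragment_id=str(frag),
                condition=str(cond),
            )
        )
    return profiles


def _sniff_read(path, decimal_candidates=(".", ",")) -> pd.DataFrame:
    """Read a delimited text table, sniffing separator and decimal mark."""
    with open(path, encoding="utf-8") as fh:
        head = fh.read(8192)
    sep = "\t" if "\t" in head.splitlines()[0] else (";" if ";" in head.splitlines()[0] else ",")
    last_err = None
    for dec in decimal_candidates:
        if dec == sep:
            continue
        try:
            frame = pd.read_csv(path, sep=sep, decimal=dec)
        except Exception as e:  # malformed with this decimal mark
            last_err = e
            continue
        # decimal-comma files read with decimal='.' leave object columns
        numericish = frame.select_dtypes(include=[np.number]).shape[1]
        if numericish > 0:
            return frame
    if last_err is not None:
        raise ValueError(f"could not parse {path}: {last_err}")
    raise ValueError(f"could not find numeric columns in {path}")


def import_external_table(
    path,
    column_map: ColumnMap,
    min_length: int = 3,
) -> list[AxisProfile]:
    """Import a foreign per-fragment intensity table as profiles.

    Fragments whose position column has gaps are split at each gap into
    sub-fragments (suffixed ``/0``, ``/1``, ...).  Pieces shorter than
    ``min_length`` and zero-variance fragments are dropped, all with
    logged counts.  Unmapped required columns raise with the available
    headers listed.
    """
    frame = _sniff_read(path)
    available = list(frame.columns)

    def col(name, label):
        if name is None:
            return None
        if name not in frame.columns:
            raise ValueError(
                f"column {name!r} (mapped as {label}) not in table; "
                f"available: {available}"
            )
        return name

    for out_ch, src in column_map.channels.items():
        col(src, f"channel {out_ch}")
    cond_c = col(column_map.condition, "condition")
    cell_c = col(column_map.cell, "cell")
    frag_c = col(column_map.fragment, "fragment")
    pos_c = col(column_map.position, "position")

    work = pd.DataFrame(
        {
            "condition": frame[cond_c].astype(str)
            if cond_c
            else column_map.fallback_condition,
            "cell_id": frame[cell_c].astype(str) if cell_c else "cell0",
            "fragment_id": frame[frag_c].astype(str) if frag_c else "frag0",
        }
    )
    for out_ch, src in column_map.channels.items():
        vals = frame[src]
        if vals.dtype == object:  # decimal-comma leftovers
            vals = vals.str.replace(",", ".", regex=False).astype(float)
        work[out_ch] = vals.astype(float)
    if pos_c:
        work["position_px"] = frame[pos_c].astype(float)
    else:
        work["position_px"] = work.groupby(
            ["condition", "cell_id", "fragment_id"]
        ).cumcount()

    profiles: list[AxisProfile] = []
    n_split = n_short = n_flat = 0
    channels = list(column_map.channels)
    for (cond, cell, frag), grp in work.groupby(
        ["condition", "cell_id", "fragment_id"], sort=False
    ):
        grp = grp.sort_values("position_px")
        grp = grp.dropna(subset=channels)
        pos = grp["position_px"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) != 1)
        pieces = np.split(np.arange(len(pos)), breaks + 1)
        if len(pieces) > 1:
            n_split += 1
        for k, piece in enumerate(pieces):
            if len(piece) < min_length:
                n_short += 1
                continue
            sub = grp.iloc[piece]
            frag_id = str(frag) if len(pieces) == 1 else f"{frag}/{k}"
            intensities = {ch: sub[ch].to_numpy(float) for ch in channels}
            if any(v.std(ddof=1) == 0.0 for v in intensities.values()):
                n_flat += 1
                logger.info("flagging zero-variance fragment %s", frag_id)
                continue
            profiles.append(
                AxisProfile(
                    intensities=intensities,
                    cell_id=str(cell),
                    fragment_id=frag_id,
                    condition=str(cond),
                )
            )
    logger.info(
        "imported %d fragments from %s (%d split at gaps, %d too-short pieces "
        "dropped, %d zero-variance dropped)",
        len(profiles), path, n_split, n_short, n_flat,
    )
    return profiles


def distance_axis(lags_px, pixel_size_nm: float = 65.0) -> pd.DataFrame:
    """Physical distances for a lag vector: columns in px, nm and um."""
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    lags = np.asarray(lags_px, dtype=float)
    nm = lags * pixel_size_nm
    return pd.DataFrame({"lag_px": lags, "distance_nm": nm, "distance_um": nm / 1000.0})


def curve_to_frame(curve) -> pd.DataFrame:
    """Tabulate a :class:`~axiscorr.correlation.CorrelationCurve`."""
    dist = distance_axis(curve.lags_px, curve.pixel_size_nm)
    return pd.DataFrame(
        {
            "lag_px": curve.lags_px,
            "distance_nm": dist["distance_nm"],
            "value": curve.values,
            "sem": curve.sem,
            "n_products": curve.n_products,
            "n_fragments": curve.n_fragments,
            "p_value": curve.p_values,
        }
    )


def write_curve(curve, path, sidecar: dict | None = None) -> None:
    """Write a curve TSV plus a JSON sidecar with estimator provenance."""
    curve_to_frame(curve).to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {
        "kind": curve.kind,
        "estimator": curve.estimator,
        "sample_unit": curve.sample_unit,
        "x_max": int(curve.lags_px.max()),
        "n_fragments": curve.n_fragments,
        "n_cells": curve.n_cells,
        "condition": curve.condition,
        "pixel_size_nm": curve.pixel_size_nm,
        "degenerate_lags": list(curve.degenerate_lags),
    }
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
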