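"""Plain-text I/O: delimited recordings, square connectivity CSVs, tables.

Recordings are stored as CSV with a header row of channel labels and one row
per sample (columns = channels); readers return the channels x samples
orientation used in memory.  EDF reading is supported through MNE when it is
installed; nothing in this package writes EDF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BandSpec, ConnectivityMatrix, Recording
from .metrics import METRIC_NAMES, MetricsRow

CONDITION_SUFFIX = {"pre": "before", "post": "after"}


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_recording_csv(
    path: str | Path,
    rate_hz: float,
    participant_id: str = "",
    condition: str = "",
) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    return Recording(
        participant_id=participant_id or path.stem.split("_")[0],
        condition=condition or (path.stem.split("_")[-1] if "_" in path.stem else ""),
        channel_labels=[str(c) for c in df.columns],
        rate_hz=rate_hz,
        data=df.to_numpy(dtype=float).T,
    )


def read_recording_edf(
    path: str | Path, participant_id: str = "", condition: str = ""
) -> Recording:
    """Read a standard 16-bit EDF recording (requires the mne package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF reading requires the 'mne' package (install bandclust[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        participant_id=participant_id or Path(path).stem.split("_")[0],
        condition=condition or Path(path).stem.split("_")[-1],
        channel_labels=list(raw.ch_names),
        rate_hz=float(raw.info["sfreq"]),
        data=raw.get_data(),
    )


def read_recording(
    path: str | Path, rate_hz: float | None = None, **kwargs
) -> Recording:
    """Dispatch on extension: ``.edf`` via MNE, anything else as delimited."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, **kwargs)
    if rate_hz is None:
        raise ValueError("rate_hz is required for delimited recordings")
    return read_recording_csv(path, rate_hz=rate_hz, **kwargs)


def write_connectivity_csv(w: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    labels = w.channel_labels or [f"Ch{i + 1:02d}" for i in range(w.n_channels)]
    pd.DataFrame(w.weights, index=labels, columns=labels).to_csv(path)
    return path


def read_connectivity_csv(
    path: str | Path,
    band: BandSpec,
    participant_id: str = "",
    condition: str = "",
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        weights=df.to_numpy(dtype=float),
        band=band,
        participant_id=participant_id,
        condition=condition,
        channel_labels=[str(c) for c in df.columns],
    )


def metrics_to_frame(rows: list[MetricsRow]) -> pd.DataFrame:
    """Long-format metrics table, one row per participant x condition x band."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "condition": [r.condition for r in rows],
            "band": [r.band for r in rows],
            "Global_Efficiency": [r.global_efficiency for r in rows],
            "Local_Efficiency": [r.local_efficiency for r in rows],
            "Clustering_Coefficient": [r.clustering_coefficient for r in rows],
            "Node_Strength": [r.node_strength for r in rows],
            "Assortativity": [r.assortativity for r in rows],
        }
    )


def feature_table_from_metrics(metrics: pd.DataFrame, band: str) -> pd.DataFrame:
    """Wide 10-feature table (5 metrics x before/after) for one band.

    Columns follow the published naming contract, e.g.
    ``Global_Efficiency_before``.  Undefined (NaN) metric values abort with
    the offending participants named, since they cannot be standardized.
    """
    sub = metrics[metrics["band"] == band]
    if sub.empty:
        raise ValueError(f"no metric rows for band {band!r}")
    wide = {}
    for condition, suffix in CONDITION_SUFFIX.items():
        block = sub[sub["condition"] == condition].set_index("participant_id")
        if block.empty:
            raise ValueError(f"no {condition!r} rows for band {band!r}")
        for name in METRIC_NAMES:
            wide[f"{name}_{suffix}"] = block[name]
    table = pd.DataFrame(wide).sort_index()
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(
            f"undefined metric values for participants {bad} in band {band!r}"
        )
    return table
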