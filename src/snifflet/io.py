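"""Dataset container and delimited-text readers/writers.

All tables are comma-delimited UTF-8 text with a header row and '.'
decimal; times are seconds. A dataset is three tables:

- ``spikes.csv``: ``cell_id,t``
- ``sniffs.csv``: ``sniff_id,t_onset,t_inh_end,t_end``
- ``trials.csv``: ``trial_id,odor,concentration,t_odor_on,t_light``

Raw pressure is accepted as single-column text or as an HDF5 dataset
with a ``sample_rate`` attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sniffing import SniffTrain

__all__ = ["Dataset", "SchemaError", "load_dataset", "save_dataset", "load_pressure"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

_REQUIRED = {
    "spikes": ["cell_id", "t"],
    "sniffs": ["sniff_id", "t_onset", "t_inh_end", "t_end"],
    "trials": ["trial_id", "odor", "concentration", "t_odor_on", "t_light"],
}


class SchemaError(ValueError):
    """A dataset table violates the expected schema."""


@dataclass
class Dataset:
    """Validated in-memory dataset (three tidy tables)."""

    spikes: pd.DataFrame
    sniffs: pd.DataFrame
    trials: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, cols in _REQUIRED.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} missing column(s) {missing}")
        for name, col in (("spikes", "t"), ("sniffs", "t_onset"), ("sniffs", "t_inh_end"),
                          ("sniffs", "t_end")):
            vals = getattr(self, name)[col]
            if len(vals) == 0:
                continue
            if not np.issubdtype(vals.dtype, np.number):
                raise SchemaError(f"{name}.{col} must be numeric")
            if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                raise SchemaError(f"{name}.{col} contains non-finite times")

    def sniff_train(self) -> SniffTrain:
        df = self.sniffs.sort_values("t_onset")
        return SniffTrain.from_arrays(
            df["t_onset"].to_numpy(float),
            df["t_inh_end"].to_numpy(float),
            df["t_end"].to_numpy(float),
        )

    def cell_ids(self) -> list:
        return sorted(self.spikes["cell_id"].unique().tolist())

    def spike_times(self, cell_id) -> np.ndarray:
        return np.sort(self.spikes.loc[self.spikes["cell_id"] == cell_id, "t"].to_numpy(float))


def load_dataset(path, schema_version: str = SCHEMA_VERSION) -> Dataset:
    """Load and validate a dataset directory containing the three tables."""
    p = Path(path)
    frames = {}
    for name in _REQUIRED:
        f = p / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing table {f}")
        frames[name] = pd.read_csv(f)
    ds = Dataset(**frames, metadata={"source": str(p), "schema_version": schema_version})
    logger.info(
        "loaded dataset: %d spikes, %d sniffs, %d trials",
        len(ds.spikes), len(ds.sniffs), len(ds.trials),
    )
    return ds


def save_dataset(ds: Dataset, path) -> None:
    """Write the three tables as CSV under ``path``."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    for name in _REQUIRED:
        getattr(ds, name).to_csv(p / f"{name}.csv", index=False)


def load_pressure(path, sample_rate: Optional[float] = None) -> tuple[np.ndarray, float]:
    """Load a raw pressure trace from single-column text or HDF5.

    For HDF5 the first dataset is used and its ``sample_rate`` attribute
    read unless overridden.
    """
    p = Path(path)
    if p.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(p, "r") as f:
            key = next(iter(f.keys()))
            data = f[key][...]
            sr = sample_rate or float(f[key].attrs.get("sample_rate", 0))
    else:
        data = np.loadtxt(p)
        sr = sample_rate or 0.0
    if sr <= 0:
        raise ValueError("sample_rate must be provided (or stored as an HDF5 attribute)")
    return np.asarray(data, dtype=float).ravel(), sr
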