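"""File-format glue: tidy CSV datasets, trajectory CSVs, JSON results.

Datasets use a long ("tidy") CSV with columns time_h, variable, value and
optional sd, n — tolerant of variables missing at individual time points,
which is the reality of figure-derived data.  Trajectories are wide CSVs
(time_h, H_mM, P_mM, X_gL[, E_mM]).  Every command writes a metadata
sidecar (config, seed, package version) sufficient to re-run it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import FitResult, TimeSeriesDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_fit_result",
    "write_chains",
    "write_metadata",
]


def read_dataset(path) -> TimeSeriesDataset:
    """Read a tidy long-format dataset CSV."""
    return TimeSeriesDataset.from_tidy(
        pd.read_csv(path, float_precision="round_trip")
    )


def write_dataset(data: TimeSeriesDataset, path) -> None:
    """Write a dataset as tidy long-format CSV (17 significant digits)."""
    data.to_tidy().to_csv(path, index=False, float_format="%.17g")


def write_fit_result(result: FitResult, path) -> None:
    """Write the JSON summary of a fit (best fit, CIs, R^2, diagnostics)."""
    with open(path, "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2, default=float)


def write_chains(result: FitResult, path) -> None:
    """Dump posterior chains as CSV: chain, iteration, one column per parameter."""
    frames = []
    n_chains = next(iter(result.chains.values())).shape[0]
    for c in range(n_chains):
        df = pd.DataFrame(
            {name: result.chains[name][c] for name in result.param_names}
        )
        df.insert(0, "iteration", np.arange(len(df)))
        df.insert(0, "chain", c)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_metadata(path, **payload) -> None:
    """Write a JSON metadata sidecar (config, seed, package version)."""
    from . import __version__

    payload = {"acetokin_version": __version__, **payload}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
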