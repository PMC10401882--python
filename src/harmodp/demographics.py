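"""Per-site scanner and demographic summary tables.

The packaged fixture describes the 16-site ABIDE II cohort this package's
synthetic generator is calibrated to: per-site scanner, acquisition
parameters, diagnosis (ASD/HC) and sex counts, and age mean ± sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["DemographicsTable", "load_abide2_demographics", "summarize_demographics"]

_COUNT_COLS = ("n_asd", "n_hc", "n_male", "n_female")


@dataclass
class DemographicsTable:
    """One row per site: scanner, TR/TE, flip angle, voxel size, counts, age."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.frame
        required = ("site",) + _COUNT_COLS + ("age_mean", "age_sd")
        for col in required:
            if col not in df.columns:
                raise ValueError(f"demographics table missing column '{col}'")
        for col in _COUNT_COLS:
            vals = df[col]
            if (vals < 0).any() or not (vals == vals.astype(int)).all():
                raise ValueError(f"column '{col}' must hold non-negative integers")
            df[col] = vals.astype(int)

    @property
    def n_sites(self) -> int:
        return len(self.frame)


def load_abide2_demographics(path: str | Path | None = None) -> DemographicsTable:
    """Load the packaged 16-site demographics fixture (or a compatible CSV)."""
    if path is None:
        src = resources.files("harmodp.data").joinpath("abide2_demographics.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return DemographicsTable(frame=df)


def summarize_demographics(table: DemographicsTable) -> dict:
    """Totals across sites: n_sites, n_ASD, n_HC, n_total (= ASD + HC)."""
    df = table.frame
    n_asd = int(df["n_asd"].sum())
    n_hc = int(df["n_hc"].sum())
    return {
        "n_sites": int(len(df)),
        "n_ASD": n_asd,
        "n_HC": n_hc,
        "n_total": n_asd + n_hc,
    }
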