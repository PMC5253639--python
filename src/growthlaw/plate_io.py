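"""Reading, validation and background correction of plate-reader data.

The canonical on-disk format is a pair of tidy CSVs:

``timeseries.csv``
    columns ``time_min, well, channel, value`` with
    ``channel in {OD, GFP}`` — one row per reading.
``wells.csv``
    columns ``well, strain, reporter, carbon_source, camp_mM,
    perturbation, day`` — one row per well, ``reporter`` one of
    ``crp`` (CRP-activity reporter), ``sigma70`` (constitutive
    sigma-70 reporter) or ``promoterless`` (background).

Each analysis group — wells sharing (carbon source, cAMP dose,
perturbation, day) — is expected to contain all three reporter
strains; the promoterless well measures autofluorescence and is
subtracted from the GFP of the other two before promoter activities
are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "WellMeta",
    "WellSeries",
    "PlateExperiment",
    "read_plate_csv",
    "write_plate_csv",
    "subtract_background",
]

logger = logging.getLogger(__name__)

REPORTERS = ("crp", "sigma70", "promoterless")

# ``strain`` labels the circuit background (e.g. wild type vs the
# open-loop cAMP-synthesis deletion) shared by a group's three reporter
# wells, so it is part of the grouping key alongside the condition.
GROUP_KEYS = ("strain", "carbon_source", "camp_mM", "perturbation", "day")


@dataclass(frozen=True)
class WellMeta:
    """Identity and condition of one well."""

    well: str
    strain: str = ""
    reporter: str = "crp"
    carbon_source: str = ""
    camp_mM: float = 0.0
    perturbation: str = ""
    day: int = 1

    def __post_init__(self) -> None:
        if self.reporter not in REPORTERS:
            raise ValueError(
                f"unknown reporter {self.reporter!r}; expected one of {REPORTERS}")
        if self.camp_mM < 0:
            raise ValueError("cAMP concentration must be >= 0")

    @property
    def group_key(self) -> tuple:
        return (self.strain, self.carbon_source, self.camp_mM,
                self.perturbation, self.day)


@dataclass
class WellSeries:
    """One well's OD and GFP time series.

    times are minutes since inoculation, strictly increasing, nominally
    on a 9-min cadence; OD is blank-corrected optical density and GFP
    is raw (or, after :func:`subtract_background`, background-corrected)
    fluorescence in arbitrary units.
    """

    times: np.ndarray
    od: np.ndarray
    gfp: np.ndarray
    meta: WellMeta
    background_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (len(self.times) == len(self.od) == len(self.gfp)):
            raise ValueError("times, od and gfp must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PlateExperiment:
    """A collection of wells plus provenance of how they were loaded."""

    wells: list[WellSeries] = field(default_factory=list)
    source: str = ""
    rejected: dict[str, str] = field(default_factory=dict)  # well -> reason

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self) -> Iterator[WellSeries]:
        return iter(self.wells)

    def groups(self) -> dict[tuple, list[WellSeries]]:
        """Wells grouped by (strain, carbon_source, camp_mM, perturbation, day)."""
        out: dict[tuple, list[WellSeries]] = {}
        for w in self.wells:
            out.setdefault(w.meta.group_key, []).append(w)
        return out

    def get(self, well: str) -> WellSeries:
        for w in self.wells:
            if w.meta.well == well:
                return w
        raise KeyError(well)


def read_plate_csv(path: str | Path, meta_path: str | Path) -> PlateExperiment:
    """Load a tidy time-series CSV plus its well-metadata CSV.

    Wells with a missing channel or non-monotone timestamps are
    excluded (not fatal) and recorded in ``experiment.rejected`` with
    the reason; duplicated (well, time, channel) rows, unknown reporter
    labels, or an empty file raise immediately.
    """
    ts = pd.read_csv(path, float_precision="round_trip")
    required = {"time_min", "well", "channel", "value"}
    if ts.empty:
        raise ValueError(f"{path}: empty time-series file")
    if not required.issubset(ts.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if ts.duplicated(subset=["well", "time_min", "channel"]).any():
        dup = ts[ts.duplicated(subset=["well", "time_min", "channel"])]
        raise ValueError(
            f"{path}: duplicated (well, time, channel) rows, e.g. "
            f"{dup.iloc[0].to_dict()}")

    meta_df = pd.read_csv(meta_path, dtype={"well": str})

    def _str(row, key):
        v = row.get(key, "")
        return "" if pd.isna(v) else str(v)

    def _num(row, key, default, cast):
        v = row.get(key, default)
        return cast(default) if pd.isna(v) else cast(v)

    meta_by_well: dict[str, WellMeta] = {}
    for _, row in meta_df.iterrows():
        meta_by_well[str(row["well"])] = WellMeta(
            well=str(row["well"]),
            strain=_str(row, "strain"),
            reporter=str(row["reporter"]),
            carbon_source=_str(row, "carbon_source"),
            camp_mM=_num(row, "camp_mM", 0.0, float),
            perturbation=_str(row, "perturbation"),
            day=_num(row, "day", 1, int),
        )

    exp = PlateExperiment(source=str(path))
    for well, sub in ts.groupby("well", sort=False):
        well = str(well)
        if well not in meta_by_well:
            exp.rejected[well] = "no metadata"
            logger.warning("well %s: no metadata row, excluded", well)
            continue
        piv = sub.pivot_table(index="time_min", columns="channel",
                              values="value", aggfunc="first")
        if "OD" not in piv.columns or "GFP" not in piv.columns:
            exp.rejected[well] = "missing channel"
            logger.warning("well %s: missing OD or GFP channel, excluded", well)
            continue
        piv = piv.dropna(subset=["OD", "GFP"]).sort_index()
        t = piv.index.to_numpy(dtype=float)
        if len(t) == 0 or np.any(np.diff(t) <= 0):
            exp.rejected[well] = "non-monotone or empty time axis"
            logger.warning("well %s: bad time axis, excluded", well)
            continue
        exp.wells.append(WellSeries(
            times=t,
            od=piv["OD"].to_numpy(dtype=float),
            gfp=piv["GFP"].to_numpy(dtype=float),
            meta=meta_by_well[well],
        ))
    return exp


def write_plate_csv(exp: PlateExperiment, path: str | Path,
                    meta_path: str | Path) -> None:
    """Write an experiment back to the tidy CSV pair (lossless round trip)."""
    ts_rows = []
    meta_rows = []
    for w in exp.wells:
        m = w.meta
        meta_rows.append({
            "well": m.well, "strain": m.strain, "reporter": m.reporter,
            "carbon_source": m.carbon_source, "camp_mM": m.camp_mM,
            "perturbation": m.perturbation, "day": m.day,
        })
        for t, od, gfp in zip(w.times, w.od, w.gfp):
            ts_rows.append({"time_min": t, "well": m.well,
                            "channel": "OD", "value": od})
            ts_rows.append({"time_min": t, "well": m.well,
                            "channel": "GFP", "value": gfp})
    # repr-precision floats so that read(write(x)) == x bit for bit
    pd.DataFrame(ts_rows).to_csv(path, index=False,
                                 float_format=lambda v: repr(float(v)))
    pd.DataFrame(meta_rows).to_csv(meta_path, index=False,
                                   float_format=lambda v: repr(float(v)))


def subtract_background(group: Iterable[WellSeries], *,
                        clip_at_zero: bool = False) -> list[WellSeries]:
    """Subtract the promoterless well's GFP from the reporter wells.

    The promoterless strain carries no promoter driving GFP, so its
    fluorescence is cellular autofluorescence plus instrument offset.
    Its trace is linearly interpolated onto each reporter well's
    timestamps and subtracted from that well's GFP; OD is untouched.
    Negative corrected values are kept (and logged) unless
    ``clip_at_zero`` is set — clipping biases low signals upward.

    Returns the corrected crp/sigma70 wells (promoterless excluded).
    """
    group = list(group)
    background = [w for w in group if w.meta.reporter == "promoterless"]
    if not background:
        raise ValueError("group has no promoterless (background) well")
    bg = background[0]
    out = []
    for w in group:
        if w.meta.reporter == "promoterless":
            continue
        bg_interp = np.interp(w.times, bg.times, bg.gfp)
        corrected = w.gfp - bg_interp
        n_neg = int(np.sum(corrected < 0))
        if n_neg:
            logger.info("well %s: %d negative GFP values after background "
                        "subtraction", w.meta.well, n_neg)
            if clip_at_zero:
                corrected = np.clip(corrected, 0.0, None)
        out.append(replace(w, gfp=corrected, background_corrected=True))
    return out
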