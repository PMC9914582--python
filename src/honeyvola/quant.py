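"""Internal-standard semi-quantification and retention indexing.

Concentrations are expressed against a benzophenone internal standard (IS)
spiked at a known level, assuming a unit response factor:

    C_analyte (mg/kg) = A_analyte / A_IS * C_IS

Retention indices use the linear (temperature-programmed, van den Dool &
Kratz) convention on an n-alkane ladder:

    RI(t) = 100 * (n + (t - t_n) / (t_{n+1} - t_n))      t_n <= t <= t_{n+1}

Compounds eluting outside the ladder span get a below-/above-range marker
instead of an extrapolated number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .table_io import SampleTable

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import PeakTable


@dataclass
class QuantConfig:
    """Semi-quantification settings.

    c_is
        Internal-standard concentration in mg/kg (default 1, the spiking
        level of the reference protocol).
    ladder
        Optional alkane ladder as (carbon, rt_min) rows for retention
        indexing.
    """

    c_is: float = 1.0
    ladder: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.c_is <= 0:
            raise ValueError("c_is must be positive")


def semi_quantify(peaks: "PeakTable", c_is: float = 1.0) -> pd.Series:
    """Convert one run's peak areas to mg/kg relative to the IS area.

    Returns a Series indexed by compound. Raises ``ValueError`` when the
    internal-standard area is non-positive (the ratio is undefined).
    """
    if peaks.is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if (peaks.df["area"] < 0).any():
        raise ValueError("negative peak area")
    conc = peaks.df["area"].to_numpy(dtype=float) / peaks.is_area * c_is
    return pd.Series(conc, index=peaks.df["compound"].to_numpy(), name="conc_mg_kg")


def average_duplicates(runs: Iterable["PeakTable"], c_is: float = 1.0) -> SampleTable:
    """Quantify each run, then average runs per sample (arithmetic mean).

    Compounds absent from a run contribute 0 to that run. Each sample needs
    at least one run; group labels are carried through from the peak tables.
    """
    per_sample: dict[str, list[pd.Series]] = {}
    groups: dict[str, str] = {}
    for run in runs:
        per_sample.setdefault(run.sample_id, []).append(semi_quantify(run, c_is))
        groups[run.sample_id] = run.group
    if not per_sample:
        raise ValueError("no runs supplied")
    all_compounds: list[str] = []
    for series_list in per_sample.values():
        for s in series_list:
            for c in s.index:
                if c not in all_compounds:
                    all_compounds.append(c)
    rows = {}
    for sid, series_list in per_sample.items():
        stacked = pd.DataFrame(
            [s.reindex(all_compounds).fillna(0.0) for s in series_list]
        )
        rows[sid] = stacked.mean(axis=0)
    df = pd.DataFrame(rows).T
    df.insert(0, "group", [groups[sid] for sid in df.index])
    df.index.name = "sample_id"
    return SampleTable(df)


@dataclass(frozen=True)
class RetentionIndex:
    """A retention index, or an out-of-ladder-range marker.

    ``value`` holds the unrounded index when in range, ``marker`` holds the
    printable out-of-range form ("<800", ">2000") otherwise.
    """

    value: float | None = None
    marker: str | None = None

    @property
    def in_range(self) -> bool:
        return self.value is not None

    @property
    def rounded(self) -> int | None:
        """Integer index for reporting (half-up), None when out of range."""
        if self.value is None:
            return None
        return int(math.floor(self.value + 0.5))

    def __str__(self) -> str:
        return self.marker if self.marker is not None else str(self.rounded)


def _ladder_arrays(ladder: pd.DataFrame | Sequence[tuple[int, float]]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ladder, pd.DataFrame):
        carbons = ladder["carbon"].to_numpy(dtype=float)
        rts = ladder["rt_min"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(ladder), dtype=float)
        carbons, rts = arr[:, 0], arr[:, 1]
    if len(carbons) < 2:
        raise ValueError("ladder must span at least two alkanes")
    if not (np.diff(rts) > 0).all() or not (np.diff(carbons) > 0).all():
        raise ValueError("alkane ladder must be strictly increasing")
    return carbons, rts


def retention_index(
    rt: float, ladder: pd.DataFrame | Sequence[tuple[int, float]]
) -> RetentionIndex:
    """Linear retention index of a peak at ``rt`` minutes on an alkane ladder."""
    carbons, rts = _ladder_arrays(ladder)
    if rt < rts[0]:
        return RetentionIndex(marker=f"<{100 * carbons[0]:.0f}")
    if rt > rts[-1]:
        return RetentionIndex(marker=f">{100 * carbons[-1]:.0f}")
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(i, len(rts) - 2)
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    value = 100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i]))
    return RetentionIndex(value=value)
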