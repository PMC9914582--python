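"""Data model and CSV I/O for honey volatilome tables.

Three tabular objects flow through the analysis:

* :class:`GroupSummaryTable` — per-compound, per-group mean/SD concentrations
  (mg/kg) together with retention data and the published per-compound F
  statistics. The packaged fixture (41 compounds, five origin groups) is the
  reference summary against which everything downstream is checked.
* :class:`SampleTable` — a samples x compounds concentration matrix with a
  group label per sample; the central exchange object between stages.
* plain CSV reports written by :func:`write_report`.

Concentrations printed as "nd" (not detected) are stored as exactly 0 with
SD 0; retention indices printed as "<800" are kept as a below-range flag
rather than a number.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Origin groups, in fixture column order. "Nectar" is the mixed
#: flower/thyme ("other nectar honey") validation group from Greece.
GROUPS: tuple[str, ...] = ("Egypt", "Morocco", "Greece", "Spain", "Nectar")

#: Number of honey samples per origin group in the reference study design.
GROUP_SIZES: dict[str, int] = {
    "Egypt": 7,
    "Morocco": 6,
    "Greece": 17,
    "Spain": 8,
    "Nectar": 6,
}

COMPOUND_CLASSES = frozenset(
    {"alcohol", "aldehyde", "ester", "ether", "hydrocarbon", "ketone", "phenolic", "terpene"}
)

SIG_CODES = ("ns", "*", "**", "***")

#: Published total semi-quantitative volatile content (mg/kg) per group.
PRINTED_TSQVC: dict[str, float] = {
    "Egypt": 1.07,
    "Morocco": 1.33,
    "Greece": 1.33,
    "Spain": 0.87,
    "Nectar": 1.05,
}

#: Published marker-ratio index per group with its group-difference letter.
PRINTED_R: dict[str, tuple[float, str]] = {
    "Egypt": (0.35, "a"),
    "Morocco": (0.29, "b"),
    "Greece": (0.04, "c"),
    "Spain": (0.27, "d"),
    "Nectar": (0.08, "e"),
}

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Canonical compound-name key: whitespace collapsed, case folded."""
    return _WS.sub(" ", name.strip()).casefold()


class TableIntegrityError(ValueError):
    """Raised when a summary table violates its structural invariants."""


@dataclass(frozen=True)
class CompoundRecord:
    """One volatile compound: identity, chemical class and retention data.

    ``ri`` is the experimental retention index; compounds eluting before the
    first ladder alkane carry ``ri=None`` with ``ri_below_range=True``
    (printed "<800" in the reference table).
    """

    name: str
    compound_class: str
    rt_min: float
    ri: float | None = None
    ri_below_range: bool = False
    f_value: float | None = None
    sig_code: str | None = None

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise TableIntegrityError(f"{self.name}: retention time must be positive")
        if self.compound_class not in COMPOUND_CLASSES:
            raise TableIntegrityError(
                f"{self.name}: unknown compound class {self.compound_class!r}"
            )
        if self.sig_code is not None and self.sig_code not in SIG_CODES:
            raise TableIntegrityError(f"{self.name}: bad significance code {self.sig_code!r}")
        if self.ri is not None and self.ri_below_range:
            raise TableIntegrityError(f"{self.name}: ri and below-range flag are exclusive")


@dataclass
class GroupSummaryTable:
    """Per-compound, per-group concentration summary (means and SDs, mg/kg).

    ``mean`` and ``sd`` are DataFrames indexed by compound name with one
    column per group; ``n`` gives group sizes. A mean of 0 with SD 0 encodes
    a compound not detected in that group.
    """

    compounds: list[CompoundRecord]
    mean: pd.DataFrame
    sd: pd.DataFrame
    n: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers -------------------------------------------------
    @property
    def groups(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def compound_names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def record(self, name: str) -> CompoundRecord:
        key = normalize_name(name)
        for c in self.compounds:
            if normalize_name(c.name) == key:
                return c
        raise KeyError(name)

    def resolve(self, name: str) -> str:
        """Map a loosely written compound name onto the table's exact string."""
        return self.record(name).name

    def validate(self) -> None:
        names = self.compound_names
        for row, name in enumerate(names):
            if names.index(name) != row:
                raise TableIntegrityError(f"row {row}: duplicate compound {name!r}")
        if list(self.mean.index) != names or list(self.sd.index) != names:
            raise TableIntegrityError("mean/sd index does not match compound list")
        if list(self.mean.columns) != list(self.sd.columns):
            raise TableIntegrityError("mean and sd carry different group sets")
        for g in self.mean.columns:
            if g not in self.n or self.n[g] < 1:
                raise TableIntegrityError(f"group {g!r}: missing or non-positive size")
        bad = (self.mean < 0) | (self.sd < 0)
        if bad.to_numpy().any():
            name = self.mean.index[bad.any(axis=1)][0]
            raise TableIntegrityError(f"negative concentration summary for {name!r}")

    # -- round-trip ------------------------------------------------------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = pd.DataFrame(
            {
                "compound": self.compound_names,
                "compound_class": [c.compound_class for c in self.compounds],
                "rt_min": [c.rt_min for c in self.compounds],
                "ri": [
                    "<800" if c.ri_below_range else ("" if c.ri is None else f"{c.ri:g}")
                    for c in self.compounds
                ],
                "f_value": [c.f_value for c in self.compounds],
                "sig_code": [c.sig_code for c in self.compounds],
            }
        )
        for g in self.groups:
            df[f"mean_{g}"] = self.mean[g].to_numpy()
            df[f"sd_{g}"] = self.sd[g].to_numpy()
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path | io.TextIOBase, n: Mapping[str, int] | None = None
    ) -> "GroupSummaryTable":
        df = pd.read_csv(path, dtype={"ri": str})
        groups = [c[len("mean_"):] for c in df.columns if c.startswith("mean_")]
        compounds = []
        for row, rec in enumerate(df.itertuples(index=False)):
            ri_raw = "" if pd.isna(rec.ri) else str(rec.ri).strip()
            below = ri_raw.startswith("<")
            try:
                compounds.append(
                    CompoundRecord(
                        name=str(rec.compound),
                        compound_class=str(rec.compound_class),
                        rt_min=float(rec.rt_min),
                        ri=None if (below or not ri_raw) else float(ri_raw),
                        ri_below_range=below,
                        f_value=None if pd.isna(rec.f_value) else float(rec.f_value),
                        sig_code=None if pd.isna(rec.sig_code) else str(rec.sig_code),
                    )
                )
            except (TableIntegrityError, ValueError) as exc:
                raise TableIntegrityError(f"row {row} ({rec.compound!r}): {exc}") from exc
        names = [c.name for c in compounds]
        mean = pd.DataFrame(
            {g: df[f"mean_{g}"].astype(float).to_numpy() for g in groups}, index=names
        )
        sd = pd.DataFrame(
            {g: df[f"sd_{g}"].astype(float).to_numpy() for g in groups}, index=names
        )
        sizes = dict(n) if n is not None else {g: GROUP_SIZES[g] for g in groups}
        return cls(compounds=compounds, mean=mean, sd=sd, n=sizes)


def load_fixture() -> GroupSummaryTable:
    """Load the packaged reference summary (41 compounds, 5 origin groups)."""
    with resources.files("honeyvola.data").joinpath("reference_summary.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        table = GroupSummaryTable.from_csv(fh)
    if len(table.compounds) != 41:
        raise TableIntegrityError(
            f"fixture corrupted: expected 41 compounds, found {len(table.compounds)}"
        )
    if table.groups != list(GROUPS):
        raise TableIntegrityError(f"fixture corrupted: groups {table.groups}")
    return table


# ---------------------------------------------------------------------------
# SampleTable


@dataclass
class SampleTable:
    """Per-sample compound concentrations (mg/kg) with a group label.

    Wraps a DataFrame indexed by ``sample_id`` whose first column is
    ``group`` and remaining columns are compounds.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.df.columns:
            raise ValueError("sample table needs a 'group' column")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        conc = self.df[self.compounds]
        if (conc.to_numpy(dtype=float) < 0).any():
            bad = conc.columns[(conc < 0).any(axis=0)][0]
            raise ValueError(f"negative concentration in column {bad!r}")

    @property
    def compounds(self) -> list[str]:
        return [c for c in self.df.columns if c != "group"]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.df["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def conc(self) -> pd.DataFrame:
        """Concentration block only (samples x compounds, float)."""
        return self.df[self.compounds].astype(float)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, compounds: Iterable[str]) -> "SampleTable":
        cols = ["group", *compounds]
        return SampleTable(self.df[cols].copy())


def read_sample_table(path: str | Path | io.TextIOBase) -> SampleTable:
    """Read a sample x compound CSV (columns: sample_id, group, compounds...).

    Blank concentration cells are read as 0 with a logged warning; negative
    concentrations and duplicate sample ids raise ``ValueError``.
    """
    df = pd.read_csv(path, index_col="sample_id")
    comp_cols = [c for c in df.columns if c != "group"]
    n_blank = int(df[comp_cols].isna().to_numpy().sum())
    if n_blank:
        logger.warning("read_sample_table: %d blank cells read as 0", n_blank)
        df[comp_cols] = df[comp_cols].fillna(0.0)
    df[comp_cols] = df[comp_cols].astype(float)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path | io.TextIOBase) -> None:
    """Write a SampleTable CSV; floats at 6 significant digits."""
    table.df.to_csv(path, index_label="sample_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Reports


def write_report(result: object, path: str | Path) -> None:
    """Write a deterministic human-readable summary of any stage output.

    Dispatches on the result type; unknown objects fall back to ``repr``.
    ``None`` or an empty collection produces an empty-but-valid report.
    """
    lines = _render_report(result)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _render_report(result: object) -> list[str]:
    # local imports: the report writer sits below every stage module
    from . import discriminant, screening
    from .kn_index import IndexResult

    if result is None or (isinstance(result, (list, tuple, dict)) and not result):
        return ["(empty report)"]
    if isinstance(result, IndexResult):
        lines = ["group,tsqvc_mg_kg,marker_sum_mg_kg,R,letters"]
        for g in result.tsqvc:
            letters = (result.letters or {}).get(g, "")
            lines.append(
                f"{g},{result.tsqvc[g]:.4f},{result.marker_sum[g]:.4f},"
                f"{result.r_rounded[g]:.2f},{letters}"
            )
        return lines
    if isinstance(result, discriminant.LdaModel):
        lines = ["function,eigenvalue,pct_variance,canonical_corr,wilks,chi2,df,p"]
        for k in range(result.n_functions):
            lam, chi2, df, p = result.wilks_chain[k]
            lines.append(
                f"{k + 1},{result.eigenvalues[k]:.6g},{result.pct_variance[k]:.3f},"
                f"{result.canonical_corr[k]:.4f},{lam:.6g},{chi2:.3f},{df},{p:.3g}"
            )
        if result.excluded:
            lines.append("excluded (tolerance): " + ", ".join(result.excluded))
        return lines
    if isinstance(result, discriminant.ConfusionMatrix):
        lines = [f"method: {result.method}  overall_rate: {result.overall_rate:.1f}%"]
        lines.extend(result.counts.to_csv().strip().splitlines())
        return lines
    if isinstance(result, discriminant.PcaResult):
        lines = ["component,eigenvalue,pct_variance,cumulative_pct"]
        for k, ev in enumerate(result.eigenvalues):
            lines.append(
                f"{k + 1},{ev:.6g},{result.pct_variance[k]:.3f},{result.cumulative_pct[k]:.3f}"
            )
        lines.append(f"retained (eigenvalue > 1): {result.retained}")
        return lines
    if isinstance(result, screening.ManovaResult):
        return [
            f"Wilks lambda: {result.wilks_lambda:.6g} "
            f"(F={result.wilks_f:.3f}, df=({result.wilks_df[0]:.0f},{result.wilks_df[1]:.1f}), "
            f"p={result.wilks_p:.3g}, observed power={result.observed_power_wilks:.3f})",
            f"Pillai trace: {result.pillai_trace:.6g} "
            f"(F={result.pillai_f:.3f}, df=({result.pillai_df[0]:.0f},{result.pillai_df[1]:.0f}), "
            f"p={result.pillai_p:.3g}, observed power={result.observed_power_pillai:.3f})",
        ]
    if isinstance(result, list) and result and isinstance(result[0], screening.AnovaRow):
        lines = ["compound,f_value,df_between,df_within,p_value,sig_code"]
        for row in result:
            p = "" if row.p_value is None else f"{row.p_value:.6g}"
            lines.append(
                f"{row.compound},{row.f_value:.4g},{row.df_between},{row.df_within},"
                f"{p},{row.sig_code}"
            )
        return lines
    if isinstance(result, SampleTable):
        buf = io.StringIO()
        write_sample_table(result, buf)
        return buf.getvalue().strip().splitlines()
    return [repr(result)]
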