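"""Marker-ratio origin index for honey volatilomes.

The index R of a sample (or group) is the summed semi-quantitative content
of a small set of discriminant marker compounds divided by the total
semi-quantitative volatile content (TSQVC):

    R = sum_{m in markers} C_m / sum_{all compounds} C

R is dimensionless, lies in [0, 1], and is invariant under global rescaling
of all concentrations. The default marker set is the seven compounds with
the highest discrimination power in the reference citrus-honey study (lilac
aldehyde D, dill ether, 2-methylbutanal, heptane, benzaldehyde,
alpha,4-dimethyl-3-cyclohexene-1-acetaldehyde, herboxide isomer II);
model-derived marker selection from a fitted discriminant ranking is
available as an alternative.

Group differences in per-sample R are summarized with compact letter
display: groups whose R distributions are not distinguished by a pairwise
Welch t-test at p < 0.001 share a letter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .table_io import GroupSummaryTable, SampleTable, normalize_name

logger = logging.getLogger(__name__)

#: The seven reference marker compounds, in fixture order of citation.
DEFAULT_MARKERS: tuple[str, ...] = (
    "Lilac aldehyde (isomer IV, D)",
    "Dill ether",
    "2-Methylbutanal",
    "Heptane",
    "Benzaldehyde",
    "α,4-Dimethyl-3-cyclohexene-1-acetaldehyde",
    "Herboxide isomer II",
)


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of marker compounds with its provenance."""

    compounds: tuple[str, ...]
    provenance: str = "reference-default"

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("marker set must be non-empty")

    def resolve(self, table: GroupSummaryTable | SampleTable) -> list[str]:
        """Exact table names for the markers; raises KeyError on a miss."""
        if isinstance(table, GroupSummaryTable):
            return [table.resolve(m) for m in self.compounds]
        lut = {normalize_name(c): c for c in table.compounds}
        out = []
        for m in self.compounds:
            key = normalize_name(m)
            if key not in lut:
                raise KeyError(m)
            out.append(lut[key])
        return out


def default_markers() -> MarkerSet:
    return MarkerSet(DEFAULT_MARKERS, provenance="reference-default")


def tsqvc(conc: Mapping[str, float] | pd.Series) -> float:
    """Total semi-quantitative volatile content: the sum over all compounds."""
    values = np.asarray(list(conc.values()) if isinstance(conc, Mapping) else conc, dtype=float)
    if (values < 0).any():
        raise ValueError("concentrations must be >= 0")
    return float(values.sum())


def select_markers(
    ranking: Sequence[tuple[str, float]], k: int = 7
) -> MarkerSet:
    """Top-k compounds from a discrimination-power ranking.

    The ranking (from :func:`honeyvola.discriminant.discrimination_power`)
    is already sorted with ties broken by table order, so selection is a
    deterministic prefix.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not ranking:
        raise ValueError("empty ranking")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    return MarkerSet(tuple(name for name, _ in ranking[:k]), provenance="top-k-from-model")


@dataclass
class IndexResult:
    """Marker-ratio index per group (and optionally per sample)."""

    markers: MarkerSet
    tsqvc: dict[str, float]
    marker_sum: dict[str, float]
    r_value: dict[str, float]
    per_compound_ratio: pd.DataFrame        # markers x groups
    letters: dict[str, str] | None = None
    untested_groups: list[str] = field(default_factory=list)
    per_sample: pd.DataFrame | None = None  # columns: group, r

    @property
    def r_rounded(self) -> dict[str, float]:
        """R per group rounded half-up to 2 decimals for reporting."""
        return {g: np.floor(v * 100 + 0.5) / 100 for g, v in self.r_value.items()}


def kn_index(
    table: GroupSummaryTable | SampleTable,
    markers: MarkerSet | None = None,
    per_sample: bool = False,
    letters_alpha: float = 0.001,
) -> IndexResult:
    """Compute the marker-ratio index R per group.

    On a :class:`GroupSummaryTable` the index is computed from group means
    (which reproduces the published group values exactly). On a
    :class:`SampleTable` with ``per_sample=True`` R is computed per sample,
    summarized per group by its mean, and group-difference letters are
    assigned by pairwise tests at ``letters_alpha``.
    """
    markers = markers or default_markers()
    if isinstance(table, GroupSummaryTable):
        names = markers.resolve(table)
        totals = {g: float(table.mean[g].sum()) for g in table.groups}
        for g, t in totals.items():
            if t <= 0:
                raise ValueError(f"group {g!r}: TSQVC is 0, ratio undefined")
        msum = {g: float(table.mean.loc[names, g].sum()) for g in table.groups}
        ratio = pd.DataFrame(
            {g: table.mean.loc[names, g] / totals[g] for g in table.groups}
        )
        return IndexResult(
            markers=markers,
            tsqvc=totals,
            marker_sum=msum,
            r_value={g: msum[g] / totals[g] for g in table.groups},
            per_compound_ratio=ratio,
        )

    names = markers.resolve(table)
    conc = table.conc
    totals_s = conc.sum(axis=1)
    if (totals_s <= 0).any():
        bad = totals_s.index[totals_s <= 0][0]
        raise ValueError(f"sample {bad!r}: TSQVC is 0, ratio undefined")
    r_s = conc[names].sum(axis=1) / totals_s
    per = pd.DataFrame({"group": table.df["group"], "r": r_s})
    groups = table.groups
    gmean = {g: float(per.loc[per["group"] == g, "r"].mean()) for g in groups}
    tsq = {g: float(totals_s[per["group"] == g].mean()) for g in groups}
    msum = {g: float(conc.loc[per["group"] == g, names].sum(axis=1).mean()) for g in groups}
    ratio = pd.DataFrame(
        {g: conc.loc[per["group"] == g, names].mean(axis=0) / tsq[g] for g in groups}
    )
    letters = untested = None
    if per_sample:
        letters, untested = compare_r_across_groups(per, alpha=letters_alpha)
    return IndexResult(
        markers=markers,
        tsqvc=tsq,
        marker_sum=msum,
        r_value=gmean,
        per_compound_ratio=ratio,
        letters=letters,
        untested_groups=untested or [],
        per_sample=per,
    )


def compare_r_across_groups(
    per_sample: pd.DataFrame, alpha: float = 0.001
) -> tuple[dict[str, str], list[str]]:
    """Compact letter display of group differences in per-sample R.

    Pairwise Welch t-tests at ``alpha``; groups not distinguished from each
    other share a letter (letters follow descending group mean R). Groups
    with a single sample cannot be tested: they get their own letter and are
    returned in the untested list.
    """
    groups = list(dict.fromkeys(per_sample["group"]))
    values = {g: per_sample.loc[per_sample["group"] == g, "r"].to_numpy() for g in groups}
    untested = [g for g in groups if len(values[g]) < 2]
    order = sorted(groups, key=lambda g: -float(np.mean(values[g])))

    graph = nx.Graph()
    graph.add_nodes_from(order)
    for a, b in itertools.combinations(order, 2):
        if a in untested or b in untested:
            continue
        va, vb = values[a], values[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0:
            distinct = float(va[0]) != float(vb[0])
        else:
            _, p = stats.ttest_ind(va, vb, equal_var=False)
            distinct = bool(p < alpha)
        if not distinct:
            graph.add_edge(a, b)

    cliques = [frozenset(c) for c in nx.find_cliques(graph)]
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip(_letter_stream(), cliques):
        for g in sorted(clique, key=order.index):
            letters[g] += letter
    for g in untested:
        logger.warning("compare_r_across_groups: group %r has <2 samples, untested", g)
    return letters, untested


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)
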