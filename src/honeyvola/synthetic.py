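"""Synthetic per-sample and per-run data with the structure of the reference study.

The published study reports only group means and SDs (mg/kg) for 41 volatile
compounds across five origin groups (citrus honey from Egypt n=7, Morocco
n=6, Greece n=17, Spain n=8; other nectar honey n=6), with every sample run
in duplicate on the GC-MS. This module generates:

* sample tables — per-group draws around the summary means, independently
  per compound (an optional equicorrelation hook exists for robustness
  checks); cells printed "nd" (mean 0, SD 0) stay exactly 0;
* peak tables — two runs per sample obtained by inverting the
  internal-standard semi-quantification equation, with multiplicative
  between-run noise and a small retention-time jitter;
* the C8-C20 n-alkane ladder anchored at the published octane/nonane
  retention times.

Because many printed SDs equal or exceed their means, an untruncated normal
is infeasible for non-negative concentrations. The default "censored-normal"
model draws Normal(mean, sd) and clamps negatives to 0 (which biases the
realized mean upward — documented, and exactly what downstream robustness
tests want to stress). "truncated-normal" and plain "normal" (no censoring,
for convergence checks) are available alternatives.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .table_io import GROUP_SIZES, GroupSummaryTable, SampleTable

NOISE_MODELS = ("censored-normal", "truncated-normal", "normal")

#: Published retention-time anchors for the first two ladder alkanes (min).
OCTANE_RT = 12.26
NONANE_RT = 14.94


@dataclass
class SimulationConfig:
    """Knobs for the synthetic generator.

    group_sizes
        Samples per group; defaults to the study design (7, 6, 17, 8, 6).
    seed
        Master seed; per-group streams are derived from it so changing one
        group's size never reshuffles the others.
    noise_model
        "censored-normal" (default), "truncated-normal", or "normal".
    duplicate_cv
        Relative SD between duplicate GC-MS runs of the same sample
        (default 0.05, a typical headspace-SPME repeatability).
    is_area
        Internal-standard peak area per run, arbitrary counts.
    c_is
        Internal-standard concentration, mg/kg.
    rt_jitter
        Half-width (min) of the uniform retention-time jitter per peak.
    within_group_corr
        Optional equicorrelation of the latent normals within a group
        (0 = independent compounds, the default).
    """

    group_sizes: dict[str, int] | None = None
    seed: int = 0
    noise_model: str = "censored-normal"
    duplicate_cv: float = 0.05
    is_area: float = 1.0e5
    c_is: float = 1.0
    rt_jitter: float = 0.02
    within_group_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.duplicate_cv < 0:
            raise ValueError("duplicate_cv must be >= 0")
        if self.is_area <= 0:
            raise ValueError("is_area must be positive")
        if self.group_sizes is not None:
            for g, n in self.group_sizes.items():
                if n < 1:
                    raise ValueError(f"group {g!r}: size must be >= 1")
        if not -1.0 / 40 < self.within_group_corr < 1:
            raise ValueError("within_group_corr out of range")

    def sizes(self, summary: GroupSummaryTable) -> dict[str, int]:
        if self.group_sizes is None:
            return {g: summary.n[g] for g in summary.groups}
        for g in self.group_sizes:
            if g not in summary.groups:
                raise ValueError(f"unknown group label {g!r}")
        return dict(self.group_sizes)


@dataclass
class PeakTable:
    """One chromatographic run: per-compound retention time and peak area."""

    sample_id: str
    run: int
    df: pd.DataFrame  # columns: compound, rt_min, area
    is_area: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.is_area <= 0:
            raise ValueError("is_area must be positive")
        if (self.df["area"] < 0).any():
            raise ValueError("negative peak area")
        if (self.df["rt_min"] <= 0).any():
            raise ValueError("non-positive retention time")


def _group_rng(seed: int, group: str, stream: str) -> np.random.Generator:
    # deterministic per-(seed, group, purpose) stream; crc32 keeps entropy < 2^32
    key = zlib.crc32(f"{stream}:{group}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _draw_group(
    mean: np.ndarray,
    sd: np.ndarray,
    n: int,
    rng: np.random.Generator,
    noise_model: str,
    rho: float,
) -> np.ndarray:
    p = mean.size
    if rho != 0.0:
        # equicorrelated latent normals: common factor + idiosyncratic part
        common = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, p))
        z = np.sqrt(rho) * common + np.sqrt(1 - rho) * own
    else:
        z = rng.standard_normal((n, p))
    x = mean + sd * z
    if noise_model == "censored-normal":
        x = np.clip(x, 0.0, None)
    elif noise_model == "truncated-normal":
        positive_sd = sd > 0
        for j in np.nonzero(positive_sd)[0]:
            a = (0.0 - mean[j]) / sd[j]
            x[:, j] = stats.truncnorm.ppf(
                rng.uniform(size=n), a, np.inf, loc=mean[j], scale=sd[j]
            )
    # cells with sd == 0 are exact in every model
    x[:, sd == 0] = mean[sd == 0]
    return x


def simulate_samples(
    summary: GroupSummaryTable, cfg: SimulationConfig | None = None
) -> SampleTable:
    """Draw per-sample concentration vectors around the summary means.

    Cells with mean 0 and SD 0 ("nd") are exactly 0 in every sample; all
    concentrations are >= 0 unless ``noise_model="normal"`` is selected for
    convergence checks (negatives are then kept as drawn but clipped at 0
    only when building peak tables).
    """
    cfg = cfg or SimulationConfig()
    sizes = cfg.sizes(summary)
    names = summary.compound_names
    frames = []
    for g in summary.groups:
        if g not in sizes:
            continue
        n = sizes[g]
        rng = _group_rng(cfg.seed, g, "samples")
        x = _draw_group(
            summary.mean[g].to_numpy(),
            summary.sd[g].to_numpy(),
            n,
            rng,
            cfg.noise_model,
            cfg.within_group_corr,
        )
        df = pd.DataFrame(x, columns=names)
        df.insert(0, "group", g)
        df.index = [f"{g}-{i + 1:02d}" for i in range(n)]
        frames.append(df)
    out = pd.concat(frames)
    out.index.name = "sample_id"
    if cfg.noise_model == "normal":
        # uncensored draws may be negative; bypass SampleTable's guard by
        # carrying them through a plain frame wrapper
        table = SampleTable.__new__(SampleTable)
        table.df = out
        return table
    return SampleTable(out)


def simulate_peaks(
    samples: SampleTable,
    summary: GroupSummaryTable,
    cfg: SimulationConfig | None = None,
) -> list[PeakTable]:
    """Invert the IS semi-quantification to per-run peak tables, 2 runs/sample.

    Analyte area = conc * is_area / c_is, perturbed multiplicatively with
    relative SD ``duplicate_cv`` (log-normal, unit mean); retention times are
    the summary values jittered uniformly by at most ``rt_jitter`` minutes.
    """
    cfg = cfg or SimulationConfig()
    rts = {c.name: c.rt_min for c in summary.compounds}
    for name in samples.compounds:
        if name not in rts:
            raise ValueError(f"compound {name!r} missing from summary (no retention time)")
    sigma = float(np.sqrt(np.log1p(cfg.duplicate_cv**2)))
    out: list[PeakTable] = []
    for g in samples.groups:
        rng = _group_rng(cfg.seed, g, "peaks")
        block = samples.df[samples.df["group"] == g]
        for sid, row in block.iterrows():
            conc = row[samples.compounds].to_numpy(dtype=float).clip(min=0.0)
            base_area = conc * cfg.is_area / cfg.c_is
            for run in (1, 2):
                if cfg.duplicate_cv > 0:
                    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=conc.size)
                else:
                    noise = np.ones_like(conc)
                rt = np.array([rts[c] for c in samples.compounds])
                rt = rt + rng.uniform(-cfg.rt_jitter, cfg.rt_jitter, size=rt.size)
                df = pd.DataFrame(
                    {
                        "compound": samples.compounds,
                        "rt_min": rt,
                        "area": base_area * noise,
                    }
                )
                out.append(
                    PeakTable(
                        sample_id=str(sid), run=run, df=df, is_area=cfg.is_area, group=str(row["group"])
                    )
                )
    return out


def simulate_alkane_ladder(cfg: SimulationConfig | None = None) -> pd.DataFrame:
    """C8-C20 n-alkane ladder (carbon, rt_min), linear in carbon number.

    Anchored at the published octane (12.26 min) and nonane (14.94 min)
    retention times and extended linearly to eicosane.
    """
    carbons = np.arange(8, 21)
    slope = NONANE_RT - OCTANE_RT
    rt = OCTANE_RT + slope * (carbons - 8)
    return pd.DataFrame({"carbon": carbons, "rt_min": rt})
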