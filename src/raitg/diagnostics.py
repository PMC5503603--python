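"""Visual-predictive-check computation and fitted-group summaries.

The VPC simulates replicate cohorts from the fitted population model under
the original trial design (same regimens and observation times), then checks
whether the empirical 10/50/90 Tg percentiles per time bin fall inside the
90% prediction band of the corresponding simulated percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import CohortEngine
from .synthetic_cohort import (
    PARAM_NAMES,
    PatientRecord,
    PopulationParameters,
    sample_individual,
)

__all__ = ["VpcResult", "vpc", "group_summary", "plot_vpc"]


@dataclass
class VpcResult:
    """Binned observed percentiles with simulation-based prediction bands."""

    bin_edges: np.ndarray  # months, length n_bins + 1
    percentiles: tuple  # e.g. (10, 50, 90)
    empirical: np.ndarray  # (n_bins, n_percentiles)
    band_lo: np.ndarray
    band_hi: np.ndarray
    within: np.ndarray  # bool, empirical inside band
    n_obs: np.ndarray  # observations per bin
    merged: np.ndarray  # True where a sparse bin was merged into a neighbor
    n_sim: int
    seed: int

    @property
    def fraction_within(self) -> float:
        return float(self.within.mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi in range(self.empirical.shape[0]):
            for pj, pct in enumerate(self.percentiles):
                rows.append(
                    {
                        "bin_lo": self.bin_edges[bi],
                        "bin_hi": self.bin_edges[bi + 1],
                        "n_obs": int(self.n_obs[bi]),
                        "percentile": pct,
                        "empirical": self.empirical[bi, pj],
                        "band_lo": self.band_lo[bi, pj],
                        "band_hi": self.band_hi[bi, pj],
                        "within": bool(self.within[bi, pj]),
                        "merged": bool(self.merged[bi]),
                    }
                )
        return pd.DataFrame(rows)


def _quantile_bins(times: np.ndarray, n_bins: int, min_count: int):
    """Quantile-based bin edges with sparse bins merged into neighbors.

    Observation times cluster at cycle boundaries, so quantile edges may
    repeat; duplicates are dropped and any bin holding fewer than
    ``min_count`` observations is merged with its smaller neighbor.
    """
    edges = np.unique(np.quantile(times, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        edges = np.array([times.min(), times.max() + 1e-9])
    merged_any = []
    while True:
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, edges.size - 2)
        counts = np.bincount(idx, minlength=edges.size - 1)
        if edges.size <= 2 or counts.min() >= min_count:
            break
        k = int(np.argmin(counts))
        # merge with the smaller neighboring bin
        if k == 0:
            drop = 1
        elif k == counts.size - 1:
            drop = k
        else:
            drop = k if counts[k - 1] <= counts[k + 1] else k + 1
        merged_any.append(edges[drop])
        edges = np.delete(edges, drop)
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    merged = np.zeros(edges.size - 1, dtype=bool)
    for e in merged_any:
        pos = np.clip(np.searchsorted(edges, e, side="right") - 1, 0, edges.size - 2)
        merged[pos] = True
    return edges, idx, counts, merged


def _binned_percentiles(values, idx, n_bins, percentiles):
    out = np.full((n_bins, len(percentiles)), np.nan)
    for bi in range(n_bins):
        sel = idx == bi
        if sel.any():
            out[bi] = np.percentile(values[sel], percentiles)
    return out


def vpc(
    records: list[PatientRecord],
    pop_hat: PopulationParameters,
    n_sim: int = 200,
    seed: int = 0,
    n_bins: int = 8,
    percentiles: tuple = (10, 50, 90),
    band: float = 0.90,
    min_bin_count: int = 5,
) -> VpcResult:
    """Visual predictive check of ``pop_hat`` against a dataset.

    Simulates ``n_sim`` replicate cohorts with the original regimens and
    observation schedules (new individuals, steady-state baselines,
    proportional noise), and compares empirical Tg percentiles per time bin
    with the central ``band`` prediction interval of the simulated
    percentiles.  Deterministic for a fixed seed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile bands")
    rng = np.random.default_rng(seed)
    engine = CohortEngine(records)

    t_all = np.concatenate([rec.obs_times for rec in records])
    y_all = np.concatenate([rec.obs_tg for rec in records])
    edges, idx, counts, merged = _quantile_bins(t_all, n_bins, min_bin_count)
    n_eff = edges.size - 1
    empirical = _binned_percentiles(y_all, idx, n_eff, percentiles)

    obs_mask = engine.obs_mask
    sim_pct = np.empty((n_sim, n_eff, len(percentiles)))
    for s in range(n_sim):
        theta = {name: np.empty(engine.n) for name in PARAM_NAMES}
        for i in range(engine.n):
            ind = sample_individual(pop_hat, rng)
            for name in PARAM_NAMES:
                theta[name][i] = getattr(ind, name)
        f = engine.tg_at_observations(theta, tg0=engine.steady_tg0(theta))
        eps = rng.standard_normal(f.shape)
        y = np.maximum(f * (1.0 + pop_hat.b * eps), 0.0)
        sim_pct[s] = _binned_percentiles(y[obs_mask], idx, n_eff, percentiles)

    tail = (1.0 - band) / 2.0
    band_lo = np.nanquantile(sim_pct, tail, axis=0)
    band_hi = np.nanquantile(sim_pct, 1.0 - tail, axis=0)
    within = (empirical >= band_lo) & (empirical <= band_hi)
    return VpcResult(
        bin_edges=edges,
        percentiles=tuple(percentiles),
        empirical=empirical,
        band_lo=band_lo,
        band_hi=band_hi,
        within=within,
        n_obs=counts,
        merged=merged,
        n_sim=n_sim,
        seed=seed,
    )


def group_summary(fit) -> pd.DataFrame:
    """Five-number summary (plus mean and geometric mean) of EBE doubling
    times per posterior-assigned group.

    Group 1 collects patients with posterior category-1 probability >= 0.5.
    A group with no members yields a flagged, empty row.  Invariant to
    patient ordering.
    """
    if fit.ebe is None:
        raise ValueError("fit carries no empirical-Bayes estimates")
    frame = fit.ebe.sort_values("ID")
    rows = []
    for group in (1, 2):
        td = frame.loc[frame["category"] == group, "Td"].to_numpy()
        if td.size == 0:
            rows.append(
                {
                    "group": group,
                    "n": 0,
                    "empty": True,
                    **{k: np.nan for k in ("min", "q1", "median", "q3", "max", "mean", "geomean")},
                }
            )
            continue
        rows.append(
            {
                "group": group,
                "n": int(td.size),
                "empty": False,
                "min": td.min(),
                "q1": np.percentile(td, 25),
                "median": np.median(td),
                "q3": np.percentile(td, 75),
                "max": td.max(),
                "mean": td.mean(),
                "geomean": math.exp(float(np.mean(np.log(td)))),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def plot_vpc(result: VpcResult, path) -> None:
    """Write a simple VPC figure (bands + empirical percentiles) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = 0.5 * (result.bin_edges[:-1] + result.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = ["#1f77b4", "#d62728", "#1f77b4"]
    for pj, pct in enumerate(result.percentiles):
        ax.fill_between(
            mids, result.band_lo[:, pj], result.band_hi[:, pj], alpha=0.25,
            color=colors[pj % len(colors)], lw=0,
        )
        ax.plot(mids, result.empirical[:, pj], "o-", ms=4,
                color=colors[pj % len(colors)], label=f"{pct}th percentile")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("stimulated Tg (µg/L)")
    ax.set_yscale("log")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
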