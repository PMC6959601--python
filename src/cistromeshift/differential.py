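"""Differential transcription-factor binding from region read counts.

Consensus regions are tested for a change in normalized binding signal between
an induced and a vehicle condition with a moderated t-statistic on log2 counts:
per-region pooled variances are shrunk toward the across-region mean variance
with a prior weight ``d0``, and the t reference distribution gains ``d0``
degrees of freedom. Regions significant at a Benjamini-Hochberg FDR are split
into gained (log2FC > 0) and lost (log2FC < 0) sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "CountMatrix",
    "bh_adjust",
    "classify_sites",
    "size_factors",
    "test_region_differential",
]

CONDITIONS = ("induced", "vehicle")


@dataclass
class CountMatrix:
    """Region x sample read counts with a two-condition sample sheet.

    ``counts`` is indexed by region_id with one integer column per sample;
    ``regions`` carries region_id/chrom/start/end; ``samples`` carries
    sample/condition/replicate with condition in {induced, vehicle}.
    """

    counts: pd.DataFrame = field(repr=False)
    regions: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("region ids must be unique")
        unknown = set(self.samples["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        missing = set(self.samples["sample"]) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples missing from count columns: {sorted(missing)}")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample"]
        return list(sel)

    def swap_conditions(self) -> "CountMatrix":
        """Relabel induced as vehicle and vice versa (for symmetry checks)."""
        samples = self.samples.copy()
        samples["condition"] = samples["condition"].map(
            {"induced": "vehicle", "vehicle": "induced"}
        )
        return CountMatrix(self.counts, self.regions, samples)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        table = pd.read_csv(counts_path, sep="\t")
        meta_cols = ["region_id", "chrom", "start", "end"]
        regions = table[meta_cols].copy()
        counts = table.drop(columns=meta_cols[1:]).set_index("region_id")
        samples = pd.read_csv(samples_path, sep="\t", dtype={"sample": str})
        return cls(counts, regions, samples)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        out = self.regions.merge(
            self.counts, left_on="region_id", right_index=True, validate="1:1"
        )
        out.to_csv(counts_path, sep="\t", index=False)
        self.samples.to_csv(samples_path, sep="\t", index=False)


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    The reference is the per-region geometric mean over regions where every
    sample is nonzero; each sample's factor is the median ratio to it.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be 2-dimensional (regions x samples)")
    if (x.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no region with all-nonzero counts; cannot normalize")
    sub = x[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return factors


def _trigamma_inverse(y: float, n_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (x > 0)."""
    from scipy.special import polygamma

    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(n_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior_variance(
    s2: np.ndarray, df_resid: int
) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) for variance shrinkage.

    Moment-matching on log sample variances: the excess of var(log s2) over
    trigamma(df/2) identifies the prior degrees of freedom; homogeneous true
    variances give d0 -> infinity (returned capped), i.e. full pooling.
    """
    from scipy.special import digamma, polygamma

    cap = 1e6
    pos = s2[s2 > 0]
    if len(pos) < 3:
        return cap, float(s2.mean()) if s2.size else 0.0
    z = np.log(pos)
    e = z - digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    excess = float(np.var(e, ddof=1)) - float(polygamma(1, df_resid / 2.0))
    if excess <= 0:
        return cap, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(excess)
    d0 = min(d0, cap)
    s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s02


def test_region_differential(
    matrix: CountMatrix, d0: float | None = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-region moderated-t contrast of induced vs vehicle log2 counts.

    Each region's pooled variance is shrunk toward a prior variance with
    weight ``d0`` and tested against t with (n1 + n2 - 2 + d0) degrees of
    freedom. With ``d0=None`` the prior (weight and scale) is estimated from
    the data by moment matching, which keeps the null calibrated whether true
    variances are homogeneous or spread; pass a number to fix the prior
    weight (the prior scale is then the across-region mean variance).

    Returns a DataFrame with region_id, chrom, start, end, log2FC
    (induced - vehicle), t, p. Requires >= 2 replicates per condition.
    """
    ind = matrix.condition_samples("induced")
    veh = matrix.condition_samples("vehicle")
    if len(ind) < 2 or len(veh) < 2:
        raise ValueError(
            f"need >=2 replicates per condition, got {len(ind)} induced / "
            f"{len(veh)} vehicle"
        )
    cols = ind + veh
    sf = size_factors(matrix.counts[cols])
    y = np.log2(matrix.counts[cols].to_numpy(dtype=float) / sf + pseudocount)
    y_ind, y_veh = y[:, : len(ind)], y[:, len(ind) :]
    n1, n2 = len(ind), len(veh)
    log2fc = y_ind.mean(axis=1) - y_veh.mean(axis=1)
    df_resid = n1 + n2 - 2
    pooled = (
        y_ind.var(axis=1, ddof=1) * (n1 - 1) + y_veh.var(axis=1, ddof=1) * (n2 - 1)
    ) / df_resid
    if d0 is None:
        d0_used, var_prior = estimate_prior_variance(pooled, df_resid)
    else:
        d0_used, var_prior = float(d0), float(pooled.mean())
    var_mod = (d0_used * var_prior + df_resid * pooled) / (d0_used + df_resid)
    se = np.sqrt(var_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid + d0_used)
    out = matrix.regions.copy()
    out["log2FC"] = log2fc
    out["t"] = t
    out["p"] = p
    return out


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_sites(
    records: pd.DataFrame, alpha: float = 0.05
) -> tuple[PeakSet, PeakSet]:
    """Split tested regions into gained and lost PeakSets at FDR ``alpha``.

    Adds/uses a ``q`` column (computed from ``p`` if absent) and a
    ``direction`` column in {gained, lost, unchanged}, modifying ``records``
    in place; returns (gained, lost).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if "q" not in records.columns:
        records["q"] = bh_adjust(records["p"].to_numpy())
    sig = records["q"].to_numpy() < alpha
    lfc = records["log2FC"].to_numpy()
    direction = np.where(
        sig & (lfc > 0), "gained", np.where(sig & (lfc < 0), "lost", "unchanged")
    )
    records["direction"] = direction

    def _to_peakset(mask: np.ndarray, name: str) -> PeakSet:
        ivs = [
            GenomicInterval(
                row.chrom, int(row.start), int(row.end), name=str(row.region_id)
            )
            for row in records.loc[mask].itertuples()
        ]
        return PeakSet(name, ivs)

    return _to_peakset(direction == "gained", "gained"), _to_peakset(
        direction == "lost", "lost"
    )
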