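"""Target-capture performance metrics and sample-level filters.

Works from pre-tabulated per-sample read counts and run-length depth tables
(the shape produced by standard depth-of-coverage tools), never from BAMs.
The headline metrics are the on-target read proportion p, the fold-increase
of p over an unenriched baseline, and the enrichment factor
EF = p / (L/G) for target size L and genome size G; coverage homogeneity is
summarised by median depth in 10-kb windows tiled over the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_GENOME_SIZE, RegionSet


def on_target_proportion(on_target: int, total: int) -> float:
    """Fraction of reliable reads mapping inside the target region.

    Returns NaN (undefined) when ``total`` is zero.
    """
    if total == 0:
        return float("nan")
    if not (0 <= on_target <= total):
        raise ValueError(f"need 0 <= on_target <= total, got ({on_target}, {total})")
    return on_target / total


def enrichment_factor(
    p: float, target_length: int, genome_size: int = DEFAULT_GENOME_SIZE
) -> float:
    """EF = p / (L/G): 1 means no enrichment over the target's genome share."""
    if not (0 <= p <= 1):
        raise ValueError(f"proportion must be in [0,1], got {p}")
    if not (0 < target_length <= genome_size):
        raise ValueError("need 0 < target_length <= genome_size")
    return p / (target_length / genome_size)


def fold_increase(p_capture: float, p_baseline: float) -> float:
    """Ratio of on-target proportions, capture over unenriched baseline.

    Returns NaN when the baseline proportion is zero.
    """
    if p_baseline == 0:
        return float("nan")
    return p_capture / p_baseline


def tile_windows(regions: RegionSet, window: int = 10_000) -> pd.DataFrame:
    """Tile each region into fixed windows, keeping partial terminal windows.

    The window count is sum over regions of ceil(length / window).
    """
    rows = []
    for r, (s, e) in enumerate(regions.intervals):
        w0 = s
        while w0 < e:
            w1 = min(w0 + window, e)
            rows.append((r, w0, w1))
            w0 = w1
    return pd.DataFrame(rows, columns=["region_idx", "start", "end"])


def expected_window_count(regions: RegionSet, window: int = 10_000) -> int:
    return sum(math.ceil((e - s) / window) for s, e in regions.intervals)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    half = weights.sum() / 2.0
    idx = int(np.searchsorted(cum, half))
    if idx < len(values) and cum[idx] == half and idx + 1 < len(values):
        return float((values[idx] + values[idx + 1]) / 2.0)
    return float(values[min(idx, len(values) - 1)])


def window_medians(
    depths: pd.DataFrame, regions: RegionSet, window: int = 10_000
) -> pd.DataFrame:
    """Per-sample median depth per tiled window.

    ``depths`` is a run-length table (sample_id, start, end, depth) in
    0-based half-open coordinates; bases of a window not covered by any run
    count as depth 0.  Returns one row per window with one column per sample
    plus the window coordinates.
    """
    wins = tile_windows(regions, window)
    samples = list(pd.unique(depths["sample_id"]))
    out = {s: np.zeros(len(wins)) for s in samples}
    for s, sub in depths.groupby("sample_id", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["depth"].to_numpy(dtype=float)
        for wi, (ws, we) in enumerate(zip(wins["start"], wins["end"])):
            ov_s = np.maximum(starts, ws)
            ov_e = np.minimum(ends, we)
            w = (ov_e - ov_s).clip(min=0)
            sel = w > 0
            covered = int(w[sel].sum())
            uncovered = (we - ws) - covered
            v = vals[sel]
            wts = w[sel].astype(float)
            if uncovered > 0:
                v = np.append(v, 0.0)
                wts = np.append(wts, float(uncovered))
            out[s][wi] = _weighted_median(v, wts) if len(v) else 0.0
    return pd.concat([wins, pd.DataFrame(out, index=wins.index)], axis=1)


def median_target_depth(depths: pd.DataFrame, regions: RegionSet) -> pd.Series:
    """Per-sample median depth over the whole target (weighted by run length;
    uncovered target bases count as 0)."""
    L = regions.total_length
    out = {}
    for s, sub in depths.groupby("sample_id", sort=False):
        w = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        v = sub["depth"].to_numpy(dtype=float)
        covered = w.sum()
        if covered < L:
            v = np.append(v, 0.0)
            w = np.append(w, L - covered)
        out[s] = _weighted_median(v, w)
    return pd.Series(out, name="median_depth")


@dataclass
class CaptureMetrics:
    """Per-sample capture QC table plus the windowed-coverage matrix."""

    per_sample: pd.DataFrame
    windows: pd.DataFrame

    def batch_window_means(self, batches: pd.Series) -> pd.DataFrame:
        """Mean of per-sample window medians within each batch."""
        sample_cols = [c for c in self.windows.columns if c in batches.index]
        out = self.windows[["region_idx", "start", "end"]].copy()
        for b in sorted(batches.unique()):
            cols = [s for s in sample_cols if batches[s] == b]
            out[b] = self.windows[cols].mean(axis=1)
        return out


def compute_capture_metrics(
    counts: pd.DataFrame,
    depths: pd.DataFrame,
    regions: RegionSet,
    window: int = 10_000,
    genome_size: int = DEFAULT_GENOME_SIZE,
    baseline_proportion: float | None = None,
) -> CaptureMetrics:
    """Assemble the per-sample QC table.

    ``baseline_proportion`` is the unenriched on-target proportion used for
    the fold-increase; it defaults to the target's genome share L/G (i.e.
    fold-increase defaults to EF).
    """
    L = regions.total_length
    if baseline_proportion is None:
        baseline_proportion = L / genome_size
    per = counts.copy()
    per["on_target_proportion"] = [
        on_target_proportion(o, t)
        for o, t in zip(per["on_target_reads"], per["total_reads"])
    ]
    per["enrichment_factor"] = [
        enrichment_factor(p, L, genome_size) if np.isfinite(p) else float("nan")
        for p in per["on_target_proportion"]
    ]
    per["fold_increase"] = [
        fold_increase(p, baseline_proportion) if np.isfinite(p) else float("nan")
        for p in per["on_target_proportion"]
    ]
    med = median_target_depth(depths, regions)
    per = per.merge(med.rename("median_depth"), left_on="sample_id", right_index=True, how="left")
    per["median_depth"] = per["median_depth"].fillna(0.0)
    per["undefined_metrics"] = ~np.isfinite(per["on_target_proportion"])
    wins = window_medians(depths, regions, window)
    return CaptureMetrics(per_sample=per, windows=wins)


def filter_samples(
    metrics: CaptureMetrics | pd.DataFrame,
    min_median_depth: float = 4.0,
    min_fold_increase: float = 5.0,
    expect_enriched: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the sample-level QC filters.

    A sample is discarded iff its median target depth is strictly below
    ``min_median_depth``, or (for capture libraries) its fold-increase falls
    below ``min_fold_increase`` — the signature of a library that was never
    enriched.  Returns the kept sample ids and a table of every discard
    decision with its reason.
    """
    per = metrics.per_sample if isinstance(metrics, CaptureMetrics) else metrics
    kept, discarded = [], []
    for _, row in per.iterrows():
        reasons = []
        if row["median_depth"] < min_median_depth:
            reasons.append(f"median_depth {row['median_depth']:.2f} < {min_median_depth}")
        if (
            expect_enriched
            and np.isfinite(row.get("fold_increase", np.nan))
            and row["fold_increase"] < min_fold_increase
        ):
            reasons.append(
                f"not enriched: fold_increase {row['fold_increase']:.2f} < {min_fold_increase}"
            )
        if reasons:
            discarded.append((row["sample_id"], "; ".join(reasons)))
        else:
            kept.append(row["sample_id"])
    report = pd.DataFrame(discarded, columns=["sample_id", "reason"])
    return kept, report
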