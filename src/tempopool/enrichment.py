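"""Permutation-based functional-category enrichment of window outliers.

Outlier windows (top 1% of the window PBS distribution by default) are merged
into regions when separated by at most four non-outlier windows, and region
placements are randomly permuted within arms while preserving region lengths.
A category's raw p-value is the proportion of permutations in which at least
as many regions touch that category as observed; each region counts at most
once per category, so clusters of functionally linked paralogs cannot inflate
a category.  An analysis-wide significance threshold is the 5th percentile of
the per-permutation minimum raw p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CategoryMap",
    "merge_outlier_regions",
    "permutation_enrichment",
]


@dataclass
class CategoryMap:
    """Gene-like intervals plus a gene -> categories mapping."""

    genes: pd.DataFrame  # chrom, start, stop, gene
    gene_categories: dict  # gene -> list of category labels

    def categories(self) -> list:
        out = set()
        for cats in self.gene_categories.values():
            out.update(cats)
        return sorted(out)


def merge_outlier_regions(outlier_flags: np.ndarray, max_gap: int = 4) -> list:
    """Merge flagged windows separated by <= max_gap non-outlier windows.

    ``outlier_flags`` is a boolean vector over consecutive windows of one
    arm.  Returns [(start_index, stop_index)] inclusive window-index pairs.
    """
    flags = np.asarray(outlier_flags, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    regions = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - regions[-1][1] - 1 <= max_gap:
            regions[-1][1] = int(i)
        else:
            regions.append([int(i), int(i)])
    return [tuple(r) for r in regions]


def _window_categories(windows: pd.DataFrame, cat_map: CategoryMap) -> dict:
    """Boolean membership vector over windows for each category."""
    cats = cat_map.categories()
    member = {c: np.zeros(len(windows), dtype=bool) for c in cats}
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy()
    w_stop = windows["stop"].to_numpy()
    for g in cat_map.genes.itertuples():
        hit = (w_chrom == g.chrom) & (w_stop >= g.start) & (w_start <= g.stop)
        if not hit.any():
            continue
        for c in cat_map.gene_categories.get(g.gene, []):
            member[c] |= hit
    return member


def _count_hits(member_cum: np.ndarray, starts: np.ndarray, lengths: np.ndarray) -> int:
    """Number of regions overlapping >= 1 member window (cumsum trick)."""
    ends = starts + lengths
    return int(np.sum(member_cum[ends] - member_cum[starts] > 0))


def permutation_enrichment(
    windows: pd.DataFrame,
    cat_map: CategoryMap,
    outlier_quantile: float = 0.99,
    stat: str = "window_pbs",
    max_gap: int = 4,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Category enrichment of merged outlier regions by location permutation.

    Returns a table with per-category observed region counts, raw p-values
    and the analysis-wide threshold (constant column), sorted by raw p.
    Permuted regions are placed uniformly over window starts within the same
    arm, preserving each region's window length.
    """
    if n_perm < 1000:
        warnings.warn("fewer than 1000 permutations gives a coarse threshold")
    rng = np.random.default_rng(seed)
    windows = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    vals = windows[stat].to_numpy()
    thr = np.nanquantile(vals, outlier_quantile)
    flags = vals >= thr

    arms = windows["chrom"].to_numpy()
    arm_names = list(pd.unique(arms))
    arm_slices = {a: np.flatnonzero(arms == a) for a in arm_names}

    # observed regions per arm -> (global_start_index, length)
    obs_regions = []
    for a in arm_names:
        sl = arm_slices[a]
        for lo, hi in merge_outlier_regions(flags[sl], max_gap):
            obs_regions.append((a, sl[0] + lo, hi - lo + 1))

    member = _window_categories(windows, cat_map)
    cats = list(member)
    cum = {c: np.concatenate([[0], np.cumsum(member[c].astype(np.int64))]) for c in cats}

    def count_all(regions) -> dict:
        starts = np.array([s for _, s, _ in regions], dtype=np.int64)
        lengths = np.array([ln for _, _, ln in regions], dtype=np.int64)
        return {c: _count_hits(cum[c], starts, lengths) for c in cats}

    observed = count_all(obs_regions)

    exceed = {c: 0 for c in cats}
    min_p_per_perm = np.empty(n_perm)
    perm_counts = np.empty((n_perm, len(cats)), dtype=np.int64)
    for r in range(n_perm):
        perm = []
        for a, _, length in obs_regions:
            sl = arm_slices[a]
            max_start = len(sl) - length
            if max_start < 0:
                perm.append((a, sl[0], len(sl)))
                continue
            lo = int(rng.integers(0, max_start + 1))
            perm.append((a, sl[0] + lo, length))
        counts = count_all(perm)
        perm_counts[r] = [counts[c] for c in cats]
        for j, c in enumerate(cats):
            if counts[c] >= observed[c]:
                exceed[c] += 1

    raw_p = {c: exceed[c] / n_perm for c in cats}
    # analysis-wide threshold: the raw p each permutation's own counts would
    # have received, minimized across categories, then its 5th percentile
    obs_vec = np.array([observed[c] for c in cats])
    if cats:
        perm_ps = np.empty_like(perm_counts, dtype=float)
        for j in range(len(cats)):
            srt = np.sort(perm_counts[:, j])
            k = n_perm - np.searchsorted(srt, perm_counts[:, j], side="left")
            perm_ps[:, j] = k / n_perm
        min_p_per_perm = perm_ps.min(axis=1)
    else:
        min_p_per_perm[:] = 1.0
    analysis_threshold = float(np.quantile(min_p_per_perm, 0.05))

    out = pd.DataFrame(
        {
            "category": cats,
            "observed_regions": obs_vec,
            "raw_p": [max(raw_p[c], 1.0 / n_perm) for c in cats],
        }
    )
    out["analysis_threshold"] = analysis_threshold
    out["significant"] = out["raw_p"] <= analysis_threshold
    return out.sort_values("raw_p", kind="stable").reset_index(drop=True)
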