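"""Sampling theory for pooled sequencing.

Pool-seq allele frequencies carry two layers of sampling noise: which
individuals contributed DNA to the pool, and which reads were sequenced from
those contributions.  This module provides the occupancy-problem machinery to
quantify the first layer (how many distinct chromosomes underlie ``n_r`` reads
drawn from ``n_c`` equally contributing chromosomes), the Kish effective
sample size for weighted samples, ploidy-weighted combination of pool
frequencies, and the "pseudo-pool" construction that turns a panel of
individually sequenced strains into an in-silico pool.

The number of distinct lineages ``j`` among ``n_r`` reads from ``n_c``
chromosomes follows the classical occupancy distribution

    P(j | n_r, n_c) = n_c! / (n_c - j)! * S(n_r, j) / n_c**n_r

where ``S`` are Stirling numbers of the second kind.  For diploid pools the
chromosome count is ``n_c = 2 * n_e`` with ``n_e`` the effective pool size
(the number of equally contributing diploid individuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoolSample",
    "LineageTable",
    "lineage_pmf",
    "expected_lineages",
    "kish_neff",
    "combine_pools",
    "pseudo_pool",
]

#: Largest read count handled with exact big-integer arithmetic; above this the
#: pmf is evaluated in log space (doubles overflow at 171!, big ints get slow).
EXACT_LIMIT = 200


@dataclass
class PoolSample:
    """Allele counts for one pooled sequencing library.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alt, ref_count,
    alt_count`` (1-based positions).  ``n_eff`` is the effective pool size:
    the number of equally contributing diploid individuals.
    """

    pool_id: str
    season: str
    location: str
    n_flies: int
    n_eff: float
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        if not 1 <= self.n_eff <= self.n_flies:
            raise ValueError(
                f"effective pool size {self.n_eff} outside [1, {self.n_flies}]"
            )
        cov = self.coverage
        if (self.sites["alt_count"] > cov).any() or (self.sites["alt_count"] < 0).any():
            raise ValueError("allele counts must lie in [0, coverage]")

    @property
    def coverage(self) -> np.ndarray:
        return (self.sites["ref_count"] + self.sites["alt_count"]).to_numpy()

    @property
    def n_chromosomes(self) -> int:
        """Chromosome count 2*n_e used in the occupancy model (diploid pool)."""
        return int(round(2 * self.n_eff))

    def frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site; NaN where coverage is zero."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.sites["alt_count"].to_numpy() / cov, np.nan)


# ---------------------------------------------------------------------------
# Occupancy distribution of distinct lineages


@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Row ``S(n, 0..n)`` of Stirling numbers of the second kind (exact ints)."""
    if n == 0:
        return (1,)
    prev = _stirling_row(n - 1)
    row = [0] * (n + 1)
    for j in range(1, n + 1):
        above = prev[j] if j < n else 0
        row[j] = j * above + prev[j - 1]
    return tuple(row)


def _log_stirling_rows(n: int) -> np.ndarray:
    """log S(n, j) for j=0..n via the recurrence in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        jmax = min(m, n)
        j = np.arange(1, jmax + 1)
        with np.errstate(divide="ignore"):
            new[1 : jmax + 1] = np.logaddexp(np.log(j) + row[1 : jmax + 1], row[0:jmax])
        row = new
    return row


def lineage_pmf(n_r: int, n_c: int) -> np.ndarray:
    """Distribution of the number of distinct chromosomes under ``n_r`` reads.

    Returns a vector ``p`` of length ``min(n_r, n_c)`` with ``p[j-1] =
    P(j distinct lineages | n_r reads, n_c chromosomes)``.

    Exact big-integer arithmetic is used up to ``n_r = 200``; beyond that the
    pmf is assembled in log space, keeping the computation overflow-free for
    any practical coverage.
    """
    if n_r < 1 or n_c < 1:
        raise ValueError("n_r and n_c must be positive integers")
    jmax = min(n_r, n_c)
    if n_r <= EXACT_LIMIT:
        srow = _stirling_row(n_r)
        denom = n_c**n_r
        probs = []
        falling = 1
        for j in range(1, jmax + 1):
            falling *= n_c - j + 1  # n_c! / (n_c - j)!
            probs.append(falling * srow[j] / denom)
        out = np.array([float(p) for p in probs])
    else:
        logs = _log_stirling_rows(n_r)
        j = np.arange(1, jmax + 1)
        log_falling = np.cumsum(np.log(n_c - j + 1.0))
        logp = log_falling + logs[1 : jmax + 1] - n_r * math.log(n_c)
        out = np.exp(logp - logp.max())
        out /= out.sum()
    return out


@lru_cache(maxsize=None)
def expected_lineages(n_r: int, n_c: int) -> float:
    """Expected number of distinct chromosomes, E[j] = sum_j j P(j|n_r,n_c)."""
    pmf = lineage_pmf(n_r, n_c)
    return float(np.arange(1, len(pmf) + 1) @ pmf)


@dataclass
class LineageTable:
    """Memoized lookup of expected lineage counts, cacheable as TSV."""

    table: dict = field(default_factory=dict)

    def lookup(self, n_r: int, n_c: int) -> float:
        key = (int(n_r), int(n_c))
        if key not in self.table:
            self.table[key] = expected_lineages(*key)
        return self.table[key]

    def lookup_many(self, n_r: np.ndarray, n_c: int) -> np.ndarray:
        return np.array([self.lookup(r, n_c) if r >= 1 else 0.0 for r in n_r])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r, c, e) for (r, c), e in sorted(self.table.items())],
            columns=["n_reads", "n_chromosomes", "expected_lineages"],
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            {
                (int(r.n_reads), int(r.n_chromosomes)): float(r.expected_lineages)
                for r in df.itertuples()
            }
        )


# ---------------------------------------------------------------------------
# Weighted combination


def kish_neff(weights) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2 of a weighted sample."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or (w < 0).any():
        raise ValueError("weights must be nonnegative and nonempty")
    total = w.sum()
    if total == 0:
        raise ValueError("at least one weight must be positive")
    return float(total**2 / (w**2).sum())


def combine_pools(pools: list[PoolSample], site_index: int) -> float:
    """Effective-pool-size-weighted alt-allele frequency at one site.

    Pools with zero coverage at the site are excluded from the weighting; if
    no pool has coverage the result is NaN (missing, not zero).
    """
    freqs, weights = [], []
    for pool in pools:
        cov = pool.coverage[site_index]
        if cov > 0:
            freqs.append(pool.sites["alt_count"].iloc[site_index] / cov)
            weights.append(pool.n_eff)
    if not freqs:
        return float("nan")
    w = np.asarray(weights, dtype=float)
    return float(np.asarray(freqs) @ (w / w.sum()))


def combine_pool_frequencies(freqs, n_effs) -> float:
    """Ploidy-weighted mean of per-pool frequencies, skipping NaN entries."""
    f = np.asarray(freqs, dtype=float)
    w = np.asarray(n_effs, dtype=float)
    ok = ~np.isnan(f)
    if not ok.any():
        return float("nan")
    w = w[ok]
    return float(f[ok] @ (w / w.sum()))


# ---------------------------------------------------------------------------
# Pseudo-pool construction


def pseudo_pool(panel, seed: int | None = None, pool_id: str = "pseudo") -> PoolSample:
    """Merge a strain panel into one in-silico pool with equalized input.

    Each strain's reads are first thinned so every strain contributes the same
    total number of aligned reads as the shallowest strain (per-read Bernoulli
    thinning, i.e. binomial per-site coverage with hypergeometric allocation
    of alt reads), then all thinned counts are summed into a single pooled
    count table.  Mirrors merging equally downsampled per-strain BAMs.
    """
    if panel.read_depth is None or panel.alt_reads is None:
        raise ValueError("panel carries no read counts; cannot build a pseudo-pool")
    rng = np.random.default_rng(seed)
    totals = panel.read_depth.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every strain must have at least one aligned read")
    target = totals.min()
    ref_out = np.zeros(panel.n_sites, dtype=np.int64)
    alt_out = np.zeros(panel.n_sites, dtype=np.int64)
    for i in range(panel.n_strains):
        frac = target / totals[i]
        depth = panel.read_depth[i]
        alt = panel.alt_reads[i]
        if frac >= 1.0:
            kept, kept_alt = depth, alt
        else:
            kept = rng.binomial(depth, frac)
            kept_alt = rng.hypergeometric(alt, depth - alt, kept)
        alt_out += kept_alt
        ref_out += kept - kept_alt
    sites = panel.sites[["chrom", "pos", "ref", "alt"]].copy()
    sites["ref_count"] = ref_out
    sites["alt_count"] = alt_out
    return PoolSample(
        pool_id=pool_id,
        season="panel",
        location="panel",
        n_flies=panel.n_strains,
        n_eff=float(panel.n_strains),
        sites=sites,
    )
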