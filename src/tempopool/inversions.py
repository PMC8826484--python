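"""Inversion frequency inference and resampling-based difference tests.

Polymorphic inversions are tracked through marker SNPs that are fixed
differences between the inverted and standard arrangements.  In pooled
samples the inversion frequency is the mean inverted-allele frequency over
markers passing a coverage filter; in strain panels each strain is karyotyped
by majority rule over its diploid marker calls.

Seasonal and spatial frequency differences are tested against a resampling
null that replays the dual binomial sampling of pools: inverted chromosomes
into each pool, then reads at each marker at its empirical coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import PoolSample, combine_pool_frequencies

__all__ = [
    "InversionMarkerSet",
    "InversionEstimate",
    "estimate_pool_inversion",
    "karyotype_strain",
    "karyotype_panel",
    "resample_seasonal_test",
    "resample_location_test",
]

MIN_MARKER_COVERAGE = 10


@dataclass
class InversionMarkerSet:
    """Marker SNPs (fixed inverted/standard differences) of one inversion."""

    name: str
    arm: str
    positions: np.ndarray
    inverted_allele: str = "alt"  # which pool allele column is the inverted one

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError(f"duplicate marker positions for {self.name}")


@dataclass
class InversionEstimate:
    name: str
    per_pool: pd.DataFrame  # pool_id, season, location, n_eff, frequency, n_markers
    seasonal: dict = field(default_factory=dict)  # season -> weighted frequency

    def seasonal_difference(self) -> float:
        return abs(self.seasonal.get("fall", np.nan) - self.seasonal.get("spring", np.nan))


def _marker_rows(pool: PoolSample, markers: InversionMarkerSet) -> pd.DataFrame:
    sites = pool.sites
    sel = (sites["chrom"] == markers.arm) & sites["pos"].isin(markers.positions)
    return sites.loc[sel]


def _marker_cov_freq(pool: PoolSample, markers: InversionMarkerSet) -> tuple[np.ndarray, np.ndarray]:
    rows = _marker_rows(pool, markers)
    cov = (rows["ref_count"] + rows["alt_count"]).to_numpy(dtype=float)
    if markers.inverted_allele in ("alt", "ref"):
        use_alt = np.full(len(rows), markers.inverted_allele == "alt")
    else:  # an explicit base, e.g. from a marker TSV
        use_alt = (rows["alt"] == markers.inverted_allele).to_numpy()
    inv = np.where(
        use_alt,
        rows["alt_count"].to_numpy(dtype=float),
        rows["ref_count"].to_numpy(dtype=float),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov > 0, inv / cov, np.nan)
    return cov, freq


def estimate_pool_inversion(
    pool: PoolSample,
    markers: InversionMarkerSet,
    min_cov: int = MIN_MARKER_COVERAGE,
) -> float:
    """Mean inverted-allele frequency over markers with coverage >= min_cov.

    Returns NaN (with a warning) if no marker passes the filter.
    """
    cov, freq = _marker_cov_freq(pool, markers)
    if cov.size == 0:
        raise ValueError(f"pool {pool.pool_id} has no sites at {markers.name} markers")
    keep = cov >= min_cov
    if not keep.any():
        warnings.warn(
            f"no {markers.name} marker exceeds coverage {min_cov} in pool "
            f"{pool.pool_id}; inversion frequency is missing"
        )
        return float("nan")
    return float(np.nanmean(freq[keep]))


def estimate_inversion(
    pools: list[PoolSample],
    markers: InversionMarkerSet,
    min_cov: int = MIN_MARKER_COVERAGE,
) -> InversionEstimate:
    """Per-pool and n_eff-weighted seasonal inversion frequency estimates."""
    rows = []
    for pool in pools:
        rows.append(
            (
                pool.pool_id,
                pool.season,
                pool.location,
                pool.n_eff,
                estimate_pool_inversion(pool, markers, min_cov),
            )
        )
    per_pool = pd.DataFrame(
        rows, columns=["pool_id", "season", "location", "n_eff", "frequency"]
    )
    seasonal = {}
    for season, grp in per_pool.groupby("season"):
        seasonal[season] = combine_pool_frequencies(
            grp["frequency"].to_numpy(), grp["n_eff"].to_numpy()
        )
    return InversionEstimate(name=markers.name, per_pool=per_pool, seasonal=seasonal)


# ---------------------------------------------------------------------------
# Strain karyotyping


def karyotype_strain(dosages: np.ndarray, ploidy: np.ndarray) -> str:
    """Classify one strain from its marker calls by majority rule.

    ``dosages`` are inverted-allele dosages at the markers, ``ploidy`` the
    callable copies (0 = missing).  Heterozygous marker calls (dosage 1 of 2)
    vote "inverted-heterozygous"; homozygous-standard calls (dosage 0) vote
    "standard".  Ties are ambiguous and excluded with a warning.
    """
    callable_ = ploidy > 0
    if not callable_.any():
        raise ValueError("no callable marker for this strain")
    het = np.sum((dosages == 1) & (ploidy == 2) & callable_)
    hom_std = np.sum((dosages == 0) & callable_)
    if het > hom_std:
        return "inverted-heterozygous"
    if hom_std > het:
        return "standard"
    warnings.warn("ambiguous karyotype (tied marker votes); strain excluded")
    return "ambiguous"


def karyotype_panel(panel, markers: InversionMarkerSet) -> tuple[np.ndarray, float]:
    """Karyotype every strain; returns (labels, strain-level inversion freq).

    The panel inversion frequency is heterozygote count / (2 x strains),
    ambiguous strains excluded from the numerator but not the denominator of
    the published convention (all genotyped strains).
    """
    sites = panel.sites
    sel = ((sites["chrom"] == markers.arm) & sites["pos"].isin(markers.positions)).to_numpy()
    if not sel.any():
        raise ValueError(f"panel has no sites at {markers.name} markers")
    labels = np.array(
        [
            karyotype_strain(panel.genotypes[i, sel], panel.ploidy[i, sel])
            for i in range(panel.n_strains)
        ]
    )
    freq = float(np.sum(labels == "inverted-heterozygous") / (2 * panel.n_strains))
    return labels, freq


# ---------------------------------------------------------------------------
# Resampling tests


def _pool_setup(pools, markers, min_cov, n_units_diploid):
    """Extract per-pool marker coverages and the chromosome-unit counts."""
    setup = []
    for pool in pools:
        cov, freq = _marker_cov_freq(pool, markers)
        keep = cov >= min_cov
        if not keep.any():
            continue
        n_units = int(round(2 * pool.n_eff)) if n_units_diploid else int(round(pool.n_eff))
        setup.append((pool, cov[keep].astype(int), n_units))
    return setup


def _resample_estimates(setup, f_null, n_reps, rng):
    """Simulated weighted inversion estimates for one pool group.

    Per replicate and pool: chr_inv ~ Binom(n_units, f_null); per marker
    reads_inv ~ Binom(cov_j, chr_inv/n_units); pool estimate is the marker
    mean, and the group estimate the n_eff-weighted mean across pools.
    """
    weights = np.array([pool.n_eff for pool, _, _ in setup])
    weights = weights / weights.sum()
    out = np.zeros(n_reps)
    for w, (pool, covs, n_units) in zip(weights, setup):
        chr_inv = rng.binomial(n_units, f_null, size=n_reps)
        p = chr_inv / n_units
        reads = rng.binomial(covs[None, :], p[:, None])
        out += w * (reads / covs[None, :]).mean(axis=1)
    return out


def resample_seasonal_test(
    fall_pools: list[PoolSample],
    spring_pools: list[PoolSample],
    markers: InversionMarkerSet,
    n_reps: int = 10_000,
    seed: int | None = None,
    min_cov: int = MIN_MARKER_COVERAGE,
    n_units_diploid: bool = False,
) -> tuple[float, float, float]:
    """Test a seasonal inversion frequency difference against sampling noise.

    The null inversion frequency is the midpoint of the two seasonal point
    estimates; sampling of chromosomes and reads is replayed ``n_reps`` times
    and the two-sided p-value is the proportion of replicates whose absolute
    simulated seasonal difference reaches the observed one.

    ``n_units_diploid=False`` draws inverted chromosomes as Binom(n_eff, f)
    (the published notation); set True for Binom(2 n_eff, f).

    Returns (p_value, observed fall frequency, observed spring frequency).
    """
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates gives unstable p-values")
    rng = np.random.default_rng(seed)
    est_fall = estimate_inversion(fall_pools, markers, min_cov).seasonal.get("fall")
    est_spring = estimate_inversion(spring_pools, markers, min_cov).seasonal.get("spring")
    if est_fall is None or est_spring is None or np.isnan(est_fall) or np.isnan(est_spring):
        raise ValueError("both seasons need at least one pool with passing markers")
    observed = abs(est_fall - est_spring)
    f_mid = 0.5 * (est_fall + est_spring)
    setup_fall = _pool_setup(fall_pools, markers, min_cov, n_units_diploid)
    setup_spring = _pool_setup(spring_pools, markers, min_cov, n_units_diploid)
    sim_fall = _resample_estimates(setup_fall, f_mid, n_reps, rng)
    sim_spring = _resample_estimates(setup_spring, f_mid, n_reps, rng)
    p = float(np.mean(np.abs(sim_fall - sim_spring) >= observed))
    return p, float(est_fall), float(est_spring)


def resample_location_test(
    pools: list[PoolSample],
    markers: InversionMarkerSet,
    n_reps: int = 10_000,
    seed: int | None = None,
    min_cov: int = MIN_MARKER_COVERAGE,
    n_units_diploid: bool = False,
) -> tuple[float, pd.Series]:
    """Test spatial inversion differences within one season.

    The statistic is the largest pairwise difference between per-location
    weighted frequencies; the null pools all locations at their n_eff-weighted
    mean frequency.  Returns (p_value, observed per-location frequencies).
    """
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates gives unstable p-values")
    rng = np.random.default_rng(seed)
    by_loc: dict[str, list[PoolSample]] = {}
    for pool in pools:
        by_loc.setdefault(pool.location, []).append(pool)
    if len(by_loc) < 2:
        raise ValueError("location test needs pools from at least two locations")
    loc_freqs = {}
    for loc, loc_pools in by_loc.items():
        freqs = [estimate_pool_inversion(p, markers, min_cov) for p in loc_pools]
        neffs = [p.n_eff for p in loc_pools]
        loc_freqs[loc] = combine_pool_frequencies(freqs, neffs)
    obs_series = pd.Series(loc_freqs)
    vals = obs_series.to_numpy()
    observed = float(np.nanmax(vals) - np.nanmin(vals))
    all_freqs = [estimate_pool_inversion(p, markers, min_cov) for p in pools]
    all_neffs = [p.n_eff for p in pools]
    f_null = combine_pool_frequencies(all_freqs, all_neffs)
    locations = sorted(by_loc)
    sims = np.zeros((len(locations), n_reps))
    for i, loc in enumerate(locations):
        setup = _pool_setup(by_loc[loc], markers, min_cov, n_units_diploid)
        sims[i] = _resample_estimates(setup, f_null, n_reps, rng)
    stat = sims.max(axis=0) - sims.min(axis=0)
    p = float(np.mean(stat >= observed))
    return p, obs_series
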