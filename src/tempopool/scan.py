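"""Three-sample PBS selection scan over diversity-scaled windows.

The population branch statistic isolates allele-frequency differentiation
specific to one focal lineage among three samples:

    T = -log(1 - F_ST),    PBS = (T_of + T_os - T_fs) / 2

with o = old (focal) sample, f = fall pools, s = spring pools.  F_ST is a
Hudson-type estimator with sample-size-corrected within-sample heterozygosity;
window values use the ratio-of-averages form across the SNPs of a window.

Windows are diversity-scaled: each holds a fixed number of non-singleton
SNPs from a reference diversity track, so windows are short where diversity
is high.  Window and max-SNP PBS values receive empirical p-values against a
per-recombination-bin null distribution, outlier regions are delimited by a
stop rule on runs of non-significant windows, and an enrichment-removal
accounting asks how many outlier regions must be excised before low p-values
are no longer over-represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import LineageTable, kish_neff

__all__ = [
    "fst",
    "hudson_components",
    "pbs",
    "weighted_focal_frequencies",
    "delimit_windows",
    "window_pbs_scan",
    "NullDistribution",
    "simulate_null_pbs",
    "assign_pvalues",
    "call_regions",
    "OutlierRegion",
    "enrichment_removal",
    "confirm_snp_outliers",
    "REC_BINS",
]

#: Recombination-rate bins (cM/Mb); windows below the first edge are excluded.
REC_BINS = ((0.5, 1.0), (1.0, 1.5), (1.5, 2.0), (2.0, 3.0), (3.0, np.inf))

FST_CEILING = 1.0 - 1e-6


def rec_bin_label(rate: float) -> str:
    if rate <= REC_BINS[0][0]:
        return "excluded"
    for lo, hi in REC_BINS:
        if lo < rate <= hi:
            return f"({lo},{hi}]"
    return "excluded"


# ---------------------------------------------------------------------------
# F_ST and PBS


def hudson_components(p1, n1, p2, n2):
    """Numerator and denominator of the Hudson F_ST estimator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    Sample sizes may be non-integer effective allele counts; they must exceed
    one.  SNPs monomorphic in both samples give den = 0 and are excluded by
    callers (NaN ratio).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst(p1, n1, p2, n2):
    """Hudson F_ST, clamped into [0, 1-1e-6] for the PBS log transform."""
    num, den = hudson_components(p1, n1, p2, n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(raw, 0.0, FST_CEILING)


def _branch_length(f):
    return -np.log(1.0 - np.minimum(np.asarray(f, dtype=float), FST_CEILING))


def pbs(fst_focal_fall, fst_focal_spring, fst_fall_spring):
    """Population branch statistic of the focal (old) lineage.

    Raw value returned (may be slightly negative); rankings floor at zero.
    """
    t_of = _branch_length(np.maximum(fst_focal_fall, 0.0))
    t_os = _branch_length(np.maximum(fst_focal_spring, 0.0))
    t_fs = _branch_length(np.maximum(fst_fall_spring, 0.0))
    return (t_of + t_os - t_fs) / 2.0


# ---------------------------------------------------------------------------
# Inversion-reweighted focal frequencies


def weighted_focal_frequencies(
    panel,
    target_freqs: dict,
    inversions: list,
) -> pd.DataFrame:
    """Reweight panel chromosome copies to match target inversion frequencies.

    Each chromosome copy on an arm receives the product, over the inversions
    of that arm, of ``f_target/f_panel`` if the copy is inverted and
    ``(1-f_target)/(1-f_panel)`` if standard.  Per-SNP frequency is the
    weight-normalized allele average over callable copies and the effective
    allele count is the Kish effective size of the contributing weights.

    ``target_freqs`` maps inversion name to the frequency to be matched (for
    example the pooled-sample estimate); ``inversions`` lists the marker sets
    (name + arm) of the karyotyped inversions.
    """
    if panel.hap1 is None or panel.hap2 is None:
        raise ValueError("panel must carry phased copies for reweighting")
    n_strains, n_sites = panel.ploidy.shape
    w1 = {}
    w2 = {}
    for inv in inversions:
        name = getattr(inv, "name", inv)
        arm = getattr(inv, "arm", None)
        f_t = target_freqs[name]
        karyo = panel.karyotypes[name]
        f_p = float(np.sum(karyo == 1) / (2 * n_strains))
        if f_p in (0.0, 1.0) and not np.isclose(f_t, f_p):
            raise ValueError(
                f"{name}: panel frequency {f_p} cannot be reweighted to {f_t}"
            )
        std_factor = (1.0 - f_t) / (1.0 - f_p) if f_p < 1.0 else 1.0
        inv_factor = f_t / f_p if f_p > 0.0 else 1.0
        carrier = karyo == 1
        # copy 2 is the inverted chromosome of a carrier
        f1 = np.where(carrier, std_factor, std_factor)
        f2 = np.where(carrier, inv_factor, std_factor)
        w1.setdefault(arm, np.ones(n_strains))
        w2.setdefault(arm, np.ones(n_strains))
        w1[arm] = w1[arm] * f1
        w2[arm] = w2[arm] * f2

    arms = panel.sites["chrom"].to_numpy()
    freq = np.full(n_sites, np.nan)
    neff = np.full(n_sites, np.nan)
    for arm in np.unique(arms):
        cols = np.flatnonzero(arms == arm)
        cw1 = w1.get(arm, np.ones(n_strains))[:, None]
        cw2 = w2.get(arm, np.ones(n_strains))[:, None]
        pl = panel.ploidy[:, cols]
        a1 = panel.hap1[:, cols]
        a2 = panel.hap2[:, cols]
        use1 = (pl >= 1).astype(float)
        use2 = (pl == 2).astype(float)
        wsum = use1 * cw1 + use2 * cw2
        asum = use1 * cw1 * a1 + use2 * cw2 * a2
        wsq = use1 * cw1**2 + use2 * cw2**2
        tot_w = wsum.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[cols] = np.where(tot_w > 0, asum.sum(axis=0) / tot_w, np.nan)
            neff[cols] = np.where(tot_w > 0, tot_w**2 / wsq.sum(axis=0), np.nan)
    out = panel.sites[["chrom", "pos"]].copy()
    out["freq"] = freq
    out["neff"] = neff
    return out


# ---------------------------------------------------------------------------
# Window delimitation and the scan


def delimit_windows(
    diversity_track: pd.DataFrame,
    recomb_rates: dict,
    snps_per_window: int = 200,
) -> pd.DataFrame:
    """Tile each arm into consecutive blocks of track SNPs.

    ``diversity_track`` has columns chrom, pos (non-singleton reference SNPs);
    ``recomb_rates`` maps arm name to its rate in cM/Mb (scalar per arm).
    Window bounds are 1-based inclusive and tile the arm without overlap: each
    window ends at its last track SNP and the next begins one bp later.  A
    trailing block with fewer than ``snps_per_window`` SNPs is dropped.
    """
    rows = []
    for arm, grp in diversity_track.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        n_win = len(pos) // snps_per_window
        if n_win == 0:
            warnings.warn(f"arm {arm} has fewer than {snps_per_window} track SNPs")
            continue
        start = 1
        for w in range(n_win):
            block = pos[w * snps_per_window : (w + 1) * snps_per_window]
            stop = int(block[-1])
            rate = float(recomb_rates[arm])
            rows.append((arm, start, stop, snps_per_window, rate, rec_bin_label(rate)))
            start = stop + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "stop", "n_snps", "recomb_rate", "rec_bin"]
    )


def window_pbs_scan(
    windows: pd.DataFrame,
    focal: pd.DataFrame,
    fall: pd.DataFrame,
    spring: pd.DataFrame,
) -> pd.DataFrame:
    """Window and max-SNP PBS for every window.

    ``focal``, ``fall`` and ``spring`` are per-SNP tables with columns
    ``chrom, pos, freq, neff`` on a shared site grid.  Window F_ST uses the
    ratio of summed Hudson numerators to summed denominators across the
    window's SNPs (the standard low-bias window estimator); max-SNP PBS is
    the largest per-SNP PBS inside the window.  SNPs monomorphic in all three
    samples are excluded.
    """
    for name, tab in (("fall", fall), ("spring", spring)):
        if len(tab) != len(focal):
            raise ValueError(f"{name} table not aligned with focal table")
    p_o, n_o = focal["freq"].to_numpy(), focal["neff"].to_numpy()
    p_f, n_f = fall["freq"].to_numpy(), fall["neff"].to_numpy()
    p_s, n_s = spring["freq"].to_numpy(), spring["neff"].to_numpy()

    num_of, den_of = hudson_components(p_o, n_o, p_f, n_f)
    num_os, den_os = hudson_components(p_o, n_o, p_s, n_s)
    num_fs, den_fs = hudson_components(p_f, n_f, p_s, n_s)
    snp_pbs = pbs(
        _safe_ratio(num_of, den_of),
        _safe_ratio(num_os, den_os),
        _safe_ratio(num_fs, den_fs),
    )

    chroms = focal["chrom"].to_numpy()
    pos = focal["pos"].to_numpy()
    usable = ~(
        np.isnan(p_o) | np.isnan(p_f) | np.isnan(p_s)
        | ((den_of <= 0) & (den_os <= 0) & (den_fs <= 0))
    )

    out = windows.copy()
    w_pbs = np.full(len(out), np.nan)
    m_pbs = np.full(len(out), np.nan)
    m_pos = np.full(len(out), -1, dtype=np.int64)
    for i, win in enumerate(out.itertuples()):
        sel = usable & (chroms == win.chrom) & (pos >= win.start) & (pos <= win.stop)
        if not sel.any():
            continue
        f_of = _ratio_of_sums(num_of[sel], den_of[sel])
        f_os = _ratio_of_sums(num_os[sel], den_os[sel])
        f_fs = _ratio_of_sums(num_fs[sel], den_fs[sel])
        w_pbs[i] = pbs(f_of, f_os, f_fs)
        inside = snp_pbs[sel]
        if np.isfinite(inside).any():
            k = int(np.nanargmax(inside))
            m_pbs[i] = inside[k]
            m_pos[i] = pos[sel][k]
    out["window_pbs"] = w_pbs
    out["max_snp_pbs"] = m_pbs
    out["max_snp_pos"] = m_pos
    return out


def _safe_ratio(num, den):
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, 0.0, FST_CEILING)


def _ratio_of_sums(num, den) -> float:
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    if not ok.any():
        return float("nan")
    total = den[ok].sum()
    if total <= 0:
        return float("nan")
    return float(np.clip(num[ok].sum() / total, 0.0, FST_CEILING))


# ---------------------------------------------------------------------------
# Null distributions and empirical p-values


@dataclass
class NullDistribution:
    """Sorted simulated PBS values per recombination bin."""

    window: dict  # bin label -> sorted array
    max_snp: dict

    def replicates(self, bin_label: str) -> int:
        return len(self.window[bin_label])

    @classmethod
    def from_arrays(cls, window_vals, max_snp_vals, bins=None) -> "NullDistribution":
        """Share one simulated set across all bins (a labelled stand-in for
        per-bin coalescent nulls)."""
        labels = bins or [f"({lo},{hi}]" for lo, hi in REC_BINS]
        w = np.sort(np.asarray(window_vals))
        m = np.sort(np.asarray(max_snp_vals))
        return cls({b: w for b in labels}, {b: m for b in labels})


def simulate_null_pbs(
    n_windows: int,
    f0_pool: np.ndarray,
    ne: int,
    generations: int,
    focal_n: float,
    fall_scheme,
    spring_scheme,
    snps_per_window: int = 200,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Wright-Fisher stand-in null for window and max-SNP PBS.

    Start frequencies are resampled from ``f0_pool``; the old sample is a
    binomial draw of ``focal_n`` chromosomes at epoch 1 and the two seasonal
    samples are dual-binomial pool draws from the common epoch-2 frequency.
    This drift-only null omits linkage and demography and is intended as a
    testing stand-in for externally supplied coalescent simulations.
    """
    from .wf import sample_pools, simulate_frequencies

    rng = np.random.default_rng(seed)
    n_snps = n_windows * snps_per_window
    f1 = rng.choice(np.asarray(f0_pool, dtype=float), size=n_snps, replace=True)
    f2 = simulate_frequencies(f1, ne, generations, rng=rng)
    n_focal_chr = int(round(focal_n))
    p_o = rng.binomial(n_focal_chr, f1) / n_focal_chr
    p_f = sample_pools(f2, fall_scheme, rng)
    p_s = sample_pools(f2, spring_scheme, rng)
    n_f = np.full(n_snps, 2.0 * fall_scheme.n_effs.sum())
    n_s = np.full(n_snps, 2.0 * spring_scheme.n_effs.sum())
    n_o = np.full(n_snps, float(focal_n))

    num_of, den_of = hudson_components(p_o, n_o, p_f, n_f)
    num_os, den_os = hudson_components(p_o, n_o, p_s, n_s)
    num_fs, den_fs = hudson_components(p_f, n_f, p_s, n_s)
    snp_pbs = pbs(
        _safe_ratio(num_of, den_of),
        _safe_ratio(num_os, den_os),
        _safe_ratio(num_fs, den_fs),
    )
    shape = (n_windows, snps_per_window)
    w_vals = np.array(
        [
            pbs(
                _ratio_of_sums(num_of.reshape(shape)[w], den_of.reshape(shape)[w]),
                _ratio_of_sums(num_os.reshape(shape)[w], den_os.reshape(shape)[w]),
                _ratio_of_sums(num_fs.reshape(shape)[w], den_fs.reshape(shape)[w]),
            )
            for w in range(n_windows)
        ]
    )
    m_vals = np.nanmax(snp_pbs.reshape(shape), axis=1)
    return w_vals, m_vals


def assign_pvalues(
    windows: pd.DataFrame,
    null: NullDistribution,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical p-values per recombination bin with Bonferroni flags.

    p = (k+1)/(M+1) where k simulated values are strictly greater than the
    observed statistic and M is the replicate count of the window's bin.
    Windows in the excluded (<0.5 cM/Mb) bin are dropped.
    """
    out = windows[windows["rec_bin"] != "excluded"].reset_index(drop=True).copy()
    for col, dist in (("window_pbs", null.window), ("max_snp_pbs", null.max_snp)):
        pcol = "p_window" if col == "window_pbs" else "p_max_snp"
        pvals = np.full(len(out), np.nan)
        for b, grp in out.groupby("rec_bin"):
            if b not in dist:
                raise ValueError(f"null distribution missing recombination bin {b}")
            sims = dist[b]
            m = len(sims)
            obs = grp[col].to_numpy()
            # k = # simulated strictly greater = m - searchsorted(right)
            k = m - np.searchsorted(sims, obs, side="right")
            pvals[grp.index.to_numpy()] = (k + 1) / (m + 1)
        out[pcol] = pvals
    n_windows = len(out)
    out["bonferroni_window"] = out["p_window"] < alpha / n_windows
    out["bonferroni_max_snp"] = out["p_max_snp"] < alpha / n_windows
    return out


# ---------------------------------------------------------------------------
# Outlier regions


@dataclass
class OutlierRegion:
    chrom: str
    start_index: int  # window indices into the (per-scan) window table
    stop_index: int
    seed_index: int
    start: int
    stop: int
    n_windows: int
    peak_stat: float
    peak_p: float
    genes: list = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.stop - self.start + 1


def _extend(p: np.ndarray, seed: int, stop_p: float, stop_run: int) -> tuple[int, int]:
    """Extend from a seed until a run of ``stop_run`` windows with p > stop_p."""
    n = len(p)
    right = seed
    run = 0
    j = seed + 1
    while j < n:
        if p[j] > stop_p or np.isnan(p[j]):
            run += 1
            if run == stop_run:
                break
        else:
            run = 0
            right = j
        j += 1
    left = seed
    run = 0
    j = seed - 1
    while j >= 0:
        if p[j] > stop_p or np.isnan(p[j]):
            run += 1
            if run == stop_run:
                break
        else:
            run = 0
            left = j
        j -= 1
    return left, right


def call_regions(
    windows: pd.DataFrame,
    stat: str = "window",
    seed_p: float = 0.05,
    stop_p: float = 0.1,
    stop_run: int = 10,
    gene_table: pd.DataFrame | None = None,
    gene_margin: int = 10_000,
) -> list[OutlierRegion]:
    """Delimit outlier regions around low-p seed windows.

    Regions are seeded at windows with p < ``seed_p`` and extended in both
    directions until a string of ``stop_run`` consecutive windows with
    p > ``stop_p`` is hit (region edges rest on qualifying windows);
    overlapping regions are merged.  Gene labels within ``gene_margin`` of
    the peak window are attached when a gene table is supplied.
    """
    pcol = "p_window" if stat == "window" else "p_max_snp"
    scol = "window_pbs" if stat == "window" else "max_snp_pbs"
    regions: list[OutlierRegion] = []
    for arm, grp in windows.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        idx = grp.index.to_numpy()
        p = grp[pcol].to_numpy()
        s = grp[scol].to_numpy()
        seeds = np.flatnonzero(p < seed_p)
        intervals: list[list[int]] = []
        for seed in seeds:
            left, right = _extend(p, seed, stop_p, stop_run)
            if intervals and left <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], right)
            else:
                intervals.append([left, right])
        for left, right in intervals:
            inside = slice(left, right + 1)
            peak_local = left + int(np.nanargmin(p[inside]))
            region = OutlierRegion(
                chrom=arm,
                start_index=int(idx[left]),
                stop_index=int(idx[right]),
                seed_index=int(idx[peak_local]),
                start=int(grp["start"].to_numpy()[left]),
                stop=int(grp["stop"].to_numpy()[right]),
                n_windows=right - left + 1,
                peak_stat=float(s[peak_local]),
                peak_p=float(p[peak_local]),
            )
            if gene_table is not None:
                peak_start = int(grp["start"].to_numpy()[peak_local])
                peak_stop = int(grp["stop"].to_numpy()[peak_local])
                near = gene_table[
                    (gene_table["chrom"] == arm)
                    & (gene_table["stop"] >= peak_start - gene_margin)
                    & (gene_table["start"] <= peak_stop + gene_margin)
                ]
                region.genes = list(near["gene"])
            regions.append(region)
    return regions


# ---------------------------------------------------------------------------
# Enrichment-removal accounting


def _imbalance(p: np.ndarray) -> int:
    low = int(np.sum(p < 0.05))
    mid = int(np.sum((p >= 0.05) & (p <= 0.1)))
    return low - mid


def _removal_pass(
    windows: pd.DataFrame,
    pcol: str,
    choose_seed,
    confirm_ok,
    stop_p: float,
    stop_run: int,
) -> tuple[int, int]:
    """Shared machinery: remove regions until low-p bin <= mid-p bin.

    Returns (number of counted regions, total bp removed by counted regions).
    """
    counted = 0
    removed_bp = 0
    arm_of = windows["chrom"].to_numpy()
    start_of = windows["start"].to_numpy()
    stop_of = windows["stop"].to_numpy()
    p = windows[pcol].to_numpy().copy()  # caller sorts by (chrom, start)
    while True:
        active = ~np.isnan(p)
        if _imbalance(p[active]) <= 0:
            break
        seed = choose_seed(p)
        if seed is None:
            break
        arm = arm_of[seed]
        on_arm = np.flatnonzero(arm_of == arm)
        local = np.searchsorted(on_arm, seed)
        left, right = _extend(p[on_arm], local, stop_p, stop_run)
        members = on_arm[left : right + 1]
        if confirm_ok(seed):
            counted += 1
            removed_bp += int(stop_of[members[-1]] - start_of[members[0]] + 1)
        p[members] = np.nan
    return counted, removed_bp


def enrichment_removal(
    windows: pd.DataFrame,
    stat: str = "window",
    mode: str = "deterministic",
    confirm_table: pd.DataFrame | None = None,
    confirm_quantile: float = 0.95,
    n_random_reps: int = 1000,
    seed: int | None = None,
    stop_p: float = 0.1,
    stop_run: int = 10,
) -> tuple[float, float]:
    """How many outlier regions explain the excess of low p-values.

    Regions are excised until the bin of p-values in [0, 0.05) holds no more
    windows than the bin in [0.05, 0.1].  ``mode="deterministic"`` removes
    the lowest-p region first; ``mode="random"`` seeds each removal at a
    uniformly chosen window with p < 0.05 and reports the average count over
    ``n_random_reps`` repetitions.  When a pseudo-pool ``confirm_table`` is
    supplied (same window grid, with the scan statistic columns), a removed
    region is only counted if its seed window is a top-5% outlier there.

    Returns (regions removed, fraction of the scanned genome removed).
    """
    windows = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    pcol = "p_window" if stat == "window" else "p_max_snp"
    scol = "window_pbs" if stat == "window" else "max_snp_pbs"
    genome_bp = int((windows["stop"] - windows["start"] + 1).sum())

    if confirm_table is not None:
        ct = confirm_table.sort_values(["chrom", "start"]).reset_index(drop=True)
        if len(ct) != len(windows) or not (
            (ct["chrom"].to_numpy() == windows["chrom"].to_numpy()).all()
            and (ct["start"].to_numpy() == windows["start"].to_numpy()).all()
        ):
            raise ValueError("confirmation scan is on a different window grid")
        conf_stat = ct[scol].to_numpy()
        threshold = np.nanquantile(conf_stat, confirm_quantile)
        confirmed = conf_stat >= threshold

        def confirm_ok(i: int) -> bool:
            return bool(confirmed[i])

    else:

        def confirm_ok(i: int) -> bool:
            return True

    if mode == "deterministic":

        def choose(p: np.ndarray):
            if np.all(np.isnan(p)):
                return None
            return int(np.nanargmin(p))

        count, bp = _removal_pass(windows, pcol, choose, confirm_ok, stop_p, stop_run)
        return float(count), bp / genome_bp

    if mode == "random":
        rng = np.random.default_rng(seed)
        counts = np.empty(n_random_reps)
        fracs = np.empty(n_random_reps)
        for r in range(n_random_reps):

            def choose(p: np.ndarray):
                cand = np.flatnonzero(p < 0.05)
                if cand.size == 0:
                    return None
                return int(rng.choice(cand))

            c, bp = _removal_pass(windows, pcol, choose, confirm_ok, stop_p, stop_run)
            counts[r] = c
            fracs[r] = bp / genome_bp
        return float(counts.mean()), float(fracs.mean())

    raise ValueError("mode must be 'deterministic' or 'random'")


# ---------------------------------------------------------------------------
# Pseudo-pool cross-confirmation of SNP-level outliers


def confirm_snp_outliers(
    primary: pd.DataFrame,
    pseudo: pd.DataFrame,
    snp_quantile: float = 0.99,
    pseudo_quantile: float = 0.975,
    window_nonoutlier_quantile: float = 0.95,
) -> pd.DataFrame:
    """SNP-level outliers confirmed by the pseudo-pool scan.

    Windows whose max-SNP PBS is in the top 1% of the primary scan AND in the
    top 2.5% of the pseudo-pool scan, while their window PBS stays in the
    bottom 95% of the primary scan.  Quantile thresholds are inclusive at the
    boundary.  Both scans must share the window grid.
    """
    a = primary.sort_values(["chrom", "start"]).reset_index(drop=True)
    b = pseudo.sort_values(["chrom", "start"]).reset_index(drop=True)
    if len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
    ):
        raise ValueError("primary and pseudo-pool scans use different window grids")
    snp_thr = np.nanquantile(a["max_snp_pbs"], snp_quantile)
    pseudo_thr = np.nanquantile(b["max_snp_pbs"], pseudo_quantile)
    win_thr = np.nanquantile(a["window_pbs"], window_nonoutlier_quantile)
    keep = (
        (a["max_snp_pbs"] >= snp_thr)
        & (b["max_snp_pbs"].to_numpy() >= pseudo_thr)
        & (a["window_pbs"] <= win_thr)
    )
    out = a.loc[keep].copy()
    out["pseudo_max_snp_pbs"] = b.loc[keep.to_numpy(), "max_snp_pbs"].to_numpy()
    return out.reset_index(drop=True)
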