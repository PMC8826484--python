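"""Clinal-SNP temporal shift testing, ancestry reweighting, and CNV calling.

Three loosely coupled analyses share this module:

* SNPs with strong latitudinal allele-frequency clines are thinned to one per
  10 kb and tested for a systematic temporal shift of the "northern" allele
  (one-sided binomial test against a 50% null).
* Per-strain ancestry proportions are reweighted so the old panel matches the
  inversion frequencies of the new pooled samples, using the same chromosome
  copy weights as the selection scan.
* A deletion polymorphism is genotyped from depth-of-coverage ratios: strains
  classify bimodally around calibration ratios for intact and deleted
  haplotypes, and the pooled intact-allele frequency follows from the linear
  mixture r_pool = f * r_intact + (1-f) * r_deleted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinalSNPSet",
    "CNVCoverageProfile",
    "thin_clinal_snps",
    "clinal_shift_test",
    "reweight_ancestry",
    "ancestry_relative_decline",
    "cnv_frequency_pool",
    "call_cnv_genotypes",
]


@dataclass
class ClinalSNPSet:
    """Thinned clinal SNPs with old/new frequencies of the northern allele."""

    snps: pd.DataFrame  # chrom, pos, clinal_p, old_freq, new_freq (northern allele)

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class CNVCoverageProfile:
    """Depth-of-coverage summary of a deletion locus.

    ``r_pool`` is pooled focal depth over pooled genome-wide depth;
    ``r_intact``/``r_deleted`` are the calibration ratios measured in strains
    of known genotype.
    """

    r_pool: float
    r_intact: float = 1.2
    r_deleted: float = 0.0676

    def __post_init__(self) -> None:
        if self.r_intact <= self.r_deleted:
            raise ValueError("r_intact must exceed r_deleted")
        if self.r_pool < 0:
            raise ValueError("coverage ratios must be nonnegative")


def thin_clinal_snps(
    snps: pd.DataFrame,
    threshold: float = 0.001,
    min_dist: int = 10_000,
    order: str = "position",
) -> ClinalSNPSet:
    """Keep SNPs with clinal p strictly below ``threshold``, >= min_dist apart.

    ``order="position"`` runs the greedy left-to-right scan per arm (keep a
    SNP iff it lies at least ``min_dist`` from the last kept);
    ``order="significance"`` keeps most-clinal-first instead.
    """
    sel = snps[snps["clinal_p"] < threshold].copy()
    kept_idx = []
    for _, grp in sel.groupby("chrom", sort=True):
        if order == "position":
            grp = grp.sort_values("pos")
            last = -np.inf
            for row in grp.itertuples():
                if row.pos - last >= min_dist:
                    kept_idx.append(row.Index)
                    last = row.pos
        elif order == "significance":
            grp = grp.sort_values("clinal_p")
            taken: list[int] = []
            for row in grp.itertuples():
                if all(abs(row.pos - t) >= min_dist for t in taken):
                    kept_idx.append(row.Index)
                    taken.append(row.pos)
        else:
            raise ValueError("order must be 'position' or 'significance'")
    out = sel.loc[kept_idx].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return ClinalSNPSet(out)


def clinal_shift_test(snp_set: ClinalSNPSet) -> tuple[float, int, float]:
    """Temporal shift of northern-associated alleles.

    Returns (mean shift, number of SNPs whose northern allele increased,
    one-sided binomial tail probability of at least that many increases under
    a 50% null).  SNPs with exactly zero shift are excluded from the tally.
    """
    if len(snp_set) == 0:
        raise ValueError("empty clinal SNP set")
    shift = (snp_set.snps["new_freq"] - snp_set.snps["old_freq"]).to_numpy()
    mean_shift = float(np.mean(shift))
    nonzero = shift != 0.0
    n_trials = int(nonzero.sum())
    n_up = int(np.sum(shift > 0.0))
    if n_trials == 0:
        return mean_shift, 0, float("nan")
    p = float(stats.binomtest(n_up, n_trials, 0.5, alternative="greater").pvalue)
    return mean_shift, n_up, p


def _strain_weights(karyotypes: dict, panel_freqs: dict, target_freqs: dict) -> np.ndarray:
    """Mean chromosome-copy weight per strain under inversion matching.

    A heterozygous carrier has one inverted copy (weight f_t/f_p) and one
    standard copy (weight (1-f_t)/(1-f_p)); a non-carrier has two standard
    copies.  Weights multiply across inversions.
    """
    names = list(karyotypes)
    n = len(karyotypes[names[0]])
    w = np.ones(n)
    for name in names:
        f_p = panel_freqs[name]
        f_t = target_freqs[name]
        if f_p in (0.0, 1.0) and not np.isclose(f_t, f_p):
            raise ValueError(f"{name}: panel frequency {f_p} cannot be reweighted")
        std = (1.0 - f_t) / (1.0 - f_p) if f_p < 1.0 else 1.0
        inv = f_t / f_p if f_p > 0.0 else 1.0
        carrier = np.asarray(karyotypes[name]) == 1
        w = w * np.where(carrier, 0.5 * (inv + std), std)
    return w


def reweight_ancestry(
    ancestry: np.ndarray,
    karyotypes: dict,
    target_freqs: dict,
    panel_freqs: dict | None = None,
) -> float:
    """Inversion-matched weighted mean of per-strain ancestry proportions.

    ``karyotypes`` maps inversion name to a 0/1 carrier vector over strains;
    ``target_freqs`` the pooled-sample inversion frequencies to match.  Panel
    frequencies default to carrier_count / (2 * strains).
    """
    ancestry = np.asarray(ancestry, dtype=float)
    if panel_freqs is None:
        panel_freqs = {
            name: float(np.sum(np.asarray(k) == 1) / (2 * len(ancestry)))
            for name, k in karyotypes.items()
        }
    w = _strain_weights(karyotypes, panel_freqs, target_freqs)
    return float(np.sum(w * ancestry) / np.sum(w))


def ancestry_relative_decline(old_mean: float, new_mean: float) -> float:
    """Relative loss of ancestry between time points, (old - new) / old."""
    if old_mean <= 0:
        raise ValueError("old ancestry mean must be positive")
    return (old_mean - new_mean) / old_mean


def cnv_frequency_pool(profile: CNVCoverageProfile) -> float:
    """Intact-allele frequency from the pooled coverage ratio.

    Inverts the mixture r_pool = f * r_intact + (1-f) * r_deleted:
    f = (r_pool - r_deleted) / (r_intact - r_deleted), clamped to [0, 1].
    """
    f = (profile.r_pool - profile.r_deleted) / (profile.r_intact - profile.r_deleted)
    return float(np.clip(f, 0.0, 1.0))


def call_cnv_genotypes(
    ratios: np.ndarray,
    r_intact: float = 1.2,
    r_deleted: float = 0.0676,
    ambiguous_band: float = 0.0,
    collection_year: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Classify strains as intact (1) or deleted (0) from coverage ratios.

    The decision boundary is the midpoint of the calibration ratios on the
    log scale, sqrt(r_intact * r_deleted); ratios within ``ambiguous_band``
    log10-units of the boundary are flagged uncalled (-1).  When collection
    years are given, a per-year count table (year, n, k) suitable for the
    exact-match ABC is also returned.
    """
    if r_intact <= r_deleted:
        raise ValueError("r_intact must exceed r_deleted")
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("coverage ratios must be positive")
    boundary = np.sqrt(r_intact * r_deleted)
    calls = np.where(ratios > boundary, 1, 0).astype(np.int8)
    if ambiguous_band > 0:
        near = np.abs(np.log10(ratios) - np.log10(boundary)) < ambiguous_band
        calls[near] = -1
    table = None
    if collection_year is not None:
        rows = []
        for year in sorted(set(int(y) for y in collection_year)):
            sel = (np.asarray(collection_year) == year) & (calls >= 0)
            rows.append((year, int(sel.sum()), int(calls[sel].sum())))
        table = pd.DataFrame(rows, columns=["year", "n", "k"])
    return calls, table
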