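"""Synthetic two-epoch population data with known ground truth.

Emulates every input the pipeline consumes: an old panel of partially inbred
isofemale strains sampled at epoch 1, pooled seasonal samples at epoch 2
separated by decades of Wright-Fisher drift (with optional selected loci),
polymorphic inversions tagged by fixed marker SNPs, a copy-number locus
observable only through depth of coverage, clinal-SNP annotations, a
diversity track for window delimitation, and gene/category maps.

Every latent value (local Ne, selection coefficients, inversion frequencies,
shifted SNP ids) is recorded in a truth dictionary so downstream estimators
can be validated against planted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pool import PoolSample
from .wf import simulate_frequencies, _select

__all__ = [
    "ChromArm",
    "InversionDef",
    "CNVLocus",
    "SimWorld",
    "StrainPanel",
    "GeneratedDataset",
    "generate_dataset",
    "generate_isofemale_panel",
    "default_world",
]

EPOCH2_SEASONS = ("fall", "spring")


@dataclass
class ChromArm:
    name: str
    length: int
    recomb_rate: float  # cM/Mb


@dataclass
class InversionDef:
    name: str
    arm: str
    marker_positions: np.ndarray
    freqs: dict  # epoch label ('old'|'fall'|'spring') -> true frequency

    def __post_init__(self) -> None:
        self.marker_positions = np.asarray(self.marker_positions, dtype=np.int64)
        if len(np.unique(self.marker_positions)) != len(self.marker_positions):
            raise ValueError(f"duplicate marker positions for {self.name}")
        for f in self.freqs.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"inversion frequency {f} outside [0,1]")


@dataclass
class CNVLocus:
    arm: str
    start: int
    stop: int
    intact_freq_by_year: dict  # collection year -> intact-allele frequency (old epoch)
    intact_freq_new: float
    r_intact: float = 1.2
    r_deleted: float = 0.0676


@dataclass
class SimWorld:
    """Full description of the simulated system (all latent truth)."""

    chrom_arms: list
    n_snps: int
    seed: int
    ancestral_freqs: np.ndarray | None = None
    selected_loci: list = field(default_factory=list)  # (snp_index, s, f0)
    cnv_locus: CNVLocus | None = None
    inversion_defs: list = field(default_factory=list)
    clinal_fraction: float = 0.03
    clinal_shift: float = 0.0244
    n_strains: int = 64
    het_fraction: float = 0.326
    het_tract_mean: float = 500_000.0
    fall_pools: int = 6
    spring_pools: int = 12
    fall_flies: int = 41
    spring_flies: int = 34
    fall_neffs: tuple = (41, 41, 41, 41, 41, 10)
    spring_neff: float = 31.0
    fall_coverage: float = 64.0
    spring_coverage: float = 16.0
    locations: tuple = ("L1", "L2", "L3", "L4", "L5")
    allow_inversion_homozygotes: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        arms = {a.name: a for a in self.chrom_arms}
        for inv in self.inversion_defs:
            if inv.arm not in arms:
                raise ValueError(f"inversion {inv.name} on unknown arm {inv.arm}")
            if (inv.marker_positions > arms[inv.arm].length).any() or (
                inv.marker_positions < 1
            ).any():
                raise ValueError(f"markers of {inv.name} fall off arm {inv.arm}")
        if self.ancestral_freqs is not None:
            f = np.asarray(self.ancestral_freqs, dtype=float)
            if f.size != self.n_snps or (f < 0).any() or (f > 1).any():
                raise ValueError("ancestral_freqs must be n_snps probabilities")
            self.ancestral_freqs = f
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must be in [0,1]")


@dataclass
class StrainPanel:
    """Per-strain genotype calls with ploidy masks and inversion karyotypes.

    ``genotypes[i, j]`` is the alt-allele dosage of strain i at site j among
    its callable copies; ``ploidy[i, j]`` is 1 (inbred/haploid call) or 2
    (residually heterozygous region), 0 for missing.
    """

    strains: list
    sites: pd.DataFrame  # chrom, pos, ref, alt
    genotypes: np.ndarray
    ploidy: np.ndarray
    karyotypes: dict = field(default_factory=dict)  # inversion -> 0/1 per strain
    collection_year: np.ndarray | None = None
    read_depth: np.ndarray | None = None
    alt_reads: np.ndarray | None = None
    cnv_calls: np.ndarray | None = None  # 1 intact / 0 deleted per strain
    # phased copies where known: copy 1 is exposed at haploid tracts; in
    # inversion carriers copy 2 is the inverted chromosome
    hap1: np.ndarray | None = None
    hap2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.genotypes > self.ploidy).any():
            raise ValueError("genotype dosage exceeds ploidy")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def allele_frequencies(self) -> np.ndarray:
        """Alt frequency per site over all callable chromosome copies."""
        called = self.ploidy.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, self.genotypes.sum(axis=0) / called, np.nan)

    def inversion_frequency(self, name: str) -> float:
        """Heterozygote count / (2 x strains), the strain-panel estimate."""
        karyo = self.karyotypes[name]
        return float(np.sum(karyo == 1) / (2 * self.n_strains))


@dataclass
class GeneratedDataset:
    world: SimWorld
    panel: StrainPanel
    pools: list
    diversity_track: pd.DataFrame  # chrom, pos
    truth: dict

    def pools_by_season(self, season: str) -> list:
        return [p for p in self.pools if p.season == season]


# ---------------------------------------------------------------------------


def _site_table(world: SimWorld, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out ordinary SNPs plus injected inversion-marker SNPs."""
    lengths = np.array([a.length for a in world.chrom_arms], dtype=float)
    per_arm = np.maximum(1, np.round(world.n_snps * lengths / lengths.sum())).astype(int)
    # adjust rounding drift on the largest arm
    per_arm[np.argmax(per_arm)] += world.n_snps - per_arm.sum()
    rows = []
    for arm, count in zip(world.chrom_arms, per_arm):
        pos = np.sort(rng.choice(np.arange(1, arm.length + 1), size=count, replace=False))
        for p in pos:
            rows.append((arm.name, int(p), "A", "T", ""))
    for inv in world.inversion_defs:
        for p in inv.marker_positions:
            rows.append((inv.arm, int(p), "A", "T", inv.name))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "marker_of"])
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="last")
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return df


def _het_mask(length: int, het_fraction: float, tract_mean: float,
              rng: np.random.Generator) -> list:
    """Alternating tracts; each tract diploid with probability het_fraction.

    Returns a list of (start, stop, ploidy) tuples covering [1, length],
    tract lengths geometric with the given mean, mimicking the blocky output
    of a heterozygosity HMM on a partially inbred genome.
    """
    tracts = []
    pos = 1
    while pos <= length:
        tract_len = int(rng.geometric(1.0 / tract_mean))
        stop = min(pos + tract_len - 1, length)
        ploidy = 2 if rng.random() < het_fraction else 1
        tracts.append((pos, stop, ploidy))
        pos = stop + 1
    return tracts


def generate_isofemale_panel(
    world: SimWorld,
    n_strains: int | None = None,
    het_fraction: float | None = None,
    rng: np.random.Generator | None = None,
    sites: pd.DataFrame | None = None,
    freqs: np.ndarray | None = None,
) -> StrainPanel:
    """Simulate a panel of isofemale strains sampled at epoch 1.

    Each strain carries two haplotypes drawn from the epoch-1 frequencies.
    Residual heterozygosity is laid out as geometric tracts (mean length
    ``world.het_tract_mean``); inbred tracts expose a single haploid call,
    heterozygous-capable tracts a diploid call.  Inversion carriers are
    simulated as heterozygotes: one haplotype carries the inverted allele at
    every marker of that inversion, and marker sites stay diploid in carriers
    so karyotyping sees heterozygous marker calls.
    """
    if n_strains is None:
        n_strains = world.n_strains
    if het_fraction is None:
        het_fraction = world.het_fraction
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0,1]")
    if n_strains < 2:
        raise ValueError("need at least two strains")
    if rng is None:
        rng = np.random.default_rng(world.seed)
    if sites is None:
        sites = _site_table(world, rng)
    if freqs is None:
        freqs = _epoch1_site_freqs(world, sites)

    n_sites = len(sites)
    arm_of = sites["chrom"].to_numpy()
    pos_of = sites["pos"].to_numpy()
    marker_of = sites["marker_of"].to_numpy()
    hap1 = (rng.random((n_strains, n_sites)) < freqs).astype(np.int8)
    hap2 = (rng.random((n_strains, n_sites)) < freqs).astype(np.int8)

    karyotypes = {}
    for inv in world.inversion_defs:
        f = inv.freqs.get("old", 0.0)
        p_het = min(1.0, 2.0 * f) if not world.allow_inversion_homozygotes else 2 * f * (1 - f)
        carrier = (rng.random(n_strains) < p_het).astype(np.int8)
        karyotypes[inv.name] = carrier
        is_marker = marker_of == inv.name
        # fixed differences between arrangements
        hap1[:, is_marker] = 0
        hap2[:, is_marker] = np.where(carrier[:, None] == 1, 1, 0)

    ploidy = np.ones((n_strains, n_sites), dtype=np.int8)
    for i in range(n_strains):
        for arm in world.chrom_arms:
            on_arm = np.flatnonzero(arm_of == arm.name)
            if on_arm.size == 0:
                continue
            arm_pos = pos_of[on_arm]
            for start, stop, pl in _het_mask(arm.length, het_fraction,
                                             world.het_tract_mean, rng):
                if pl == 2:
                    sel = on_arm[(arm_pos >= start) & (arm_pos <= stop)]
                    ploidy[i, sel] = 2
    # carriers stay heterozygous across marker sites regardless of the mask
    if world.inversion_defs:
        for inv in world.inversion_defs:
            is_marker = marker_of == inv.name
            carriers = karyotypes[inv.name] == 1
            ploidy[np.ix_(carriers, is_marker)] = 2

    # the exposed copy at inbred (haploid) tracts is haplotype 1 by convention
    genotypes = np.where(ploidy == 2, hap1 + hap2, hap1).astype(np.int8)

    mean_depth = rng.uniform(5.0, 40.0, size=n_strains)
    read_depth = rng.poisson(mean_depth[:, None], size=(n_strains, n_sites)) + 1
    with np.errstate(invalid="ignore"):
        p_alt = genotypes / np.maximum(ploidy, 1)
    alt_reads = rng.binomial(read_depth, p_alt)

    collection_year = None
    cnv_calls = None
    if world.cnv_locus is not None:
        years = sorted(world.cnv_locus.intact_freq_by_year)
        collection_year = np.sort(rng.choice(years, size=n_strains, replace=True))
        cnv_calls = np.zeros(n_strains, dtype=np.int8)
        for i, yr in enumerate(collection_year):
            cnv_calls[i] = rng.random() < world.cnv_locus.intact_freq_by_year[yr]

    return StrainPanel(
        strains=[f"RI_{i:03d}" for i in range(n_strains)],
        sites=sites,
        genotypes=genotypes,
        ploidy=ploidy,
        karyotypes=karyotypes,
        collection_year=collection_year,
        read_depth=read_depth,
        alt_reads=alt_reads,
        cnv_calls=cnv_calls,
        hap1=hap1,
        hap2=hap2,
    )


def _epoch1_site_freqs(world: SimWorld, sites: pd.DataFrame) -> np.ndarray:
    """Epoch-1 frequency per site (marker sites get the inversion frequency)."""
    rng = np.random.default_rng(world.seed + 1)
    if world.ancestral_freqs is None:
        # neutral-like SFS: density proportional to 1/f, folded away from fixation
        u = rng.random(world.n_snps)
        freqs = 0.02 * (0.98 / 0.02) ** u  # log-uniform on [0.02, 0.98]
        rng.shuffle(freqs)
    else:
        freqs = world.ancestral_freqs
    out = np.empty(len(sites))
    plain = sites["marker_of"].to_numpy() == ""
    out[plain] = freqs[: plain.sum()]
    for inv in world.inversion_defs:
        out[sites["marker_of"].to_numpy() == inv.name] = inv.freqs.get("old", 0.0)
    return out


def _draw_pool(
    sites: pd.DataFrame,
    freqs: np.ndarray,
    inv_freqs: dict,
    n_flies: int,
    n_eff: float,
    mean_cov: float,
    pool_id: str,
    season: str,
    location: str,
    rng: np.random.Generator,
    n_units_diploid: bool = True,
) -> PoolSample:
    """Dual-binomial pool: chromosomes into the pool, then reads.

    Marker SNPs of one inversion share the pool's drawn count of inverted
    chromosomes, so their read frequencies are correlated as in real pools.
    """
    n_sites = len(sites)
    cov = rng.poisson(mean_cov, size=n_sites) + 1
    n_units = int(round(2 * n_eff)) if n_units_diploid else int(round(n_eff))
    psi = rng.binomial(n_units, freqs)
    marker_of = sites["marker_of"].to_numpy()
    for inv_name, f_inv in inv_freqs.items():
        is_marker = marker_of == inv_name
        if is_marker.any():
            chr_inv = rng.binomial(n_units, f_inv)
            psi[is_marker] = chr_inv
    alt = rng.binomial(cov, psi / n_units)
    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    out["ref_count"] = cov - alt
    out["alt_count"] = alt
    return PoolSample(
        pool_id=pool_id,
        season=season,
        location=location,
        n_flies=n_flies,
        n_eff=n_eff,
        sites=out,
    )


def generate_dataset(
    world: SimWorld,
    ne_local: int,
    years_between: float = 31.0,
    gens_per_year: float = 15.0,
) -> GeneratedDataset:
    """Simulate the full two-epoch study with known truth.

    The epoch-1 panel is drawn from the ancestral frequencies; epoch-2
    frequencies follow per-generation binomial Wright-Fisher reproduction over
    ``round(years_between * gens_per_year)`` generations at size ``ne_local``
    (genic selection applied at the planted selected loci); the seasonal pools
    are then drawn by the dual binomial individual-then-read scheme.
    """
    if ne_local < 2:
        raise ValueError("ne_local must be at least 2")
    world.validate()
    rng = np.random.default_rng(world.seed)
    generations = int(round(years_between * gens_per_year))

    sites = _site_table(world, rng)
    f1 = _epoch1_site_freqs(world, sites)
    panel = generate_isofemale_panel(world, rng=rng, sites=sites, freqs=f1)

    # Wright-Fisher drift between epochs (plain sites)
    plain = sites["marker_of"].to_numpy() == ""
    f2 = f1.copy()
    sel_index = {}
    for snp_idx, s, f0 in world.selected_loci:
        sel_index[int(snp_idx)] = (s, f0)
    neutral_mask = plain.copy()
    plain_idx = np.flatnonzero(plain)
    for k, (s, f0) in sel_index.items():
        site = plain_idx[k]
        neutral_mask[site] = False
        start = f0 if f0 is not None else f1[site]
        f2[site] = simulate_frequencies(np.array([start]), ne_local, generations,
                                        s=s, rng=rng)[0]
    f2[neutral_mask] = simulate_frequencies(f1[neutral_mask], ne_local,
                                            generations, rng=rng)

    # clinal SNPs: systematic shift of the northern allele on top of drift
    n_plain = int(plain.sum())
    clinal_rng = np.random.default_rng(world.seed + 2)
    clinal_p = clinal_rng.random(n_plain) ** 2  # skew toward small p
    is_clinal = clinal_rng.random(n_plain) < world.clinal_fraction
    clinal_p[is_clinal] = clinal_rng.uniform(0.0, 0.001, size=is_clinal.sum())
    northern_is_alt = clinal_rng.random(n_plain) < 0.5
    shift = np.where(northern_is_alt, world.clinal_shift, -world.clinal_shift)
    shifted_sites = plain_idx[is_clinal]
    f2[shifted_sites] = np.clip(f2[shifted_sites] + shift[is_clinal], 0.0, 1.0)

    pools = []
    fall_locs = [world.locations[i % len(world.locations)] for i in range(world.fall_pools)]
    spring_locs = [world.locations[i % len(world.locations)] for i in range(world.spring_pools)]
    fall_neffs = [
        float(world.fall_neffs[i]) if i < len(world.fall_neffs) else float(world.fall_flies)
        for i in range(world.fall_pools)
    ]
    spring_neffs = [float(world.spring_neff)] * world.spring_pools
    for season, n_pools, locs, n_flies, neffs, cov in (
        ("fall", world.fall_pools, fall_locs, world.fall_flies, fall_neffs,
         world.fall_coverage),
        ("spring", world.spring_pools, spring_locs, world.spring_flies, spring_neffs,
         world.spring_coverage),
    ):
        inv_freqs = {inv.name: inv.freqs.get(season, inv.freqs.get("old", 0.0))
                     for inv in world.inversion_defs}
        for i in range(n_pools):
            pools.append(
                _draw_pool(
                    sites, f2, inv_freqs, n_flies, min(neffs[i], float(n_flies)), cov,
                    pool_id=f"{season}_{i + 1}", season=season,
                    location=locs[i], rng=rng,
                )
            )

    # diversity track: non-singleton sites in a simulated 100-chromosome
    # reference panel drawn from the epoch-1 frequencies
    ref_counts = rng.binomial(100, f1)
    nonsingleton = (ref_counts >= 2) & (ref_counts <= 98)
    diversity_track = sites.loc[nonsingleton, ["chrom", "pos"]].reset_index(drop=True)

    truth = {
        "ne_local": ne_local,
        "generations": generations,
        "selected_loci": [
            {"snp_index": int(k), "s": float(s), "f0": None if f0 is None else float(f0)}
            for k, (s, f0) in sel_index.items()
        ],
        "inversion_freqs": {
            inv.name: dict(inv.freqs) for inv in world.inversion_defs
        },
        "shifted_snp_sites": [int(i) for i in shifted_sites],
        "epoch1_freqs": f1.tolist(),
        "epoch2_freqs": f2.tolist(),
        "clinal_p": clinal_p.tolist(),
        "northern_is_alt": northern_is_alt.tolist(),
    }
    if world.cnv_locus is not None:
        truth["cnv"] = {
            "intact_freq_by_year": {int(y): float(v) for y, v in
                                    world.cnv_locus.intact_freq_by_year.items()},
            "intact_freq_new": world.cnv_locus.intact_freq_new,
        }
    return GeneratedDataset(
        world=world,
        panel=panel,
        pools=pools,
        diversity_track=diversity_track,
        truth=truth,
    )


def generate_category_map(
    world: SimWorld,
    n_categories: int = 30,
    gene_length: int = 8000,
    gene_gap: int = 4000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Tile the arms with gene-like intervals and assign category labels.

    Returns (gene table with chrom/start/stop/gene, gene -> [categories]).
    """
    rng = np.random.default_rng(world.seed if seed is None else seed)
    rows = []
    gid = 0
    for arm in world.chrom_arms:
        pos = 1
        while pos + gene_length <= arm.length:
            rows.append((arm.name, pos, pos + gene_length - 1, f"g{gid:05d}"))
            gid += 1
            pos += gene_length + gene_gap
    genes = pd.DataFrame(rows, columns=["chrom", "start", "stop", "gene"])
    labels = [f"cat{c:03d}" for c in range(n_categories)]
    mapping = {
        g: list(rng.choice(labels, size=rng.integers(1, 4), replace=False))
        for g in genes["gene"]
    }
    return genes, mapping


def default_world(seed: int = 0, n_snps: int = 4000, **overrides) -> SimWorld:
    """A small demonstration world with the study's headline conditions.

    Two autosome arms and an inversion per arm; one planted selected locus;
    a CNV locus whose intact allele rises over the old sampling years.
    """
    arms = [
        ChromArm("2L", 20_000_000, 2.0),
        ChromArm("2R", 20_000_000, 2.5),
    ]
    inversions = [
        InversionDef(
            "In(2L)t", "2L",
            np.arange(5_000_000, 5_000_000 + 40 * 2000, 2000),
            {"old": 0.12, "fall": 0.09, "spring": 0.09},
        ),
        InversionDef(
            "In(2R)NS", "2R",
            np.arange(9_000_000, 9_000_000 + 40 * 2000, 2000),
            {"old": 0.10, "fall": 0.068, "spring": 0.029},
        ),
    ]
    cnv = CNVLocus(
        arm="2R",
        start=10_500_000,
        stop=10_520_000,
        intact_freq_by_year={
            1975: 0.0, 1977: 0.05, 1979: 0.15, 1980: 0.25, 1981: 0.35, 1983: 0.55,
        },
        intact_freq_new=0.51,
    )
    kwargs = dict(
        chrom_arms=arms,
        n_snps=n_snps,
        seed=seed,
        selected_loci=[(n_snps // 2, 0.05, 0.1)],
        cnv_locus=cnv,
        inversion_defs=inversions,
    )
    kwargs.update(overrides)
    return SimWorld(**kwargs)
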