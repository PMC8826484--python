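"""End-to-end orchestration: simulate, analyse, and report with one config.

A run is described by a YAML config with one block per stage; every
stochastic stage receives a recorded sub-seed derived from the global seed,
so reruns with the same config are byte-identical.  Stages write their
outputs under the run directory and never touch another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cline, enrichment, inversions, io, scan, wf
from .synthetic import default_world, generate_dataset, generate_category_map
from .pool import LineageTable, combine_pool_frequencies

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "inversions", "ne_fit", "pbs_scan", "enrichment",
          "clinal", "cnv_abc")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    world: dict = field(default_factory=dict)
    ne_local: int = 9500
    years_between: float = 31.0
    gens_per_year: float = 15.0
    stages: tuple = STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"out_dir", "seed", "world", "ne_local", "years_between",
                 "gens_per_year", "stages"}
        cfg = {k: v for k, v in raw.items() if k in known}
        cfg["out_dir"] = Path(cfg.get("out_dir", "tempopool_run"))
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        params = {k: v for k, v in raw.items() if k not in known}
        return cls(params=params, **cfg)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": {},
        "outputs": {},
    }

    world = default_world(seed=config.stage_seed("simulate"), **config.world)
    dataset = generate_dataset(
        world, config.ne_local, config.years_between, config.gens_per_year
    )
    manifest["stage_seeds"]["simulate"] = config.stage_seed("simulate")

    if "simulate" in config.stages:
        io.write_sync(dataset.pools, out / "pools.sync")
        io.write_panel(dataset.panel, out / "panel")
        io.write_bed_track(dataset.diversity_track, out / "diversity_track.bed")
        io.write_truth(dataset.truth, out / "truth.json")
        for name in ("pools.sync", "panel.genotypes.tsv", "diversity_track.bed",
                     "truth.json"):
            manifest["outputs"][name] = _digest(out / name)

    marker_sets = [
        inversions.InversionMarkerSet(inv.name, inv.arm, inv.marker_positions)
        for inv in world.inversion_defs
    ]

    inv_estimates = {}
    if "inversions" in config.stages:
        sseed = config.stage_seed("inversions")
        manifest["stage_seeds"]["inversions"] = sseed
        rows = []
        fall = dataset.pools_by_season("fall")
        spring = dataset.pools_by_season("spring")
        for ms in marker_sets:
            est = inversions.estimate_inversion(dataset.pools, ms)
            p_seas, f_fall, f_spring = inversions.resample_seasonal_test(
                fall, spring, ms, n_reps=config.params.get("inversion_reps", 2000),
                seed=sseed,
            )
            _, panel_freq = inversions.karyotype_panel(dataset.panel, ms)
            inv_estimates[ms.name] = est
            rows.append((ms.name, panel_freq, f_fall, f_spring, p_seas))
        tab = pd.DataFrame(
            rows, columns=["inversion", "panel_freq", "fall_freq", "spring_freq",
                           "seasonal_p"]
        )
        tab.to_csv(out / "inversions.tsv", sep="\t", index=False)
        manifest["outputs"]["inversions.tsv"] = _digest(out / "inversions.tsv")

    # shared frequency tables for Ne fit, scan, and the clinal stage
    needs_tables = any(s in config.stages for s in ("ne_fit", "pbs_scan", "clinal"))
    panel_freqs = dataset.panel.allele_frequencies()
    fall_pools = dataset.pools_by_season("fall")
    spring_pools = dataset.pools_by_season("spring")

    def season_table(pools):
        table = LineageTable()
        freqs = np.stack([p.frequencies() for p in pools])
        neffs = np.array([p.n_eff for p in pools])
        comb = np.array(
            [combine_pool_frequencies(freqs[:, i], neffs) for i in range(freqs.shape[1])]
        )
        n_eff_alleles = np.zeros(freqs.shape[1])
        for p in pools:
            cov = p.coverage
            n_c = p.n_chromosomes
            n_eff_alleles += np.array(
                [table.lookup(int(c), n_c) if c > 0 else 0.0 for c in cov]
            )
        return comb, n_eff_alleles

    if needs_tables:
        f_fall, n_fall = season_table(fall_pools)
        f_spring, n_spring = season_table(spring_pools)

    if "ne_fit" in config.stages:
        sseed = config.stage_seed("ne_fit")
        manifest["stage_seeds"]["ne_fit"] = sseed
        scheme = wf.SamplingScheme(
            n_effs=np.array([p.n_eff for p in dataset.pools]),
            coverages=np.concatenate([p.coverage for p in dataset.pools]),
        )
        f_new = 0.5 * (f_fall + f_spring)
        mean_called = float(np.mean(dataset.panel.ploidy.sum(axis=0)))
        model = wf.EffectiveSizeGridModel(
            panel_freqs, f_new, scheme,
            generations=int(round(config.years_between * config.gens_per_year)),
            old_sample_size=mean_called,
        )
        grid = config.params.get(
            "ne_grid", list((2000 * 1.25 ** np.arange(0, 12)).astype(int))
        )
        result = model.fit(
            grid, n_snps=config.params.get("ne_fit_snps", 2000), seed=sseed
        )
        (out / "ne_fit.txt").write_text(result.summary() + "\n")
        manifest["outputs"]["ne_fit.txt"] = _digest(out / "ne_fit.txt")
        manifest["ne_estimate"] = result.best_n

    windows_p = None
    if "pbs_scan" in config.stages:
        sseed = config.stage_seed("pbs_scan")
        manifest["stage_seeds"]["pbs_scan"] = sseed
        targets = {}
        for ms in marker_sets:
            est = inv_estimates.get(ms.name) or inversions.estimate_inversion(
                dataset.pools, ms
            )
            pooled = combine_pool_frequencies(
                est.per_pool["frequency"].to_numpy(), est.per_pool["n_eff"].to_numpy()
            )
            targets[ms.name] = pooled
        focal = scan.weighted_focal_frequencies(dataset.panel, targets, marker_sets)
        fall_tab = dataset.panel.sites[["chrom", "pos"]].copy()
        fall_tab["freq"], fall_tab["neff"] = f_fall, np.maximum(n_fall, 1.01)
        spring_tab = dataset.panel.sites[["chrom", "pos"]].copy()
        spring_tab["freq"], spring_tab["neff"] = f_spring, np.maximum(n_spring, 1.01)
        rates = {a.name: a.recomb_rate for a in world.chrom_arms}
        windows = scan.delimit_windows(
            dataset.diversity_track, rates,
            snps_per_window=config.params.get("snps_per_window", 200),
        )
        windows = scan.window_pbs_scan(windows, focal, fall_tab, spring_tab)
        null_w, null_m = scan.simulate_null_pbs(
            n_windows=config.params.get("null_windows", 300),
            f0_pool=panel_freqs[~np.isnan(panel_freqs)],
            ne=config.ne_local,
            generations=int(round(config.years_between * config.gens_per_year)),
            focal_n=2 * dataset.panel.n_strains,
            fall_scheme=wf.SamplingScheme(
                np.array([p.n_eff for p in fall_pools]),
                np.concatenate([p.coverage for p in fall_pools]),
            ),
            spring_scheme=wf.SamplingScheme(
                np.array([p.n_eff for p in spring_pools]),
                np.concatenate([p.coverage for p in spring_pools]),
            ),
            snps_per_window=config.params.get("snps_per_window", 200),
            seed=sseed,
        )
        null = scan.NullDistribution.from_arrays(null_w, null_m)
        windows_p = scan.assign_pvalues(windows, null)
        windows_p.to_csv(out / "windows.tsv", sep="\t", index=False)
        regions = scan.call_regions(windows_p)
        pd.DataFrame(
            [
                (r.chrom, r.start, r.stop, r.n_windows, r.peak_stat, r.peak_p)
                for r in regions
            ],
            columns=["chrom", "start", "stop", "windows", "peak_pbs", "peak_p"],
        ).to_csv(out / "regions.tsv", sep="\t", index=False)
        manifest["outputs"]["windows.tsv"] = _digest(out / "windows.tsv")
        manifest["outputs"]["regions.tsv"] = _digest(out / "regions.tsv")

    if "enrichment" in config.stages and windows_p is not None:
        sseed = config.stage_seed("enrichment")
        manifest["stage_seeds"]["enrichment"] = sseed
        genes, mapping = generate_category_map(world, seed=sseed)
        cat_map = enrichment.CategoryMap(genes, mapping)
        table = enrichment.permutation_enrichment(
            windows_p, cat_map,
            n_perm=config.params.get("n_perm", 2000), seed=sseed,
        )
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["outputs"]["enrichment.tsv"] = _digest(out / "enrichment.tsv")

    if "clinal" in config.stages:
        plain = dataset.panel.sites["marker_of"].to_numpy() == ""
        plain_idx = np.flatnonzero(plain)
        clinal_p = np.asarray(dataset.truth["clinal_p"])
        northern_is_alt = np.asarray(dataset.truth["northern_is_alt"])
        f_new = 0.5 * (f_fall + f_spring)
        old_f = panel_freqs[plain_idx]
        new_f = f_new[plain_idx]
        old_n = np.where(northern_is_alt, old_f, 1 - old_f)
        new_n = np.where(northern_is_alt, new_f, 1 - new_f)
        snps = pd.DataFrame(
            {
                "chrom": dataset.panel.sites["chrom"].to_numpy()[plain_idx],
                "pos": dataset.panel.sites["pos"].to_numpy()[plain_idx],
                "clinal_p": clinal_p,
                "old_freq": old_n,
                "new_freq": new_n,
            }
        )
        thinned = cline.thin_clinal_snps(snps)
        if len(thinned) > 0:
            mean_shift, n_up, p = cline.clinal_shift_test(thinned)
            manifest["clinal"] = {
                "snps": len(thinned),
                "mean_shift": mean_shift,
                "increased": n_up,
                "binomial_p": p,
            }

    if "cnv_abc" in config.stages and world.cnv_locus is not None:
        sseed = config.stage_seed("cnv_abc")
        manifest["stage_seeds"]["cnv_abc"] = sseed
        rng = np.random.default_rng(sseed)
        cnv = world.cnv_locus
        ratios = np.where(
            dataset.panel.cnv_calls == 1,
            cnv.r_intact * np.exp(rng.normal(0, 0.05, dataset.panel.n_strains)),
            cnv.r_deleted * np.exp(rng.normal(0, 0.05, dataset.panel.n_strains)),
        )
        calls, counts = cline.call_cnv_genotypes(
            ratios, cnv.r_intact, cnv.r_deleted,
            collection_year=dataset.panel.collection_year,
        )
        r_pool = cnv.intact_freq_new * cnv.r_intact + (
            1 - cnv.intact_freq_new
        ) * cnv.r_deleted
        pool_freq = cline.cnv_frequency_pool(
            cline.CNVCoverageProfile(r_pool, cnv.r_intact, cnv.r_deleted)
        )
        abc = wf.ExactMatchABC(
            counts, gens_per_year=config.gens_per_year, n_e=config.ne_local
        )
        result = abc.fit(
            n_accept=config.params.get("abc_acceptances", 2000), seed=sseed
        )
        (out / "cnv_abc.txt").write_text(
            result.summary() + f"\npooled intact frequency: {pool_freq:.4f}\n"
        )
        manifest["outputs"]["cnv_abc.txt"] = _digest(out / "cnv_abc.txt")
        manifest["cnv"] = {
            "pool_intact_freq": pool_freq,
            "abc_map_s": result.map_s,
            "abc_map_f0": result.map_f0,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
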