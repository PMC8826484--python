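"""Readers and writers for the plain-text interchange formats.

The pooled allele counts travel in the PoPoolation2 "sync" dialect: one row
per position with ``chrom  pos  ref`` followed by one ``A:T:C:G:N:del``
colon-separated count column per pool (1-based positions).  Panels are a TSV
genotype matrix plus a BED ploidy mask; interval tracks are BED (0-based
half-open on disk, converted to the 1-based inclusive convention in memory);
truth records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pool import PoolSample

SYNC_ORDER = "ATCGN*"  # the del column is written under '*'


def write_sync(pools: list[PoolSample], path: str | Path) -> None:
    """Write pools side by side as a sync table (shared site grid required)."""
    base = pools[0].sites
    cols = []
    for pool in pools:
        s = pool.sites
        if not (s["pos"].to_numpy() == base["pos"].to_numpy()).all():
            raise ValueError("pools must share one site grid to share a sync file")
        counts = np.zeros((len(s), 6), dtype=np.int64)
        for i, (ref, alt, rc, ac) in enumerate(
            zip(s["ref"], s["alt"], s["ref_count"], s["alt_count"])
        ):
            counts[i, SYNC_ORDER.index(ref)] = rc
            counts[i, SYNC_ORDER.index(alt)] = ac
        cols.append([":".join(map(str, row)) for row in counts])
    with open(path, "w") as fh:
        for i in range(len(base)):
            fields = [str(base["chrom"].iloc[i]), str(base["pos"].iloc[i]),
                      str(base["ref"].iloc[i])]
            fields += [col[i] for col in cols]
            fh.write("\t".join(fields) + "\n")


def read_sync(path: str | Path, pool_meta: pd.DataFrame) -> list[PoolSample]:
    """Read a sync file into PoolSample objects.

    ``pool_meta`` has one row per pool column in file order with columns
    ``pool_id, season, location, n_flies, n_eff``.  The alt allele at each
    site is the highest-count non-reference base summed across pools.
    """
    raw = pd.read_csv(path, sep="\t", header=None)
    chrom = raw[0].astype(str)
    pos = raw[1].astype(int)
    ref = raw[2].astype(str)
    n_pools = raw.shape[1] - 3
    if n_pools != len(pool_meta):
        raise ValueError(f"sync file has {n_pools} pools, metadata has {len(pool_meta)}")
    counts = np.zeros((n_pools, len(raw), 6), dtype=np.int64)
    for j in range(n_pools):
        parts = raw[3 + j].str.split(":", expand=True).astype(np.int64).to_numpy()
        counts[j] = parts
    total = counts.sum(axis=0)
    ref_idx = np.array([SYNC_ORDER.index(r) for r in ref])
    masked = total.copy()
    masked[np.arange(len(raw)), ref_idx] = -1
    masked[:, 4:] = -1  # N and del never become the alt allele
    alt_idx = masked.argmax(axis=1)
    alt = np.array([SYNC_ORDER[i] for i in alt_idx])
    pools = []
    rows = np.arange(len(raw))
    for j, meta in enumerate(pool_meta.itertuples()):
        sites = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "ref_count": counts[j][rows, ref_idx],
                "alt_count": counts[j][rows, alt_idx],
            }
        )
        pools.append(
            PoolSample(
                pool_id=str(meta.pool_id),
                season=str(meta.season),
                location=str(meta.location),
                n_flies=int(meta.n_flies),
                n_eff=float(meta.n_eff),
                sites=sites,
            )
        )
    return pools


def write_panel(panel, prefix: str | Path) -> None:
    """Panel genotypes as TSV matrix plus a BED ploidy mask per strain."""
    prefix = Path(prefix)
    geno = pd.DataFrame(
        panel.genotypes.T, columns=panel.strains
    )
    out = pd.concat([panel.sites[["chrom", "pos", "ref", "alt"]], geno], axis=1)
    out.to_csv(prefix.with_suffix(".genotypes.tsv"), sep="\t", index=False)
    rows = []
    pos = panel.sites["pos"].to_numpy()
    chrom = panel.sites["chrom"].to_numpy()
    for i, strain in enumerate(panel.strains):
        diploid = panel.ploidy[i] == 2
        for arm in np.unique(chrom):
            sel = (chrom == arm) & diploid
            for p in pos[sel]:
                rows.append((arm, p - 1, p, strain))
    pd.DataFrame(rows, columns=["chrom", "start", "stop", "strain"]).to_csv(
        prefix.with_suffix(".ploidy2.bed"), sep="\t", index=False, header=False
    )


def write_bed_track(track: pd.DataFrame, path: str | Path) -> None:
    """Position track (chrom, pos; 1-based) to BED (0-based half-open)."""
    bed = pd.DataFrame(
        {"chrom": track["chrom"], "start": track["pos"] - 1, "stop": track["pos"]}
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed_track(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "stop"])
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["stop"].astype(int)})


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_marker_table(marker_sets: list, path: str | Path) -> None:
    rows = []
    for ms in marker_sets:
        for p in ms.positions:
            rows.append((ms.name, ms.arm, int(p), ms.inverted_allele))
    pd.DataFrame(rows, columns=["inversion", "arm", "pos", "inverted_base"]).to_csv(
        path, sep="\t", index=False
    )


def read_marker_table(path: str | Path) -> list:
    from .inversions import InversionMarkerSet

    df = pd.read_csv(path, sep="\t")
    out = []
    for (name, arm), grp in df.groupby(["inversion", "arm"], sort=True):
        out.append(
            InversionMarkerSet(
                name=name,
                arm=arm,
                positions=grp["pos"].to_numpy(),
                inverted_allele=str(grp["inverted_base"].iloc[0]),
            )
        )
    return out
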