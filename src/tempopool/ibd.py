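"""Pairwise identity-by-descent scanning for panel QC.

Two genomes are compared in sliding windows; windows whose per-site
difference rate (over jointly callable sites) falls below a threshold are
putatively IBD and are chained into tracts.  Known recurrent-IBD intervals
(for example centromere-proximal regions that are near-identical between
unrelated strains) may extend a neighbouring tract but can never seed one.
A pair with any tract longer than 5 Mb is flagged as related and one member
is masked — the lower-coverage genome by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IBDTract", "IBDReport", "ibd_scan"]

RELATEDNESS_TRACT_BP = 5_000_000


@dataclass
class IBDTract:
    chrom: str
    start: int
    stop: int
    diff_rate: float
    seeded: bool  # False if every member window lies in recurrent regions

    @property
    def span(self) -> int:
        return self.stop - self.start + 1


@dataclass
class IBDReport:
    tracts: list
    related: bool
    masked_member: int | None  # 0 or 1, which genome's tracts are masked
    masked_intervals: list = field(default_factory=list)  # (chrom, start, stop)


def _window_grid(length: int, window: int, step: int):
    start = 1
    while start <= length:
        yield start, min(start + window - 1, length)
        if start + window - 1 >= length:
            break
        start += step


def ibd_scan(
    track_a: dict,
    track_b: dict,
    arm_lengths: dict,
    window: int = 500_000,
    step: int = 100_000,
    max_diff: float = 0.0005,
    recurrent_regions: list | None = None,
    min_called: int = 100,
    coverage: tuple[float, float] | None = None,
) -> IBDReport:
    """Scan a pair of genome call tracks for IBD tracts.

    ``track_a``/``track_b`` map arm name to ``(positions, calls)`` where
    calls are integer allele codes with ``-1`` for missing; both tracks must
    share the position grid per arm.  ``recurrent_regions`` is a list of
    (chrom, start, stop) intervals allowed to extend but not seed tracts.
    ``coverage`` (mean depth of genomes a and b) picks which member of a
    flagged pair is masked: the lower-coverage one.
    """
    if window < step:
        raise ValueError("window must be at least as long as the step")
    recurrent = recurrent_regions or []
    tracts: list[IBDTract] = []
    for arm, length in arm_lengths.items():
        pos_a, calls_a = track_a[arm]
        pos_b, calls_b = track_b[arm]
        if len(pos_a) != len(pos_b) or not np.array_equal(pos_a, pos_b):
            raise ValueError(f"call tracks not aligned on arm {arm}")
        pos = np.asarray(pos_a)
        a = np.asarray(calls_a)
        b = np.asarray(calls_b)
        callable_ = (a >= 0) & (b >= 0)
        diff = callable_ & (a != b)
        arm_recurrent = [(s, t) for c, s, t in recurrent if c == arm]

        win_rows = []
        for w_start, w_stop in _window_grid(length, window, step):
            in_win = (pos >= w_start) & (pos <= w_stop)
            n_called = int(np.sum(callable_ & in_win))
            if n_called < min_called:
                continue
            rate = float(np.sum(diff & in_win)) / n_called
            if rate >= max_diff:
                continue
            mid = 0.5 * (w_start + w_stop)
            in_recurrent = any(s <= mid <= t for s, t in arm_recurrent)
            win_rows.append((w_start, w_stop, rate, in_recurrent))

        # chain overlapping/adjacent qualifying windows into tracts
        current = None
        for w_start, w_stop, rate, in_rec in win_rows:
            if current is not None and w_start <= current["stop"] + 1:
                current["stop"] = max(current["stop"], w_stop)
                current["rates"].append(rate)
                current["seeded"] = current["seeded"] or not in_rec
            else:
                if current is not None:
                    tracts.append(_close(arm, current))
                current = {
                    "start": w_start,
                    "stop": w_stop,
                    "rates": [rate],
                    "seeded": not in_rec,
                }
        if current is not None:
            tracts.append(_close(arm, current))

    qualifying = [t for t in tracts if t.seeded]
    related = any(t.span > RELATEDNESS_TRACT_BP for t in qualifying)
    masked_member = None
    masked_intervals: list = []
    if related:
        if coverage is not None and coverage[0] < coverage[1]:
            masked_member = 0
        else:
            masked_member = 1
        masked_intervals = [
            (t.chrom, t.start, t.stop)
            for t in qualifying
            if t.span > RELATEDNESS_TRACT_BP
        ]
    return IBDReport(
        tracts=qualifying,
        related=related,
        masked_member=masked_member,
        masked_intervals=masked_intervals,
    )


def _close(arm: str, current: dict) -> IBDTract:
    return IBDTract(
        chrom=arm,
        start=int(current["start"]),
        stop=int(current["stop"]),
        diff_rate=float(np.mean(current["rates"])),
        seeded=bool(current["seeded"]),
    )


def report_to_frame(report: IBDReport) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.chrom, t.start, t.stop, t.diff_rate, t.span) for t in report.tracts],
        columns=["chrom", "start", "stop", "diff_rate", "span"],
    )
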