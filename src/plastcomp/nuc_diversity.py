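"""Sliding-window Nei-Li nucleotide diversity over a multiple alignment.

For each pair of rows the difference proportion in a window is the number of
columns where both bases are unambiguous (A/C/G/T) and differ, divided by the
number of columns where both are unambiguous (pairwise deletion of gap/N
columns). Window pi is the mean of this proportion over all row pairs; pairs
with no comparable column in a window are excluded from the mean. No
sample-size correction factor is applied: pi is the plain mean of pairwise
proportions, per Nei and Li.

Windows are laid out on alignment coordinates (1-based), default 500 columns
advancing by 200; a trailing partial window is kept only when it covers at
least half the window length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .genome_io import AlignedSet


@dataclass
class DiversityWindow:
    aln_start: int  # 1-based inclusive
    aln_end: int
    pi: float | None  # None when no pair had a comparable column
    valid_pairs: int
    partial: bool = False


@dataclass
class DiversityProfile:
    windows: list[DiversityWindow]
    mean_pi: float | None  # unweighted mean of window pi values
    site_pi: float | None  # per-site weighted mean (total diffs / total sites)
    short_alignment: bool = False  # alignment shorter than one window


def pairwise_difference(row_i: str, row_j: str, cols: slice | None = None) -> float | None:
    """Difference proportion between two gapped rows over ``cols``.

    Columns where either row has a gap or N are excluded from both numerator
    and denominator; ``None`` when no column is comparable.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal length")
    if cols is not None:
        row_i, row_j = row_i[cols], row_j[cols]
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    good = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    denom = int(good.sum())
    if denom == 0:
        return None
    return float((a[good] != b[good]).sum() / denom)


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _window_starts(n_cols: int, window: int, step: int) -> list[tuple[int, int, bool]]:
    """(start, end, partial) triples, 1-based inclusive."""
    if n_cols <= window:
        return [(1, n_cols, n_cols < window)]
    out = []
    start = 1
    while start + window - 1 <= n_cols:
        out.append((start, start + window - 1, False))
        start += step
    if start <= n_cols and (n_cols - start + 1) * 2 >= window:
        out.append((start, n_cols, True))
    return out


def sliding_pi(
    msa: AlignedSet, window: int = 500, step: int = 200
) -> DiversityProfile:
    """Window-wise pi plus the overall (unweighted) mean across windows.

    Implemented with cumulative per-pair difference and comparable-site counts
    so each pair's columns are scanned once regardless of window overlap.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    n = msa.n_rows
    n_cols = msa.n_columns
    rows = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    good = [np.isin(r, _ACGT) for r in rows]

    pair_cum: list[tuple[np.ndarray, np.ndarray]] = []
    total_diff = 0
    total_sites = 0
    for i, j in combinations(range(n), 2):
        comparable = good[i] & good[j]
        diff = comparable & (rows[i] != rows[j])
        cum_c = np.concatenate(([0], np.cumsum(comparable)))
        cum_d = np.concatenate(([0], np.cumsum(diff)))
        pair_cum.append((cum_c, cum_d))
        total_diff += int(cum_d[-1])
        total_sites += int(cum_c[-1])

    layout = _window_starts(n_cols, window, step)
    windows: list[DiversityWindow] = []
    for start, end, partial in layout:
        props = []
        for cum_c, cum_d in pair_cum:
            denom = int(cum_c[end] - cum_c[start - 1])
            if denom == 0:
                continue
            props.append((cum_d[end] - cum_d[start - 1]) / denom)
        pi = float(np.mean(props)) if props else None
        windows.append(DiversityWindow(
            aln_start=start, aln_end=end, pi=pi,
            valid_pairs=len(props), partial=partial,
        ))

    pis = [w.pi for w in windows if w.pi is not None]
    mean_pi = float(np.mean(pis)) if pis else None
    site_pi = total_diff / total_sites if total_sites else None
    return DiversityProfile(
        windows=windows, mean_pi=mean_pi, site_pi=site_pi,
        short_alignment=n_cols < window,
    )


def find_peaks(
    windows: Sequence[DiversityWindow], threshold: float | None = None
) -> list[DiversityWindow]:
    """Maximal runs of consecutive windows with pi >= threshold, each reported
    at its maximum window. Default threshold: mean + 5 sd of the window pis."""
    pis = np.array([w.pi for w in windows if w.pi is not None], dtype=float)
    if pis.size == 0:
        return []
    if threshold is None:
        threshold = float(pis.mean() + 5.0 * pis.std())
    peaks: list[DiversityWindow] = []
    current: list[DiversityWindow] = []
    for w in windows:
        if w.pi is not None and w.pi >= threshold and threshold > 0:
            current.append(w)
        else:
            if current:
                peaks.append(max(current, key=lambda x: x.pi))
            current = []
    if current:
        peaks.append(max(current, key=lambda x: x.pi))
    return peaks
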