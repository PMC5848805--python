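"""Cross-species harmonization of DNase-hypersensitive site (DHS) peaks.

Per-sample peak calls (scored with -10*log10 p) are pooled across every
sample of both species and partitioned at every distinct peak boundary into
disjoint "windows" (multi-intersect semantics).  Each window then gets a
representative score per sample — the maximum score, i.e. the lowest
p-value, of any overlapping peak — an activity flag per (species, time)
requiring signal in at least one replicate, and a species-sharing class.
Windows shorter than 50 bp or longer than 2,000 bp are discarded.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix, DEResult, de_test

__all__ = [
    "Peak",
    "Window",
    "build_windows",
    "score_and_classify",
    "sharing_class_counts",
    "differential_windows",
    "directional_balance_test",
    "overlap_external",
]

SampleKey = tuple[str, str, str]  # (species, time, replicate)


@dataclass(frozen=True)
class Peak:
    """A scored called peak in one sample; score = -10*log10 p >= 0."""

    chrom: str
    start: int
    end: int
    score: float
    sample: SampleKey

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")


@dataclass
class Window:
    """A harmonized cross-sample interval with per-sample scores."""

    chrom: str
    start: int
    end: int
    scores: dict[SampleKey, float] = field(default_factory=dict)
    activity: dict[tuple[str, str], bool] = field(default_factory=dict)
    sharing_class: str = "inactive"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def build_windows(
    peaks: list[Peak], min_len: int = 50, max_len: int = 2000
) -> list[Window]:
    """Partition the pooled peak union at every peak boundary.

    Every segment between consecutive distinct boundaries that is covered by
    at least one peak becomes a window; book-ended fragments are NOT merged
    back.  Segments outside [min_len, max_len] are discarded.  Output is
    sorted and non-overlapping.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append((p.start, p.end))

    windows: list[Window] = []
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        bounds = np.unique(
            np.concatenate([[s for s, _ in ivs], [e for _, e in ivs]])
        )
        starts = np.array(sorted(s for s, _ in ivs))
        ends_sorted = np.array(sorted(e for _, e in ivs))
        # coverage of segment [bounds[i], bounds[i+1]): number of intervals
        # with start <= bounds[i] minus number with end <= bounds[i]
        seg_lo = bounds[:-1]
        n_started = np.searchsorted(starts, seg_lo, side="right")
        n_ended = np.searchsorted(ends_sorted, seg_lo, side="right")
        covered = (n_started - n_ended) > 0
        for lo, hi, cov in zip(bounds[:-1], bounds[1:], covered):
            if cov and min_len <= hi - lo <= max_len:
                windows.append(Window(chrom=chrom, start=int(lo), end=int(hi)))
    return windows


def _index_peaks(peaks: list[Peak]):
    """Per (chrom, sample): arrays of starts, ends, scores sorted by start."""
    acc: dict[tuple[str, SampleKey], list[tuple[int, int, float]]] = defaultdict(list)
    for p in peaks:
        acc[(p.chrom, p.sample)].append((p.start, p.end, p.score))
    out = {}
    for key, ivs in acc.items():
        ivs.sort()
        out[key] = (
            np.array([s for s, _, _ in ivs]),
            np.array([e for _, e, _ in ivs]),
            np.array([sc for _, _, sc in ivs]),
        )
    return out


def score_and_classify(
    windows: list[Window],
    peaks: list[Peak],
    replicate_map: dict[SampleKey, tuple[str, str]] | None = None,
    species: tuple[str, str] = ("human", "chimpanzee"),
) -> list[Window]:
    """Assign representative scores, activity flags, and sharing classes.

    Representative score per sample = max score of overlapping peaks (the
    lowest p-value), 0 when none.  A (species, time) combination is active
    when at least one replicate scores > 0.  Sharing class: ``shared`` when
    active in both species at any time; ``<species>_specific`` when active
    in exactly one; ``inactive`` otherwise.
    """
    samples = sorted({p.sample for p in peaks})
    if replicate_map is None:
        replicate_map = {s: (s[0], s[1]) for s in samples}
    missing = [s for s in samples if s not in replicate_map]
    if missing:
        raise ValueError(f"samples absent from replicate map: {missing}")
    sp_a, sp_b = species

    idx = _index_peaks(peaks)
    chrom_samples: dict[str, list[SampleKey]] = defaultdict(list)
    for chrom, sample in idx:
        chrom_samples[chrom].append(sample)

    for w in windows:
        w.scores = {}
        for sample in chrom_samples.get(w.chrom, ()):
            starts, ends, scores = idx[(w.chrom, sample)]
            # overlapping peaks: start < w.end and end > w.start
            hi = np.searchsorted(starts, w.end, side="left")
            cand = np.flatnonzero(ends[:hi] > w.start)
            w.scores[sample] = float(scores[cand].max()) if cand.size else 0.0

        act: dict[tuple[str, str], bool] = defaultdict(bool)
        for sample, score in w.scores.items():
            grp = replicate_map[sample]
            if score > 0:
                act[grp] = True
        w.activity = dict(act)

        active_a = any(v for (sp, _), v in w.activity.items() if sp == sp_a)
        active_b = any(v for (sp, _), v in w.activity.items() if sp == sp_b)
        if active_a and active_b:
            w.sharing_class = "shared"
        elif active_a:
            w.sharing_class = f"{sp_a}_specific"
        elif active_b:
            w.sharing_class = f"{sp_b}_specific"
        else:
            w.sharing_class = "inactive"
    return windows


def sharing_class_counts(windows: list[Window]) -> dict[str, int]:
    """Counts per sharing class; values sum to the window total."""
    counts: dict[str, int] = defaultdict(int)
    for w in windows:
        counts[w.sharing_class] += 1
    counts["total"] = len(windows)
    return dict(counts)


def differential_windows(
    window_counts: CountMatrix,
    groups: list[str],
    contrast: tuple[str, str],
    fdr: float = 0.05,
) -> list[DEResult]:
    """NB-GLM likelihood-ratio test on window-level read counts (5% FDR)."""
    return de_test(window_counts, groups, contrast, fdr_threshold=fdr)


def directional_balance_test(
    n_higher_a: int,
    n_higher_b: int,
    reference_ratio: float = 0.5,
) -> float:
    """Two-sided exact binomial test of the direction split among
    differential windows against a reference proportion (default 0.5)."""
    if n_higher_a < 0 or n_higher_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_higher_a + n_higher_b
    if total == 0:
        raise ValueError("no differential windows: balance undefined")
    return float(
        stats.binomtest(n_higher_a, total, reference_ratio, alternative="two-sided").pvalue
    )


def overlap_external(
    windows: list[Window],
    external: list[tuple[str, int, int]],
) -> tuple[int, float]:
    """Count windows overlapping >= 1 external interval by >= 1 bp.

    Half-open semantics: [100,200) and [200,300) do not overlap.  Each
    window counts at most once (``intersect -u`` behaviour).  Returns the
    count and the fraction of all windows.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in external:
        if end <= start:
            raise ValueError(f"malformed external interval {chrom}:{start}-{end}")
        by_chrom[chrom].append((start, end))
    idx = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        idx[chrom] = (
            np.array([s for s, _ in ivs]),
            np.array(sorted(e for _, e in ivs)),
        )

    n_overlap = 0
    for w in windows:
        if w.chrom not in idx:
            continue
        starts, ends_sorted = idx[w.chrom]
        # any interval with start < w.end and end > w.start
        n_start_before = np.searchsorted(starts, w.end, side="left")
        n_end_before = np.searchsorted(ends_sorted, w.start, side="right")
        if n_start_before > n_end_before:
            n_overlap += 1
    frac = n_overlap / len(windows) if windows else 0.0
    return n_overlap, frac


def windows_to_frame(windows: list[Window]) -> pd.DataFrame:
    """Windows as a BED-like frame with the sharing class in the name."""
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "name": [w.name for w in windows],
            "sharing_class": [w.sharing_class for w in windows],
        }
    )


def score_matrix(windows: list[Window], samples: list[SampleKey]) -> pd.DataFrame:
    """Per-window representative-score matrix over the given samples."""
    data = np.array(
        [[w.scores.get(s, 0.0) for s in samples] for w in windows]
    )
    return pd.DataFrame(
        data,
        index=[w.name for w in windows],
        columns=["_".join(s) for s in samples],
    )
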