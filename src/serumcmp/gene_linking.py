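"""Linking accessibility windows to genes and to expression.

Windows are assigned to the gene with the nearest transcription start site
(window midpoint to TSS, same chromosome, strand ignored for distance, ties
to the lexicographically smaller gene id).  Per-cluster window/gene ratios,
Spearman correlations between accessibility and expression, and an
exact-score position-weight-matrix scan over window sequences are built on
those links.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dhs_windows import Window
from .expression import CountMatrix

__all__ = [
    "GeneAnnotation",
    "PWM",
    "nearest_tss",
    "cluster_gene_summary",
    "dhs_expression_correlation",
    "fc_activity_correlation",
    "pwm_scan",
    "spearman",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("TSS must be non-negative")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T (4 x L), any finite weights."""

    motif_id: str
    matrix: np.ndarray  # rows A, C, G, T

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM must be 4 x L with L >= 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM weights must be finite")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def nearest_tss(
    windows: list[Window], annotation: list[GeneAnnotation]
) -> pd.DataFrame:
    """Nearest TSS per window (midpoint distance, same chromosome).

    Signed distance = window midpoint - TSS (negative when the window lies
    upstream of the TSS coordinate).  Midpoint ties between two TSSs go to
    the lexicographically smaller gene id.  Windows on chromosomes without
    any annotated gene are reported with gene = None.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    idx = {}
    for chrom, anns in by_chrom.items():
        anns.sort(key=lambda a: (a.tss, a.gene))
        idx[chrom] = (np.array([a.tss for a in anns]), anns)

    rows = []
    for w in windows:
        mid = (w.start + w.end) / 2.0
        if w.chrom not in idx:
            rows.append({"window": w.name, "gene": None, "distance": np.nan})
            continue
        tss_arr, anns = idx[w.chrom]
        j = int(np.searchsorted(tss_arr, mid))
        cands = [k for k in (j - 1, j) if 0 <= k < len(anns)]
        best = min(
            cands, key=lambda k: (abs(mid - tss_arr[k]), anns[k].gene)
        )
        rows.append(
            {
                "window": w.name,
                "gene": anns[best].gene,
                "distance": float(mid - tss_arr[best]),
            }
        )
    return pd.DataFrame(rows)


def cluster_gene_summary(
    labels: pd.Series,
    links: pd.DataFrame,
    classes: tuple[str, ...] = ("opening", "closing"),
) -> pd.DataFrame:
    """Windows and distinct linked genes per trajectory class.

    ``labels`` maps window name -> trajectory class; ``links`` is the
    nearest-TSS table.  Ratio = n_windows / n_genes rounded to 2 decimals
    (NaN when no window in the class has a linked gene).
    """
    link_map = links.set_index("window")["gene"]
    rows = []
    for cls in classes:
        wins = labels.index[labels == cls]
        genes = {link_map.get(w) for w in wins} - {None, np.nan}
        n_w, n_g = len(wins), len(genes)
        rows.append(
            {
                "class": cls,
                "n_windows": n_w,
                "n_genes": n_g,
                "ratio": round(n_w / n_g, 2) if n_g else np.nan,
            }
        )
    return pd.DataFrame(rows)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties.

    p from the large-sample t approximation, or by exact permutation of one
    vector when n < 10 (small-sample regime where the approximation is
    unreliable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n < 10:
        rx = stats.rankdata(x) - (n + 1) / 2.0
        ry = stats.rankdata(y) - (n + 1) / 2.0
        perms = np.array(list(itertools.permutations(range(n))))
        # correlation of rank vectors under every relabeling of x
        dots = rx[perms] @ ry
        norm = np.sqrt((rx**2).sum() * (ry**2).sum())
        r_all = dots / norm
        r_obs = float(rx @ ry) / norm
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
        return rho, p
    t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def dhs_expression_correlation(
    window_scores: pd.Series,
    links: pd.DataFrame,
    expression: CountMatrix,
    time: str,
    species: str | None = None,
) -> tuple[float, float]:
    """Spearman correlation of total linked DHS signal with expression.

    Per gene, total DHS signal = sum of representative scores of its linked
    windows; expression = mean count over the (species,) time's replicates.
    """
    totals: dict[str, float] = {}
    score_map = window_scores.to_dict()
    for _, row in links.iterrows():
        g = row["gene"]
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        totals[g] = totals.get(g, 0.0) + float(score_map.get(row["window"], 0.0))

    cols = [
        j
        for j, s in enumerate(expression.samples)
        if s[1] == time and (species is None or s[0] == species)
    ]
    if not cols:
        raise ValueError(f"no expression samples at time {time!r}")
    expr = expression.counts[:, cols].mean(axis=1)
    expr_map = dict(zip(expression.genes, expr))

    genes = sorted(set(totals) & set(expr_map))
    if len(genes) < 3:
        raise ValueError("need >= 3 genes with both DHS and expression measures")
    x = np.array([totals[g] for g in genes])
    y = np.array([expr_map[g] for g in genes])
    return spearman(x, y)


def fc_activity_correlation(
    log2fc: pd.Series,
    active_windows_a: pd.Series,
    active_windows_b: pd.Series,
    pseudocount: float = 1.0,
) -> tuple[float, float]:
    """Spearman correlation of expression fold-change with the per-gene
    ratio of active windows between species (pseudocount on both sides)."""
    genes = sorted(
        set(log2fc.index) & set(active_windows_a.index) & set(active_windows_b.index)
    )
    if len(genes) < 3:
        raise ValueError("need >= 3 genes in common")
    ratio = (active_windows_a[genes] + pseudocount) / (
        active_windows_b[genes] + pseudocount
    )
    return spearman(log2fc[genes].to_numpy(), ratio.to_numpy())


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _rel_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Relative PWM score at every start position (NaN where N occurs)."""
    mat = pwm.matrix
    length = pwm.length
    col_max = mat.max(axis=0)
    col_min = mat.min(axis=0)
    denom = col_max.sum() - col_min.sum()
    n_pos = len(seq) - length + 1
    if n_pos <= 0:
        return np.empty(0)
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    out = np.empty(n_pos)
    for i in range(n_pos):
        window = codes[i : i + length]
        if np.any(window < 0):
            out[i] = -np.inf  # N never reaches a perfect relative score
            continue
        score = mat[window, np.arange(length)].sum()
        out[i] = (score - col_min.sum()) / denom if denom > 0 else 1.0
    return out


def pwm_scan(
    sequence: str,
    pwm: PWM,
    min_rel_score: float = 1.0,
    both_strands: bool = True,
) -> list[tuple[int, str]]:
    """Report PWM matches at or above a relative-score threshold.

    Relative score = (score - min possible) / (max possible - min possible);
    at the default threshold 1.0 only consensus-maximal words match.  The
    minus strand is scanned via the reverse complement; a minus-strand hit
    at reported position i means the reverse complement of
    ``sequence[i:i+L]`` matches.  Ambiguous bases (N) never match at 1.0.
    Sequences shorter than the motif yield an empty list.
    """
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    fwd = _rel_scores(seq, pwm)
    for i in np.flatnonzero(fwd >= min_rel_score - 1e-12):
        hits.append((int(i), "+"))
    if both_strands:
        rc = seq.translate(_COMPLEMENT)[::-1]
        rev = _rel_scores(rc, pwm)
        length = len(seq)
        for i in np.flatnonzero(rev >= min_rel_score - 1e-12):
            hits.append((int(length - pwm.length - i), "-"))
    return sorted(hits)
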