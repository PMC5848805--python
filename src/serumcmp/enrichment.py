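"""Gene-set enrichment: running-sum GSEA, hypergeometric tests, set algebra.

The running-sum statistic walks the ranked gene list from top to bottom,
stepping up by the (weighted) ranking statistic when the gene belongs to the
query set and down by a constant otherwise; the enrichment score (ES) is the
signed maximum deviation of this walk.  Significance comes from gene-label
permutations: the set membership is reassigned to random genes of the same
cardinality.  Hypergeometric category enrichment is computed against an
explicit user background (all genes active in both species' fibroblasts in
the original assay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedList",
    "GeneSetCollection",
    "EnrichmentResult",
    "gsea_enrichment",
    "gsea_collection",
    "hypergeom_enrichment",
    "category_timepoint_sets",
]


@dataclass
class RankedList:
    """Genes ordered by a signed ranking statistic, descending.

    Ties in the statistic are broken by gene identifier (lexicographic) so
    the ordering is deterministic.
    """

    genes: list[str]
    stats: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list genes must be unique")
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.size != len(self.genes):
            raise ValueError("one statistic per gene required")
        order = sorted(
            range(len(self.genes)), key=lambda i: (-self.stats[i], self.genes[i])
        )
        self.genes = [self.genes[i] for i in order]
        self.stats = self.stats[order]

    @classmethod
    def from_de_results(cls, results) -> "RankedList":
        """Rank by signed -log10 p (sign of the log2 fold-change)."""
        genes = [r.gene for r in results]
        vals = np.array(
            [np.sign(r.log2fc) * -np.log10(max(r.p, 1e-300)) for r in results]
        )
        return cls(genes=genes, stats=vals)


class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty members."""

    def __init__(self, sets: dict[str, set[str]], descriptions: dict | None = None):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: set(members) for name, members in sets.items()}
        self.descriptions = descriptions or {}

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str]
    n_hits: int


def _running_sum_es(
    stats_abs_w: np.ndarray, hit_mask: np.ndarray
) -> tuple[float, int]:
    """ES and its position for one membership assignment.

    ``stats_abs_w`` holds |stat|^weight in list order; misses step down by
    1/(N - n_hits).  Returns the signed maximum deviation and its index.
    """
    n = stats_abs_w.size
    n_hits = int(hit_mask.sum())
    hit_sum = stats_abs_w[hit_mask].sum()
    steps = np.zeros(n)
    if hit_sum > 0:
        steps[hit_mask] = stats_abs_w[hit_mask] / hit_sum
    else:
        steps[hit_mask] = 1.0 / n_hits  # all-zero stats: uniform increments
    if n > n_hits:
        steps[~hit_mask] = -1.0 / (n - n_hits)
    walk = np.clip(np.cumsum(steps), -1.0, 1.0)  # guard float accumulation
    i_max, i_min = int(np.argmax(walk)), int(np.argmin(walk))
    if walk[i_max] >= -walk[i_min]:
        return float(walk[i_max]), i_max
    return float(walk[i_min]), i_min


def gsea_enrichment(
    rl: RankedList,
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "",
) -> EnrichmentResult:
    """Running-sum enrichment of one gene set in a ranked list.

    ES is the signed maximum deviation of the running sum; NES divides ES by
    the mean |permutation ES| of the same sign; p is the same-sign
    permutation tail with add-one correction.  Gene-label permutation:
    membership is reassigned uniformly at random, preserving set size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    hits = [g in gene_set for g in rl.genes]
    n_hits = sum(hits)
    if n_hits == 0:
        raise ValueError(f"gene set {set_name or '<unnamed>'} has no gene in the ranked list")
    hit_mask = np.asarray(hits)
    n = len(rl.genes)
    w = np.abs(rl.stats) ** weight

    es, i_es = _running_sum_es(w, hit_mask)

    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=n_hits, replace=False)] = True
        es_perm[b], _ = _running_sum_es(w, perm_mask)

    same_sign = es_perm >= 0 if es >= 0 else es_perm <= 0
    n_same = int(same_sign.sum())
    if n_same:
        p = (np.sum(np.abs(es_perm[same_sign]) >= abs(es)) + 1) / (n_same + 1)
        mean_abs = np.abs(es_perm[same_sign]).mean()
        nes = es / mean_abs if mean_abs > 0 else np.nan
    else:
        p, nes = 1.0 / (n_perm + 1), np.nan

    # leading edge: hits at or before (after, for negative ES) the extremum
    if es >= 0:
        leading = [g for g, h in zip(rl.genes[: i_es + 1], hits[: i_es + 1]) if h]
    else:
        leading = [g for g, h in zip(rl.genes[i_es:], hits[i_es:]) if h]

    return EnrichmentResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        p=float(p),
        fdr=float(p),
        leading_edge=leading,
        n_hits=n_hits,
    )


def gsea_collection(
    rl: RankedList,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """GSEA over a whole collection with sign-stratified FDR.

    FDR(set) compares the fraction of permutation NES values at least as
    extreme as the observed NES (same sign class, pooled over sets) with the
    fraction of observed NES values at least as extreme, following the
    canonical normalized-score procedure; values are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    nes_perm_all: list[np.ndarray] = []
    n = len(rl.genes)
    w = np.abs(rl.stats) ** weight
    present = set(rl.genes)

    for name, members in collection.items():
        n_hits = len(members & present)
        if n_hits < min_overlap:
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = gsea_enrichment(
            rl, members, weight=weight, n_perm=n_perm, seed=sub_seed, set_name=name
        )
        hit_sizes = n_hits
        es_perm = np.empty(n_perm)
        perm_rng = np.random.default_rng(sub_seed)
        for b in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[perm_rng.choice(n, size=hit_sizes, replace=False)] = True
            es_perm[b], _ = _running_sum_es(w, mask)
        pos, neg = es_perm[es_perm >= 0], es_perm[es_perm < 0]
        nes_perm = np.concatenate(
            [
                pos / pos.mean() if pos.size else pos,
                -neg / neg.mean() if neg.size else neg,
            ]
        )
        results.append(res)
        nes_perm_all.append(nes_perm)

    if not results:
        return pd.DataFrame(
            columns=["set", "es", "nes", "p", "fdr", "n_hits", "leading_edge"]
        )

    all_perm = np.concatenate(nes_perm_all)
    obs = np.array([r.nes for r in results])
    fdrs = []
    for r in results:
        if not np.isfinite(r.nes):
            fdrs.append(1.0)
            continue
        if r.nes >= 0:
            num_pool = all_perm[all_perm >= 0]
            frac_perm = np.mean(num_pool >= r.nes) if num_pool.size else 0.0
            obs_pool = obs[np.isfinite(obs) & (obs >= 0)]
            frac_obs = np.mean(obs_pool >= r.nes) if obs_pool.size else 1.0
        else:
            num_pool = all_perm[all_perm < 0]
            frac_perm = np.mean(num_pool <= r.nes) if num_pool.size else 0.0
            obs_pool = obs[np.isfinite(obs) & (obs < 0)]
            frac_obs = np.mean(obs_pool <= r.nes) if obs_pool.size else 1.0
        fdrs.append(float(np.clip(frac_perm / max(frac_obs, 1e-12), 0.0, 1.0)))

    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "fdr": fdrs,
            "n_hits": [r.n_hits for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    ).sort_values("p", kind="mergesort", ignore_index=True)


def hypergeom_enrichment(
    foreground: set[str],
    background: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment against an explicit background.

    For each set: overlap k of the n foreground genes with the K set members
    present in the N background genes; fold = (k/n)/(K/N);
    p = P(X >= k) for X ~ Hypergeom(N, K, n).  Rows sorted by p.
    """
    stray = set(foreground) - set(background)
    if stray:
        raise ValueError(
            f"{len(stray)} foreground genes absent from background: "
            f"{sorted(stray)[:10]}"
        )
    n_bg = len(background)
    n_fg = len(foreground)
    rows = []
    for name, members in collection.items():
        in_bg = members & background
        big_k = len(in_bg)
        k = len(foreground & in_bg)
        if big_k == 0 or n_fg == 0:
            fold, p = np.nan, 1.0
        else:
            fold = (k / n_fg) / (big_k / n_bg)
            p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_fg))
        rows.append({"set": name, "overlap": k, "set_size": big_k, "fold": fold, "p": p})
    return (
        pd.DataFrame(rows)
        .sort_values("p", kind="mergesort", ignore_index=True)
    )


def _norm_name(name: str) -> str:
    return " ".join(name.split()).lower()


def category_timepoint_sets(
    lists: dict[str, list[str] | set[str]],
    mode: str,
    timepoint: str | None = None,
) -> set[str]:
    """Set algebra over per-timepoint enriched-category name lists.

    ``common``: categories enriched at all four time points.
    ``serum_specific``: categories at T12 or T24 absent from the pre-serum
    union (Pre ∪ T0).  Names are compared case-insensitively after
    whitespace normalization.
    """
    required = {"Pre", "T0", "T12", "T24"}
    missing = required - set(lists)
    if missing:
        raise ValueError(f"missing time point list(s): {sorted(missing)}")
    norm = {tp: {_norm_name(c) for c in lists[tp]} for tp in required}
    if mode == "common":
        return set.intersection(*(norm[tp] for tp in ("Pre", "T0", "T12", "T24")))
    if mode == "serum_specific":
        if timepoint not in {"T12", "T24"}:
            raise ValueError("serum_specific requires timepoint T12 or T24")
        early = norm["Pre"] | norm["T0"]
        return norm[timepoint] - early
    raise ValueError(f"unknown mode {mode!r}")
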