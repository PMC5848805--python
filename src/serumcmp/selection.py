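"""Molecular-evolution tests: dN/dS gene-set analysis and a promoter
substitution-rate test.

Coding selection: per-gene dN/dS (isoform with the highest dN), the
fraction of a focal gene set with dN/dS > 1 versus all genes (Fisher's
exact test), and dN percentiles.  Genes with dS = 0 cannot form the ratio
and are reported separately.

Regulatory selection: for a human/chimpanzee/macaque alignment (macaque as
outgroup), a column counts as a human-branch substitution when human
differs from chimpanzee and macaque agrees with chimpanzee (parsimony).
Promoter (5 kb upstream, strand-aware) counts are compared with nearby
intronic counts — the neutral yardstick — by a one-sided binomial
likelihood-ratio test; a promoter is flagged as positively selected when
its human-branch rate significantly exceeds the intron rate (p <= 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubstitutionRecord",
    "BranchCounts",
    "collapse_isoforms",
    "positive_fraction_test",
    "dn_percentile",
    "lineage_substitution_counts",
    "promoter_rate_lrt",
]


@dataclass(frozen=True)
class SubstitutionRecord:
    gene: str
    isoform: str
    dn: float
    ds: float

    def __post_init__(self) -> None:
        if self.dn < 0 or self.ds < 0:
            raise ValueError("dN and dS must be non-negative")


@dataclass(frozen=True)
class BranchCounts:
    gene: str
    region: str  # "promoter" or "intron"
    k: int  # human-branch substitutions
    length: int  # aligned ungapped sites

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("aligned length must be positive")
        if not 0 <= self.k <= self.length:
            raise ValueError("substitution count outside [0, L]")

    @property
    def rate(self) -> float:
        return self.k / self.length


def collapse_isoforms(records: list[SubstitutionRecord]) -> dict[str, SubstitutionRecord]:
    """Keep, per gene, the isoform with the highest dN.

    Ties on dN go to the higher dS, then the lexicographically smaller
    isoform id, so the choice is deterministic.
    """
    best: dict[str, SubstitutionRecord] = {}
    for rec in sorted(records, key=lambda r: (r.gene, -r.dn, -r.ds, r.isoform)):
        best.setdefault(rec.gene, rec)
    return best


def _is_positive(rec: SubstitutionRecord) -> bool:
    return rec.ds > 0 and rec.dn / rec.ds > 1.0


def positive_fraction_test(
    per_gene: dict[str, SubstitutionRecord],
    focal_set: set[str],
    construction: str = "complement",
) -> dict:
    """Fraction of genes with dN/dS > 1 in a focal set vs the rest.

    A gene is "positive" iff dS > 0 and dN/dS > 1; dS = 0 genes are counted
    separately (the ratio is undefined for them) and excluded from both
    numerator and denominator.  Percentages are reported to 2 decimals.
    The 2x2 Fisher table is focal vs non-focal complement by default;
    ``construction="superset"`` compares the focal set against all genes.
    """
    focal = set(focal_set) & set(per_gene)
    if not focal:
        raise ValueError("empty focal set (no focal gene has a record)")
    ratio_defined = {g: r for g, r in per_gene.items() if r.ds > 0}
    n_ds_zero = len(per_gene) - len(ratio_defined)

    focal_def = [g for g in ratio_defined if g in focal]
    pos_focal = sum(_is_positive(ratio_defined[g]) for g in focal_def)
    pos_all = sum(_is_positive(r) for r in ratio_defined.values())
    n_focal, n_all = len(focal_def), len(ratio_defined)

    if construction == "complement":
        other_pos = pos_all - pos_focal
        other_n = n_all - n_focal
        table = [[pos_focal, n_focal - pos_focal], [other_pos, other_n - other_pos]]
    elif construction == "superset":
        table = [[pos_focal, n_focal - pos_focal], [pos_all, n_all - pos_all]]
    else:
        raise ValueError(f"unknown construction {construction!r}")
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")

    return {
        "n_focal": n_focal,
        "n_all": n_all,
        "positive_focal": pos_focal,
        "positive_all": pos_all,
        "frac_focal_pct": round(100.0 * pos_focal / n_focal, 2) if n_focal else np.nan,
        "frac_all_pct": round(100.0 * pos_all / n_all, 2) if n_all else np.nan,
        "n_ds_zero": n_ds_zero,
        "fisher_p": float(fisher_p),
        "table": table,
    }


def dn_percentile(gene: str, per_gene: dict[str, SubstitutionRecord]) -> float:
    """Percentile of a gene's dN: 100 * #(dN <= gene's dN) / n genes."""
    if len(per_gene) < 2:
        raise ValueError("need at least 2 genes")
    if gene not in per_gene:
        raise KeyError(f"gene {gene!r} has no record")
    target = per_gene[gene].dn
    n_le = sum(1 for r in per_gene.values() if r.dn <= target)
    return 100.0 * n_le / len(per_gene)


_VALID = frozenset("ACGT")


def lineage_substitution_counts(
    human: str, chimp: str, macaque: str, gene: str, region: str
) -> BranchCounts:
    """Human-branch substitutions by outgroup parsimony.

    Columns with a gap or ambiguous base in any taxon are skipped entirely
    (excluded from L).  A column is a human-branch substitution iff human
    differs from chimpanzee while macaque agrees with chimpanzee; columns
    where all three disagree are not parsimony-informative for the human
    branch and do not count.
    """
    if not len(human) == len(chimp) == len(macaque):
        raise ValueError(
            f"alignment length mismatch for {gene}/{region}: "
            f"{len(human)}/{len(chimp)}/{len(macaque)}"
        )
    k = 0
    length = 0
    for h, c, m in zip(human.upper(), chimp.upper(), macaque.upper()):
        if h not in _VALID or c not in _VALID or m not in _VALID:
            continue
        length += 1
        if h != c and m == c:
            k += 1
    if length == 0:
        raise ValueError(f"no ungapped ACGT columns for {gene}/{region}")
    return BranchCounts(gene=gene, region=region, k=k, length=length)


def _binom_loglik(k: int, n: int, p: float) -> float:
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return k * np.log(p) + (n - k) * np.log1p(-p)


def promoter_rate_lrt(
    promoter: BranchCounts,
    intron: BranchCounts,
    alpha: float = 0.01,
) -> tuple[float, float, bool]:
    """One-sided binomial LRT: promoter rate above the intronic rate?

    Null: one shared substitution probability (k_p+k_i)/(L_p+L_i).
    Alternative: separate MLE rates.  LRT = 2(l1 - l0) ~ chi2_1; the
    one-sided p halves the chi-square tail when the promoter rate exceeds
    the intron rate and is 1 - half-tail otherwise.  Selected iff
    p <= alpha and promoter rate > intron rate.
    """
    kp, lp = promoter.k, promoter.length
    ki, li = intron.k, intron.length
    p_null = (kp + ki) / (lp + li)
    ll0 = _binom_loglik(kp, lp, p_null) + _binom_loglik(ki, li, p_null)
    ll1 = _binom_loglik(kp, lp, kp / lp) + _binom_loglik(ki, li, ki / li)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    if promoter.rate > intron.rate:
        # one-sided: halve the chi-square tail (boundary mixture 0.5*chi2_0
        # + 0.5*chi2_1 under the null)
        p = float(0.5 * stats.chi2.sf(lrt, df=1))
    else:
        p = 1.0  # deviation in the unselected direction
    selected = bool(p <= alpha and promoter.rate > intron.rate)
    return float(lrt), p, selected


def selection_summary(
    lrt_results: dict[str, tuple[float, float, bool]]
) -> dict:
    """Fraction of promoters flagged as positively selected."""
    n = len(lrt_results)
    n_sel = sum(1 for _, _, s in lrt_results.values() if s)
    return {
        "n_genes": n,
        "n_selected": n_sel,
        "selected_pct": round(100.0 * n_sel / n, 2) if n else np.nan,
    }
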