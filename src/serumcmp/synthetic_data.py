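"""Synthetic fixture generation for the serum-challenge pipeline.

Emulates the statistical structure of a two-species fibroblast
serum-challenge experiment so every downstream stage runs without any
external download: negative-binomial ortholog read counts over a
four-time-point design (Pre, T0, T12, T24; four human and three chimpanzee
replicates), serum-responsive up/down gene sets, per-sample DHS peak lists
with planted shared/species-specific windows and opening/closing score
trajectories, and three-taxon promoter/intron alignments with optional
elevated human-branch promoter substitution rates.  Every generator returns
a truth table for recovery tests, and everything is deterministic given the
config seed.

Counts are NB with variance mu + phi*mu^2 (one global dispersion with
per-gene jitter); coordinates are 0-based half-open; library sizes are
log-normal (sigma = 0.2) so normalization is actually exercised.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dhs_windows import Peak
from .expression import CountMatrix
from .gene_linking import GeneAnnotation

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "default_design",
    "simulate_expression",
    "simulate_dhs",
    "simulate_alignments",
    "simulate_coupled_gene_dhs",
    "write_fixture_bundle",
]

TIMES = ("Pre", "T0", "T12", "T24")


def default_design(
    n_human: int = 4, n_chimp: int = 3
) -> list[tuple[str, str, str]]:
    """Species x time x replicate design: 4 human + 3 chimpanzee replicates
    at each of Pre, T0, T12, T24."""
    design = []
    for t in TIMES:
        for r in range(1, n_human + 1):
            design.append(("human", t, f"H{r}"))
        for r in range(1, n_chimp + 1):
            design.append(("chimpanzee", t, f"C{r}"))
    return design


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    Sharing fractions follow the proportions observed among the 264,091
    harmonized fibroblast windows (shared 0.475, human-only 0.363,
    chimpanzee-only 0.162) and must sum to 1.
    """

    n_genes: int = 2000
    n_windows: int = 1000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000}
    )
    design: list[tuple[str, str, str]] = field(default_factory=default_design)
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    frac_csr_up: float = 0.05
    frac_csr_down: float = 0.05
    frac_shared_windows: float = 0.475
    frac_speciesA_only: float = 0.363
    frac_speciesB_only: float = 0.162
    frac_opening: float = 0.3
    frac_closing: float = 0.3
    jitter_bp: int = 20
    peak_score_threshold: float = 50.0  # -10*log10(1e-5)
    promoter_len: int = 5000
    intron_len: int = 5000
    neutral_sub_rate: float = 0.01
    promoter_rate_multiplier: float = 5.0
    frac_selected: float = 0.1
    n_alignment_genes: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for name in (
            "frac_de",
            "frac_csr_up",
            "frac_csr_down",
            "frac_shared_windows",
            "frac_speciesA_only",
            "frac_speciesB_only",
            "frac_opening",
            "frac_closing",
            "frac_selected",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        share_sum = (
            self.frac_shared_windows
            + self.frac_speciesA_only
            + self.frac_speciesB_only
        )
        if abs(share_sum - 1.0) > 1e-12:
            raise ValueError(f"sharing fractions must sum to 1, got {share_sum}")
        if self.frac_opening + self.frac_closing > 1.0 + 1e-12:
            raise ValueError("frac_opening + frac_closing must not exceed 1")
        for name in ("promoter_len", "intron_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")
        if self.neutral_sub_rate < 0:
            raise ValueError("neutral_sub_rate must be non-negative")
        if self.frac_selected > 0 and self.promoter_rate_multiplier < 1:
            raise ValueError(
                "promoter_rate_multiplier < 1 contradicts planted positive selection"
            )


@dataclass
class TruthTable:
    """Planted ground truth: per-gene DE status, per-window class and
    trajectory, per-gene promoter-selection flag."""

    genes: pd.DataFrame | None = None
    windows: pd.DataFrame | None = None
    promoters: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_TIME_RAMP = {"Pre": 0.0, "T0": 0.0, "T12": 1.0, "T24": 1.0}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB with variance mu + phi*mu^2 via its gamma-Poisson mixture."""
    shape = 1.0 / phi
    lam = rng.gamma(shape=shape, scale=mean * phi)
    return rng.poisson(lam)


def gene_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Deterministic TSS placement: genes evenly spaced along chromosomes,
    alternating strand."""
    chroms = sorted(config.chrom_sizes)
    anns = []
    per_chrom = int(np.ceil(config.n_genes / len(chroms)))
    g = 0
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        step = max(size // (per_chrom + 1), 1)
        for i in range(per_chrom):
            if g >= config.n_genes:
                break
            anns.append(
                GeneAnnotation(
                    gene=f"g{g:05d}",
                    chrom=chrom,
                    tss=(i + 1) * step,
                    strand="+" if g % 2 == 0 else "-",
                )
            )
            g += 1
    return anns


def simulate_expression(
    config: SimulationConfig,
) -> tuple[CountMatrix, TruthTable]:
    """NB ortholog counts with planted species effects and serum-response
    (CSR-like) time effects.

    A ``frac_de`` share of genes carries a between-species log2 fold-change
    of ``planted_log2fc`` (alternating sign).  Disjoint CSR-up/-down gene
    sets shift expression after serum replacement (T12/T24) by the same
    magnitude, up or down, in both species.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = [f"g{i:05d}" for i in range(g)]
    samples = list(config.design)
    n = len(samples)

    # lognormal draws centered so E[base] = baseline_mean, E[lib_factor] = 1
    base = config.baseline_mean * rng.lognormal(mean=-0.5, sigma=1.0, size=g)
    phi = config.nb_dispersion * rng.lognormal(mean=-0.03125, sigma=0.25, size=g)
    lib_factor = rng.lognormal(mean=-0.02, sigma=0.2, size=n)

    n_de = int(round(config.frac_de * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    species_lfc = np.zeros(g)
    species_lfc[de_idx] = np.where(
        np.arange(n_de) % 2 == 0, config.planted_log2fc, -config.planted_log2fc
    )

    remaining = np.setdiff1d(np.arange(g), de_idx)
    n_up = int(round(config.frac_csr_up * g))
    n_down = int(round(config.frac_csr_down * g))
    csr_pick = rng.choice(remaining, size=min(n_up + n_down, remaining.size), replace=False)
    csr_up_idx = csr_pick[:n_up]
    csr_down_idx = csr_pick[n_up : n_up + n_down]
    time_lfc = np.zeros(g)
    time_lfc[csr_up_idx] = abs(config.planted_log2fc)
    time_lfc[csr_down_idx] = -abs(config.planted_log2fc)

    mean = np.empty((g, n))
    for j, (sp, t, _rep) in enumerate(samples):
        lfc = time_lfc * _TIME_RAMP[t]
        if sp == "human":
            lfc = lfc + species_lfc  # positive planted lfc = higher in human
        mean[:, j] = base * (2.0 ** lfc) * lib_factor[j]

    counts = _nb_draw(rng, mean, phi[:, None])
    cm = CountMatrix(genes=genes, samples=samples, counts=counts)

    truth = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base,
            "is_de": np.isin(np.arange(g), de_idx),
            "true_log2fc": species_lfc,
            "csr_set": [
                "up" if i in set(csr_up_idx) else ("down" if i in set(csr_down_idx) else "none")
                for i in range(g)
            ],
        }
    )
    return cm, TruthTable(genes=truth)


def csr_gene_sets(truth: TruthTable) -> dict[str, set[str]]:
    """The planted serum-response gene sets as a GMT-ready mapping."""
    t = truth.genes
    return {
        "CSR_UP": set(t.loc[t["csr_set"] == "up", "gene"]),
        "CSR_DOWN": set(t.loc[t["csr_set"] == "down", "gene"]),
    }


# ---------------------------------------------------------------------------
# DHS peaks and windows
# ---------------------------------------------------------------------------

_PROFILE = {
    # multiplicative score trajectory over (Pre, T0, T12, T24)
    "opening": np.array([1.0, 1.0, 2.5, 4.0]),
    "closing": np.array([1.0, 1.0, 0.4, 0.25]),
    "flat": np.array([1.0, 1.0, 1.0, 1.0]),
}


def _place_windows(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Non-overlapping planted intervals with inter-window gaps wide enough
    that +/- jitter cannot merge neighbours."""
    min_gap = 4 * config.jitter_bp + 60
    widths = rng.integers(100, 601, size=config.n_windows)
    total_needed = int(widths.sum()) + config.n_windows * (min_gap + 200)
    if total_needed > sum(config.chrom_sizes.values()):
        raise ValueError(
            f"chrom_sizes too small to place {config.n_windows} windows "
            f"without overlap (need ~{total_needed} bp)"
        )
    chroms = sorted(config.chrom_sizes)
    placements = []
    i = 0
    for chrom in chroms:
        pos = 1000
        size = config.chrom_sizes[chrom]
        while i < config.n_windows:
            w = int(widths[i])
            gap = min_gap + int(rng.integers(0, 201))
            if pos + w + gap > size - 1000:
                break
            placements.append((chrom, pos, pos + w))
            pos += w + gap
            i += 1
    if i < config.n_windows:
        raise ValueError(
            f"chrom_sizes too small: placed only {i} of {config.n_windows} windows"
        )
    return placements


def simulate_dhs(
    config: SimulationConfig,
) -> tuple[list[Peak], CountMatrix, TruthTable]:
    """Per-sample peak lists with planted sharing classes and trajectories.

    Shared windows emit peaks in both species, species-specific windows in
    one.  Opening windows ramp their score up after serum replacement,
    closing windows ramp down — and drop below the calling threshold, so
    the peak disappears (scores below the threshold are never emitted).
    Peak boundaries are jittered +/- ``jitter_bp`` per sample; window-level
    read counts are NB with mean proportional to the underlying score.
    """
    rng = np.random.default_rng(config.seed + 1)
    placements = _place_windows(config, rng)
    nw = len(placements)

    class_labels = rng.permutation(
        np.repeat(
            ["shared", "human_specific", "chimpanzee_specific"],
            _partition_counts(
                nw,
                [
                    config.frac_shared_windows,
                    config.frac_speciesA_only,
                    config.frac_speciesB_only,
                ],
            ),
        )
    )
    traj_labels = rng.permutation(
        np.repeat(
            ["opening", "closing", "flat"],
            _partition_counts(
                nw,
                [
                    config.frac_opening,
                    config.frac_closing,
                    1.0 - config.frac_opening - config.frac_closing,
                ],
            ),
        )
    )

    base_score = rng.uniform(90.0, 160.0, size=nw)
    samples = list(config.design)
    peaks: list[Peak] = []
    window_names = [f"{c}:{s}-{e}" for c, s, e in placements]
    time_index = {t: k for k, t in enumerate(TIMES)}

    score_truth = np.zeros((nw, len(samples)))
    for j, (sp, t, _rep) in enumerate(samples):
        for i, (chrom, start, end) in enumerate(placements):
            cls = class_labels[i]
            if cls == "human_specific" and sp != "human":
                continue
            if cls == "chimpanzee_specific" and sp != "chimpanzee":
                continue
            profile = _PROFILE[traj_labels[i]][time_index[t]]
            score = base_score[i] * profile * rng.lognormal(0.0, 0.15)
            if score < config.peak_score_threshold:
                continue  # below the calling threshold: no peak in this sample
            jit = config.jitter_bp
            js = int(rng.integers(-jit, jit + 1)) if jit else 0
            je = int(rng.integers(-jit, jit + 1)) if jit else 0
            ps, pe = start + js, end + je
            if pe - ps < 20:
                pe = ps + 20
            peaks.append(
                Peak(chrom=chrom, start=ps, end=pe, score=round(float(score), 4), sample=(sp, t, _rep))
            )
            score_truth[i, j] = score

    # window-level read counts tracking the underlying (uncensored) score
    count_scale = 2.0
    mean = np.zeros((nw, len(samples)))
    for j, (sp, t, _rep) in enumerate(samples):
        for i in range(nw):
            cls = class_labels[i]
            active = not (
                (cls == "human_specific" and sp != "human")
                or (cls == "chimpanzee_specific" and sp != "chimpanzee")
            )
            if active:
                mean[i, j] = (
                    base_score[i] * _PROFILE[traj_labels[i]][time_index[t]] * count_scale
                )
            else:
                mean[i, j] = 1.0  # background
    counts = _nb_draw(rng, np.maximum(mean, 0.1), np.full((nw, 1), config.nb_dispersion))
    window_counts = CountMatrix(genes=window_names, samples=samples, counts=counts)

    truth = pd.DataFrame(
        {
            "window": window_names,
            "chrom": [c for c, _, _ in placements],
            "start": [s for _, s, _ in placements],
            "end": [e for _, _, e in placements],
            "sharing_class": class_labels,
            "trajectory": traj_labels,
        }
    )
    return peaks, window_counts, TruthTable(windows=truth)


def _partition_counts(n: int, fractions: list[float]) -> list[int]:
    """Integer class sizes summing exactly to n (largest-remainder)."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def match_windows_to_truth(
    window_names: list[str], truth: pd.DataFrame, margin: int = 40
) -> pd.Series:
    """Map harmonized (possibly jitter-shifted) windows back to planted
    truth rows by midpoint containment, for recovery scoring.

    Returns a Series window name -> planted window name (NaN if unmatched).
    The margin absorbs boundary jitter.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for _, r in truth.iterrows():
        by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"], r["window"]))
    for ivs in by_chrom.values():
        ivs.sort()
    out = {}
    for name in window_names:
        chrom, rest = name.split(":")
        s, e = (int(v) for v in rest.split("-"))
        mid = (s + e) / 2.0
        match = np.nan
        for ps, pe, pname in by_chrom.get(chrom, ()):
            if ps - margin <= mid <= pe + margin:
                match = pname
                break
            if ps - margin > mid:
                break
        out[name] = match
    return pd.Series(out, name="planted_window")


# ---------------------------------------------------------------------------
# three-taxon alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = (seq[hit] + shift) % 4
    return out


def simulate_alignments(
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, dict[str, str]]], TruthTable]:
    """Promoter and intron alignments on the fixed ((human,chimp),macaque)
    topology.

    Substitutions are placed independently per branch at
    ``neutral_sub_rate`` per site; genes flagged as selected get
    ``promoter_rate_multiplier`` times that rate on the human promoter
    branch only.  Returns ``alignments[gene][region][taxon] -> sequence``.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_alignment_genes
    genes = [f"g{i:05d}" for i in range(n)]
    n_sel = int(round(config.frac_selected * n))
    sel_idx = set(rng.choice(n, size=n_sel, replace=False).tolist())

    alignments: dict[str, dict[str, dict[str, str]]] = {}
    flags = []
    for i, gene in enumerate(genes):
        selected = i in sel_idx
        flags.append(selected)
        alignments[gene] = {}
        for region, length in (("promoter", config.promoter_len), ("intron", config.intron_len)):
            root = rng.integers(0, 4, size=length)
            hc_anc = _mutate(rng, root, config.neutral_sub_rate)
            h_rate = config.neutral_sub_rate
            if selected and region == "promoter":
                h_rate *= config.promoter_rate_multiplier
            human = _mutate(rng, hc_anc, h_rate)
            chimp = _mutate(rng, hc_anc, config.neutral_sub_rate)
            macaque = _mutate(rng, root, config.neutral_sub_rate)
            alignments[gene][region] = {
                "human": "".join(_BASES[human]),
                "chimpanzee": "".join(_BASES[chimp]),
                "macaque": "".join(_BASES[macaque]),
            }
    truth = pd.DataFrame({"gene": genes, "promoter_selected": flags})
    return alignments, TruthTable(promoters=truth)


# ---------------------------------------------------------------------------
# coupled gene/DHS fixture (for correlation recovery tests)
# ---------------------------------------------------------------------------


def simulate_coupled_gene_dhs(
    n: int, spearman_rho: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (total DHS signal, expression) values with a target Spearman
    correlation via a Gaussian copula; marginals are monotone transforms,
    which Spearman ignores."""
    r = 2.0 * np.sin(np.pi * spearman_rho / 6.0)  # Pearson r giving rho_s
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    dhs = 50.0 * np.exp(0.5 * z[:, 0])  # score-like, positive
    expr = np.exp(1.0 + 0.8 * z[:, 1])  # count-like, positive
    return dhs, expr


# ---------------------------------------------------------------------------
# fixture bundle serialization
# ---------------------------------------------------------------------------


def write_fixture_bundle(directory: str | Path, config: SimulationConfig) -> dict:
    """Generate everything and write a self-describing fixture bundle.

    Layout: counts.tsv + design.tsv (expression), truth_genes.tsv,
    gene_sets.gmt, annotation.bed, peaks/<sample>.bed, window_counts.tsv,
    truth_windows.tsv, alignments/<region>.fasta, truth_promoters.tsv and a
    manifest.json listing every file with its sha256 checksum.
    """
    from . import io as pkg_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    cm, truth_expr = simulate_expression(config)
    pkg_io.write_counts(directory / "counts.tsv", cm)
    pkg_io.write_design(directory / "design.tsv", cm.samples)
    truth_expr.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    files += [directory / "counts.tsv", directory / "design.tsv", directory / "truth_genes.tsv"]

    sets = csr_gene_sets(truth_expr)
    pkg_io.write_gmt(directory / "gene_sets.gmt", sets)
    files.append(directory / "gene_sets.gmt")

    anns = gene_annotation(config)
    pkg_io.write_annotation_bed(directory / "annotation.bed", anns)
    files.append(directory / "annotation.bed")

    peaks, window_counts, truth_dhs = simulate_dhs(config)
    peak_dir = directory / "peaks"
    peak_dir.mkdir(exist_ok=True)
    by_sample: dict[tuple[str, str, str], list[Peak]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample, []).append(p)
    for sample in sorted(by_sample):
        path = peak_dir / ("_".join(sample) + ".bed")
        pkg_io.write_peaks_bed(path, by_sample[sample])
        files.append(path)
    pkg_io.write_counts(directory / "window_counts.tsv", window_counts)
    truth_dhs.windows.to_csv(directory / "truth_windows.tsv", sep="\t", index=False)
    files += [directory / "window_counts.tsv", directory / "truth_windows.tsv"]

    alignments, truth_sel = simulate_alignments(config)
    aln_dir = directory / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for region in ("promoter", "intron"):
        path = aln_dir / f"{region}.fasta"
        pkg_io.write_alignments_fasta(path, alignments, region)
        files.append(path)
    truth_sel.promoters.to_csv(directory / "truth_promoters.tsv", sep="\t", index=False)
    files.append(directory / "truth_promoters.tsv")

    manifest = {
        "config": {
            k: (v if not isinstance(v, list) else [list(s) for s in v])
            for k, v in vars(config).items()
        },
        "files": {
            str(f.relative_to(directory)): _sha256(f) for f in files
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()
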