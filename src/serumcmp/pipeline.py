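"""End-to-end orchestration of the serum-challenge comparative analysis.

Stages run in order — simulate, expression, enrichment, windows,
clustering, linking, selection — each writing tab-separated tables plus a
single JSON report with the headline summaries: per-time-point
differential-expression counts (higher-in-human / higher-in-chimpanzee,
totals, ratios), enrichment tables, window sharing-class counts,
trajectory-cluster gene ratios, DHS/expression correlations, and
positive-selection results.  All randomness flows from the single
configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pkg_io
from .dhs_windows import (
    build_windows,
    differential_windows,
    directional_balance_test,
    score_and_classify,
    score_matrix,
    sharing_class_counts,
    windows_to_frame,
)
from .enrichment import GeneSetCollection, RankedList, gsea_collection
from .expression import (
    CountMatrix,
    de_test,
    results_to_frame,
    summarize_de_counts,
    tmm_factors,
)
from .fuzzy_clustering import (
    choose_cluster_number,
    estimate_fuzzifier,
    fuzzy_cmeans,
    standardize_profiles,
    trajectory_classes,
)
from .gene_linking import cluster_gene_summary, dhs_expression_correlation, nearest_tss
from .selection import (
    lineage_substitution_counts,
    promoter_rate_lrt,
    selection_summary,
)
from .synthetic_data import SimulationConfig, TIMES, write_fixture_bundle

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Stage toggles, paths, and the thresholds applied throughout.

    Defaults follow the analysis conventions: expression FDR 0.10, window
    FDR 0.05, fuzzy membership minimum 0.6, window size limits 50–2,000 bp,
    promoter-selection alpha 0.01.
    """

    out_dir: str = "results"
    fixture_dir: str | None = None  # simulate into out_dir/fixture when None
    seed: int = 0
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "expression",
            "enrichment",
            "windows",
            "clustering",
            "linking",
            "selection",
        ]
    )
    fdr_expression: float = 0.10
    fdr_windows: float = 0.05
    membership_min: float = 0.6
    window_min: int = 50
    window_max: int = 2000
    gsea_perms: int = 200
    alpha_selection: float = 0.01
    cluster_range: tuple[int, int] = (2, 8)
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        for name in ("fdr_expression", "fdr_windows", "membership_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 < self.window_min <= self.window_max:
            raise ValueError("window size limits must satisfy 0 < min <= max")
        if not 0.0 < self.alpha_selection < 1.0:
            raise ValueError("alpha_selection must lie in (0, 1)")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "seed": cfg.seed,
        "fdr_expression": cfg.fdr_expression,
        "fdr_windows": cfg.fdr_windows,
        "membership_min": cfg.membership_min,
        "window_min": cfg.window_min,
        "window_max": cfg.window_max,
        "gsea_perms": cfg.gsea_perms,
        "alpha_selection": cfg.alpha_selection,
        "stages": cfg.stages,
    }}

    if not cfg.stages:
        _write_report(out, report)
        return report

    fixture = Path(cfg.fixture_dir) if cfg.fixture_dir else out / "fixture"
    sim = cfg.simulation or SimulationConfig(seed=cfg.seed)

    if "simulate" in cfg.stages:
        logger.info("simulating fixture bundle into %s", fixture)
        write_fixture_bundle(fixture, sim)
        report["simulate"] = {"fixture_dir": str(fixture)}
    elif any(
        s in cfg.stages
        for s in ("expression", "enrichment", "windows", "clustering", "linking", "selection")
    ) and not fixture.exists():
        raise FileNotFoundError(
            f"input fixture {fixture} missing and the simulate stage is disabled"
        )

    cm = de_by_time = None
    if "expression" in cfg.stages:
        cm = pkg_io.parse_counts(fixture / "counts.tsv")
        logger.info("expression: %d genes x %d samples, FDR %.2f",
                    cm.n_genes, cm.n_samples, cfg.fdr_expression)
        factors = tmm_factors(cm)
        species_groups = [s[0] for s in cm.samples]
        de_by_time = {}
        for t in TIMES:
            mask = np.array([s[1] == t for s in cm.samples])
            sub = cm.subset_samples(mask)
            res = de_test(
                sub,
                [s[0] for s in sub.samples],
                ("human", "chimpanzee"),
                norm_factors=factors[mask] / np.exp(np.mean(np.log(factors[mask]))),
                fdr_threshold=cfg.fdr_expression,
            )
            de_by_time[t] = res
            results_to_frame(res).to_csv(out / f"de_{t}.tsv", sep="\t", index=False)
        summary = summarize_de_counts(
            de_by_time, label_a="higher_in_human", label_b="higher_in_chimpanzee"
        )
        summary.to_csv(out / "de_summary.tsv", sep="\t")
        report["expression"] = json.loads(summary.to_json())

    if "enrichment" in cfg.stages:
        if cm is None:
            cm = pkg_io.parse_counts(fixture / "counts.tsv")
        sets = GeneSetCollection(pkg_io.parse_gmt(fixture / "gene_sets.gmt"))
        # within-species serum response T0 -> T12 ranking (human)
        human_mask = np.array([s[0] == "human" for s in cm.samples])
        sub = cm.subset_samples(human_mask)
        res = de_test(sub, [s[1] for s in sub.samples], ("T12", "T0"))
        rl = RankedList.from_de_results(res)
        gsea = gsea_collection(
            rl, sets, n_perm=cfg.gsea_perms, seed=cfg.seed + 10
        )
        gsea.to_csv(out / "gsea.tsv", sep="\t", index=False)
        report["enrichment"] = gsea.drop(columns="leading_edge").to_dict("records")

    windows = labels = links = profiles = None
    if "windows" in cfg.stages:
        peak_files = sorted((fixture / "peaks").glob("*.bed"))
        peaks = []
        for f in peak_files:
            sample = tuple(f.stem.split("_"))
            peaks.extend(pkg_io.parse_peaks_bed(f, sample))
        logger.info("windows: %d peaks from %d samples; size filter [%d, %d] bp",
                    len(peaks), len(peak_files), cfg.window_min, cfg.window_max)
        windows = build_windows(peaks, min_len=cfg.window_min, max_len=cfg.window_max)
        windows = score_and_classify(windows, peaks)
        counts = sharing_class_counts(windows)
        windows_to_frame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
        report["windows"] = counts

        wc = pkg_io.parse_counts(fixture / "window_counts.tsv")
        diff_by_time = {}
        for t in ("T0", "T24"):
            mask = np.array([s[1] == t for s in wc.samples])
            sub = wc.subset_samples(mask)
            res = differential_windows(
                sub, [s[0] for s in sub.samples], ("human", "chimpanzee"), fdr=cfg.fdr_windows
            )
            diff_by_time[t] = res
        dsum = summarize_de_counts(
            diff_by_time, label_a="higher_in_human", label_b="higher_in_chimpanzee"
        )
        dsum.to_csv(out / "dhs_diff_summary.tsv", sep="\t")
        report["differential_windows"] = json.loads(dsum.to_json())
        n_a = int(dsum.loc["higher_in_human"].sum())
        n_b = int(dsum.loc["higher_in_chimpanzee"].sum())
        if n_a + n_b > 0:
            report["directional_balance_p"] = directional_balance_test(n_a, n_b)

    if "clustering" in cfg.stages:
        if windows is None:
            raise ValueError("clustering requires the windows stage")
        all_samples = sorted({s for w in windows for s in w.scores})
        scores = score_matrix(windows, all_samples)
        rep_map = {"_".join(s): (s[0], s[1]) for s in all_samples}
        report["clustering"] = {}
        labels = {}
        profiles = {}
        for species in ("human", "chimpanzee"):
            pm = standardize_profiles(scores, rep_map, species, list(TIMES))
            m = estimate_fuzzifier(pm)
            c, dmin = choose_cluster_number(
                pm, cfg.cluster_range, m, seed=cfg.seed + 20
            )
            fc = fuzzy_cmeans(pm, c, m, seed=cfg.seed + 21)
            lab = trajectory_classes(fc, pm, membership_min=cfg.membership_min)
            labels[species] = lab
            profiles[species] = pm
            lab.to_frame().to_csv(out / f"trajectories_{species}.tsv", sep="\t")
            report["clustering"][species] = {
                "fuzzifier": round(m, 4),
                "chosen_c": c,
                "dmin": {str(k): round(v, 4) for k, v in dmin.items()},
                "n_profiles": pm.n,
                "n_dropped_constant": pm.n_dropped,
                "label_counts": lab.value_counts().to_dict(),
            }

    if "linking" in cfg.stages:
        if windows is None or labels is None:
            raise ValueError("linking requires the windows and clustering stages")
        anns = pkg_io.parse_annotation_bed(fixture / "annotation.bed")
        links = nearest_tss(windows, anns)
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        report["linking"] = {}
        for species, lab in labels.items():
            summary = cluster_gene_summary(lab, links)
            report["linking"][species] = summary.to_dict("records")
        if cm is None:
            cm = pkg_io.parse_counts(fixture / "counts.tsv")
        all_samples = sorted({s for w in windows for s in w.scores})
        scores = score_matrix(windows, all_samples)
        t24_cols = [c for c in scores.columns if c.split("_")[1] == "T24" and c.startswith("human")]
        if t24_cols:
            per_window = scores[t24_cols].mean(axis=1)
            try:
                rho, p = dhs_expression_correlation(
                    per_window, links, cm, time="T24", species="human"
                )
                report["linking"]["dhs_expression_spearman_T24"] = {
                    "rho": round(rho, 4), "p": p
                }
            except ValueError as exc:
                report["linking"]["dhs_expression_spearman_T24"] = str(exc)

    if "selection" in cfg.stages:
        proms = pkg_io.parse_alignments_fasta(fixture / "alignments" / "promoter.fasta")
        introns = pkg_io.parse_alignments_fasta(fixture / "alignments" / "intron.fasta")
        lrt_results = {}
        rows = []
        for gene in sorted(proms):
            bp = lineage_substitution_counts(
                proms[gene]["human"], proms[gene]["chimpanzee"], proms[gene]["macaque"],
                gene, "promoter",
            )
            bi = lineage_substitution_counts(
                introns[gene]["human"], introns[gene]["chimpanzee"], introns[gene]["macaque"],
                gene, "intron",
            )
            lrt, p, sel = promoter_rate_lrt(bp, bi, alpha=cfg.alpha_selection)
            lrt_results[gene] = (lrt, p, sel)
            rows.append(
                {
                    "gene": gene,
                    "k_promoter": bp.k, "L_promoter": bp.length,
                    "k_intron": bi.k, "L_intron": bi.length,
                    "lrt": lrt, "p": p, "selected": sel,
                }
            )
        pd.DataFrame(rows).to_csv(out / "promoter_selection.tsv", sep="\t", index=False)
        report["selection"] = selection_summary(lrt_results)

    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
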