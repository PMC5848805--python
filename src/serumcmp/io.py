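"""Readers and writers for the pipeline's plain-text formats.

BED intervals are 0-based half-open and validated strictly (malformed
lines raise with their line number).  FASTA goes through Biopython;
JASPAR position-frequency matrices through Bio.motifs.  Count and design
tables are tab-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dhs_windows import Peak
from .expression import CountMatrix
from .gene_linking import GeneAnnotation, PWM

__all__ = [
    "parse_bed",
    "parse_peaks_bed",
    "parse_gmt",
    "parse_counts",
    "parse_design",
    "parse_fasta",
    "parse_annotation_bed",
    "parse_jaspar",
    "write_peaks_bed",
    "write_bed",
    "write_gmt",
    "write_counts",
    "write_design",
    "write_annotation_bed",
    "write_alignments_fasta",
    "parse_alignments_fasta",
]


def _bed_fields(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: end <= start ({fields[0]}:{start}-{end})"
                )
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            yield lineno, fields, start, end


def parse_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain intervals from a BED3+ file (half-open, validated)."""
    return [(f[0], s, e) for _, f, s, e in _bed_fields(path)]


def parse_peaks_bed(path: str | Path, sample: tuple[str, str, str]) -> list[Peak]:
    """Scored peaks (BED6: score in column 5 holds -10*log10 p)."""
    peaks = []
    for lineno, fields, start, end in _bed_fields(path):
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: peak BED needs a score column")
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
        peaks.append(Peak(chrom=fields[0], start=start, end=end, score=score, sample=sample))
    return peaks


def write_peaks_bed(path: str | Path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda q: (q.chrom, q.start, q.end)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.score:.4f}\t.\n")


def write_bed(path: str | Path, intervals: list[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def parse_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, members.  Duplicate names error."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, desc, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gmt(path: str | Path, sets: dict[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na"] + sorted(sets[name])) + "\n")


def parse_counts(path: str | Path) -> CountMatrix:
    """Genes x samples TSV with sample ids ``species_time_replicate``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = []
    for col in df.columns:
        parts = col.split("_")
        if len(parts) != 3:
            raise ValueError(f"sample id {col!r} is not species_time_replicate")
        samples.append(tuple(parts))
    return CountMatrix(
        genes=[str(g) for g in df.index],
        samples=samples,
        counts=df.to_numpy(),
    )


def write_counts(path: str | Path, cm: CountMatrix) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene")


def parse_design(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "species", "time", "replicate"}
    if not need <= set(df.columns):
        raise ValueError(f"design file must have columns {sorted(need)}")
    return [
        (str(r.species), str(r.time), str(r.replicate)) for r in df.itertuples()
    ]


def write_design(path: str | Path, samples: list[tuple[str, str, str]]) -> None:
    pd.DataFrame(
        {
            "sample": ["_".join(s) for s in samples],
            "species": [s[0] for s in samples],
            "time": [s[1] for s in samples],
            "replicate": [s[2] for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def parse_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_alignments_fasta(
    path: str | Path, alignments: dict[str, dict[str, dict[str, str]]], region: str
) -> None:
    """Three records per gene, ids ``gene|region|taxon``."""
    records = []
    for gene in sorted(alignments):
        for taxon, seq in alignments[gene][region].items():
            records.append(
                SeqRecord(Seq(seq), id=f"{gene}|{region}|{taxon}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def parse_alignments_fasta(path: str | Path) -> dict[str, dict[str, str]]:
    """Inverse of :func:`write_alignments_fasta` for one region file:
    returns ``{gene: {taxon: seq}}``."""
    out: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _region, taxon = rec.id.split("|")
        out.setdefault(gene, {})[taxon] = str(rec.seq).upper()
    return out


def parse_annotation_bed(path: str | Path) -> list[GeneAnnotation]:
    """Gene TSSs from BED6: strand-aware (minus-strand TSS = end - 1)."""
    anns = []
    for lineno, fields, start, end in _bed_fields(path):
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: annotation BED needs 6 fields")
        strand = fields[5]
        tss = start if strand == "+" else end - 1
        anns.append(
            GeneAnnotation(gene=fields[3], chrom=fields[0], tss=tss, strand=strand)
        )
    return anns


def write_annotation_bed(path: str | Path, anns: list[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        for a in sorted(anns, key=lambda x: (x.chrom, x.tss)):
            if a.strand == "+":
                start, end = a.tss, a.tss + 1
            else:
                start, end = a.tss, a.tss + 1  # 1-bp TSS feature; strand kept
            fh.write(f"{a.chrom}\t{start}\t{end}\t{a.gene}\t0\t{a.strand}\n")
    # note: for 1-bp features the strand-aware reader recovers the same TSS


def parse_jaspar(path: str | Path) -> list[PWM]:
    """JASPAR position-frequency matrices via Bio.motifs."""
    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(PWM(motif_id=m.matrix_id or m.name, matrix=mat))
    return out
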