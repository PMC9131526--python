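"""Annotation-derived features: gene-density tracks, external-track
re-binning, and homopolymeric amino-acid runs (HAARs) in proteomes.

Gene counting follows the split-gene rule: a gene overlapping several
windows contributes to every window it overlaps, so per-window counts sum
to at least the number of genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqfeats import FeatureTrack
from .windows import WindowGrid

log = logging.getLogger(__name__)

GENE_TYPES = ("mRNA", "tRNA", "rRNA", "pseudogene")


@dataclass
class GeneModel:
    """One gene: longest transcript's extent and exon structure.

    Coordinates are 0-based half-open. ``type`` is the transcript type
    (mRNA/tRNA/rRNA) or "pseudogene"; the legacy feature type
    "protein_coding_gene" is normalised to a gene with an mRNA transcript.
    """

    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    type: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:])]


def load_gff3(path, scaffold_lengths: dict[str, int] | None = None) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon hierarchy into GeneModels.

    One model per transcript-bearing gene (the longest transcript wins when
    a gene has several). Features lying outside the provided scaffold
    bounds raise ValueError naming the feature.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    gene_like = ("gene", "protein_coding_gene", "pseudogene")
    for gene in db.features_of_type(gene_like, order_by=("seqid", "start")):
        transcripts = list(db.children(gene, level=1))
        if gene.featuretype == "pseudogene":
            gtype = "pseudogene"
            best = max(transcripts, key=lambda t: t.end - t.start, default=gene)
        else:
            if not transcripts:
                raise ValueError(
                    f"{path}: gene {gene.id!r} has no transcript children"
                )
            best = max(transcripts, key=lambda t: t.end - t.start)
            gtype = best.featuretype if best.featuretype in GENE_TYPES else "mRNA"
        exons = [
            (e.start - 1, e.end)
            for e in sorted(db.children(best, featuretype="exon"), key=lambda e: e.start)
        ]
        start, end = best.start - 1, best.end
        if scaffold_lengths is not None:
            if gene.seqid not in scaffold_lengths:
                raise ValueError(
                    f"{path}: feature {gene.id!r} on unknown scaffold {gene.seqid!r}"
                )
            if start < 0 or end > scaffold_lengths[gene.seqid]:
                raise ValueError(
                    f"{path}: feature {gene.id!r} coordinates [{start},{end}) "
                    f"outside scaffold {gene.seqid!r}"
                )
        models.append(
            GeneModel(
                id=gene.id,
                scaffold=gene.seqid,
                start=start,
                end=end,
                strand=gene.strand or ".",
                type=gtype,
                exons=exons or [(start, end)],
            )
        )
    return models


GENE_TRACK_NAMES = (
    "mRNA_annotations",
    "tRNA_annotations",
    "rRNA_annotations",
    "pseudogene_annotations",
    "gene_length",
    "exon_count",
    "gene_average_exon_length",
    "gene_average_intron_length",
)


def gene_density_tracks(
    models: Sequence[GeneModel], grid: WindowGrid
) -> list[FeatureTrack]:
    """Per-window gene counts by type and per-gene structural means.

    A gene split across windows is counted in every window it overlaps.
    The length/exon/intron tracks are means over the genes counted in the
    window; windows with no genes score 0.
    """
    n = len(grid)
    counts = {t: np.zeros(n) for t in GENE_TYPES}
    sums = {k: np.zeros(n) for k in ("length", "exons", "exlen", "intlen")}
    ngenes = np.zeros(n)
    for gm in models:
        idx = grid.overlapping_windows(gm.scaffold, gm.start, gm.end)
        if len(idx) == 0:
            continue
        counts[gm.type][idx] += 1
        ngenes[idx] += 1
        sums["length"][idx] += gm.length
        sums["exons"][idx] += len(gm.exons)
        sums["exlen"][idx] += float(np.mean([e - s for s, e in gm.exons]))
        intr = gm.introns
        sums["intlen"][idx] += (
            float(np.mean([e - s for s, e in intr])) if intr else 0.0
        )
    with np.errstate(invalid="ignore"):
        denom = np.where(ngenes > 0, ngenes, 1.0)
    tracks = [
        FeatureTrack("mRNA_annotations", counts["mRNA"], "count"),
        FeatureTrack("tRNA_annotations", counts["tRNA"], "count"),
        FeatureTrack("rRNA_annotations", counts["rRNA"], "count"),
        FeatureTrack("pseudogene_annotations", counts["pseudogene"], "count"),
        FeatureTrack("gene_length", sums["length"] / denom, "bp"),
        FeatureTrack("exon_count", sums["exons"] / denom, "count"),
        FeatureTrack("gene_average_exon_length", sums["exlen"] / denom, "bp"),
        FeatureTrack("gene_average_intron_length", sums["intlen"] / denom, "bp"),
    ]
    return tracks


def read_bedgraph(path) -> pd.DataFrame:
    """Bedgraph intervals as a DataFrame (scaffold, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["scaffold", "start", "end", "value"],
        dtype={"scaffold": str},
        skiprows=_count_track_lines(path),
    )
    return df


def _count_track_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            elif not line.startswith("#"):
                break
    return n


def rebin_bedgraph(
    path, grid: WindowGrid, aggregator: str = "mean", name: str | None = None
) -> FeatureTrack:
    """Re-bin an external bedgraph track onto the window grid.

    ``mean``: length-weighted mean over the window, uncovered bases
    contributing 0. ``sum``: interval values summed, pro-rated by the
    fraction of each interval inside the window (suited to count tracks).
    Intervals running beyond the scaffold end are clipped with a warning.
    """
    if aggregator not in ("mean", "sum"):
        raise ValueError(f"aggregator must be 'mean' or 'sum', got {aggregator!r}")
    df = read_bedgraph(path)
    values = np.zeros(len(grid))
    for scaffold, sub in df.groupby("scaffold", sort=False):
        if scaffold not in grid.scaffold_lengths:
            log.warning("bedgraph %s: scaffold %r not in grid; skipped", path, scaffold)
            continue
        slen = grid.scaffold_lengths[scaffold]
        if (sub["end"] > slen).any() or (sub["start"] < 0).any():
            log.warning(
                "bedgraph %s: intervals beyond scaffold %r bounds clipped",
                path, scaffold,
            )
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            start = max(0, int(start))
            end = min(slen, int(end))
            if end <= start:
                continue
            ilen = end - start
            for wi in grid.overlapping_windows(scaffold, start, end):
                ws, we = grid.start[wi], grid.end[wi]
                ov = min(end, we) - max(start, ws)
                if aggregator == "mean":
                    values[wi] += value * ov
                else:
                    values[wi] += value * ov / ilen
    if aggregator == "mean":
        values = values / grid.lengths
    track_name = name or Path(path).stem
    return FeatureTrack(track_name, values, "rebinned")


# ---------------------------------------------------------------------------
# homopolymeric amino-acid runs

DEFAULT_HAAR_RESIDUES = "ASQLN"


@dataclass
class HaarRun:
    protein_id: str
    residue: str
    start: int   # 0-based offset in the protein
    length: int


def find_haars(
    proteins_path, residues: str = DEFAULT_HAAR_RESIDUES, min_run: int = 7
) -> list[HaarRun]:
    """Maximal single-residue runs of length >= min_run in a proteome FASTA."""
    pattern = re.compile(
        "|".join(f"{re.escape(r)}{{{min_run},}}" for r in residues)
    )
    runs: list[HaarRun] = []
    for rec in SeqIO.parse(str(proteins_path), "fasta"):
        seq = str(rec.seq).upper()
        for m in pattern.finditer(seq):
            runs.append(
                HaarRun(
                    protein_id=rec.id,
                    residue=m.group(0)[0],
                    start=m.start(),
                    length=m.end() - m.start(),
                )
            )
    return runs


def haar_counts(runs: Sequence[HaarRun]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in runs:
        out[r.residue] = out.get(r.residue, 0) + 1
    return out


def write_haars_tsv(runs: Sequence[HaarRun], path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.residue, r.start, r.length) for r in runs],
        columns=["protein_id", "residue", "start", "length"],
    ).to_csv(path, sep="\t", index=False)
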