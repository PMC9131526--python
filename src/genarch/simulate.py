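"""Synthetic genomes with planted architecture.

Chromosomes are built from ordered segments, each with its own base
composition, optional telomere-like motif arrays, optional tandem
duplication of a repeat unit (which lowers sequence uniqueness the way
multigene-family arrays do), and its own gene density. Every base carries
a truth label, so clustering output can be scored against the plant.

Bases within a segment are drawn i.i.d. at the segment's target GC —
deliberately the simplest model under which GC%, skews, CpG, k-mer
deviation and mappability separate the planted segment types. Real
genomes add correlation structure (isochores, codon bias, repeat decay)
that this generator does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .windows import SequenceRecord, WindowGrid, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass
class MotifArray:
    """A tandem array of a short motif, inserted verbatim into a segment."""

    motif: str
    copies: int


@dataclass
class SegmentSpec:
    """One architectural segment of a simulated chromosome."""

    label: str
    length: int
    gc: float = 0.4
    motif_arrays: Sequence[MotifArray] = ()
    tandem_duplication: tuple[int, int] | None = None  # (unit bp, copies)
    copy_divergence: float = 0.002   # per-base divergence between duplicated copies
    gene_density: float = 0.0        # genes per 10 kb
    gene_length_mean: float = 1500.0
    gene_length_sd: float = 400.0

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError(f"gc must be in (0,1), got {self.gc}")
        if self.length <= 0:
            raise ValueError("segment length must be positive")


@dataclass
class SimulatedGenome:
    records: list[SequenceRecord]
    genes: list[dict]                 # gene/mRNA/exon entries for GFF3
    truth: pd.DataFrame               # scaffold, start, end, label

    def write_fasta(self, path):
        write_fasta(self.records, path)

    def write_truth_bed(self, path):
        self.truth.to_csv(path, sep="\t", index=False, header=False)

    def write_gff3(self, path):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in self.records:
                fh.write(f"##sequence-region {rec.id} 1 {rec.length}\n")
            for g in self.genes:
                gid = g["id"]
                scaf, s, e, strand = g["scaffold"], g["start"], g["end"], g["strand"]
                fh.write(
                    f"{scaf}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n"
                )
                fh.write(
                    f"{scaf}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={gid}.1;Parent={gid}\n"
                )
                for j, (es, ee) in enumerate(g["exons"], 1):
                    fh.write(
                        f"{scaf}\tsim\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                        f"ID={gid}.1.exon{j};Parent={gid}.1\n"
                    )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _segment_sequence(rng: np.random.Generator, spec: SegmentSpec) -> str:
    if spec.tandem_duplication is not None:
        unit_len, copies = spec.tandem_duplication
        if unit_len <= 0 or copies < 2:
            raise ValueError("tandem_duplication needs unit length > 0, copies >= 2")
        unit = _random_bases(rng, unit_len, spec.gc)
        reps = int(np.ceil(spec.length / unit_len))
        copies = []
        for _ in range(reps):
            copy = unit.copy()
            if spec.copy_divergence > 0:
                n_mut = rng.binomial(unit_len, spec.copy_divergence)
                pos = rng.choice(unit_len, size=n_mut, replace=False)
                copy[pos] = (copy[pos] + rng.integers(1, 4, size=n_mut)) % 4
            copies.append(copy)
        seq = np.concatenate(copies)[: spec.length]
    else:
        seq = _random_bases(rng, spec.length, spec.gc)
    chars = list("".join(_BASES[seq]))
    for array in spec.motif_arrays:
        block = array.motif.upper() * array.copies
        if len(block) > spec.length:
            raise ValueError(
                f"motif array ({len(block)} bp) longer than segment "
                f"{spec.label!r} ({spec.length} bp)"
            )
        pos = int(rng.integers(0, spec.length - len(block) + 1))
        chars[pos : pos + len(block)] = list(block)
    return "".join(chars)


def _place_genes(
    rng: np.random.Generator, spec: SegmentSpec, offset: int, scaffold: str,
    counter: list[int],
) -> list[dict]:
    n_genes = int(round(spec.gene_density * spec.length / 10_000))
    genes: list[dict] = []
    if n_genes == 0:
        return genes
    max_len = spec.length
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 50:
        attempts += 1
        glen = int(rng.normal(spec.gene_length_mean, spec.gene_length_sd))
        glen = max(150, glen)
        if glen > max_len:
            raise ValueError(
                f"gene of {glen} bp cannot fit segment {spec.label!r} "
                f"({spec.length} bp)"
            )
        start = int(rng.integers(0, spec.length - glen + 1))
        if any(start < e and start + glen > s for s, e in occupied):
            continue
        occupied.append((start, start + glen))
        n_exons = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(1, glen), 2 * n_exons - 2, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        cuts = [0, *bounds.tolist(), glen]
        exons = [
            (offset + start + cuts[2 * i], offset + start + cuts[2 * i + 1])
            for i in range(n_exons)
        ]
        exons = [(s, e) for s, e in exons if e > s]
        counter[0] += 1
        genes.append(
            {
                "id": f"gene{counter[0]:05d}",
                "scaffold": scaffold,
                "start": offset + start,
                "end": offset + start + glen,
                "strand": "+" if rng.random() < 0.5 else "-",
                "exons": exons,
            }
        )
    return genes


def simulate_genome(
    chromosome_plans: Sequence[Sequence[SegmentSpec]],
    seed: int = 0,
    chrom_names: Sequence[str] | None = None,
) -> SimulatedGenome:
    """Concatenate segment plans into chromosomes with truth labels.

    Deterministic for a fixed seed: identical plans + seed reproduce
    identical FASTA/GFF3/BED content.
    """
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    genes: list[dict] = []
    truth_rows = []
    counter = [0]
    for ci, plan in enumerate(chromosome_plans):
        name = chrom_names[ci] if chrom_names else f"chr{ci + 1}"
        parts: list[str] = []
        offset = 0
        for spec in plan:
            parts.append(_segment_sequence(rng, spec))
            genes.extend(_place_genes(rng, spec, offset, name, counter))
            truth_rows.append((name, offset, offset + spec.length, spec.label))
            offset += spec.length
        records.append(SequenceRecord(id=name, seq="".join(parts)))
    truth = pd.DataFrame(truth_rows, columns=["scaffold", "start", "end", "label"])
    genes.sort(key=lambda g: (g["scaffold"], g["start"]))
    return SimulatedGenome(records=records, genes=genes, truth=truth)


def parasite_preset(
    core_gc: float = 0.19,
    tare_gc: float = 0.55,
    multigene_gc: float = 0.30,
    telomere_motif: str = "TTTAGGG",
) -> list[list[SegmentSpec]]:
    """Three ~1 Mb chromosomes with GC-rich telomere-motif repeat ends,
    tandem-duplicated multigene-family arrays inside them, and an AT-rich
    gene-dense core — the architecture of a small parasite genome."""

    def tare(length):
        return SegmentSpec(
            "tare", length, gc=tare_gc,
            motif_arrays=[MotifArray(telomere_motif, 120), MotifArray(telomere_motif, 80)],
        )

    def multigene(length):
        return SegmentSpec(
            "multigene", length, gc=multigene_gc,
            tandem_duplication=(10_000, length // 10_000),
            gene_density=2.0,
        )

    def core(length):
        return SegmentSpec("core", length, gc=core_gc, gene_density=4.0)

    plans = []
    for core_len in (680_000, 780_000, 580_000):
        plans.append(
            [tare(60_000), multigene(100_000), core(core_len),
             multigene(100_000), tare(60_000)]
        )
    return plans


# ---------------------------------------------------------------------------
# recovery scoring


def window_truth_labels(truth: pd.DataFrame, grid: WindowGrid) -> np.ndarray:
    """Majority-base truth label per window (object array)."""
    out = np.empty(len(grid), dtype=object)
    names = grid.scaffold_names()
    for scaf, sub in truth.groupby("scaffold", sort=False):
        sel = np.flatnonzero(names == scaf)
        for wi in sel:
            ws, we = grid.start[wi], grid.end[wi]
            best_label, best_ov = None, -1
            for s, e, lab in zip(sub["start"], sub["end"], sub["label"]):
                ov = min(we, e) - max(ws, s)
                if ov > best_ov:
                    best_label, best_ov = lab, ov
            out[wi] = best_label
    return out


def score_recovery(
    labels: np.ndarray, truth: pd.DataFrame, grid: WindowGrid
) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and confusion table of labels vs planted truth."""
    truth_labels = window_truth_labels(truth, grid)
    ari = float(adjusted_rand_score(truth_labels.astype(str), np.asarray(labels)))
    confusion = pd.crosstab(
        pd.Series(truth_labels, name="truth"),
        pd.Series(np.asarray(labels), name="cluster"),
    )
    return ari, confusion
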