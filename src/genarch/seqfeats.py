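"""Per-window sequence-derived features.

All features are computed from the window's own sequence (case-insensitive),
so any motif, k-mer or codon that straddles a window border is counted in
neither window. Frequencies are normalised by the window's *effective
length* — the number of non-N bases — so short trailing windows and
N-containing windows stay comparable. All-N windows receive the degenerate
value of each feature (0, or 100 for N percentage) and are never dropped.

Three features replace external tools with simple deterministic
definitions of the same quantity:

- ``low_complexity_fraction`` — fraction of the window masked by a
  DUST-style triplet-repetition score (scan window 64 bp, score
  threshold 20).
- ``tandem_repeat_fraction`` — fraction covered by maximal perfect tandem
  runs with unit length 1..12.
- ``mappability_depth`` — fold-coverage of error-free tiled fragments,
  each down-weighted by its number of exact-match loci in the assembly
  (both strands); unique sequence scores ~``fold``, sequence present in
  m copies scores ~``fold``/m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .windows import SequenceRecord, WindowGrid

log = logging.getLogger(__name__)

DEFAULT_TELOMERE_MOTIF = "TTTAGGG"

_COMP = str.maketrans("ACGTN", "TGCAN")

# base encoding: A=0 C=1 G=2 T=3, N (and anything else) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Sequence to uint8 codes A=0 C=1 G=2 T=3, N=4 (case-insensitive)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass
class MotifSpec:
    """A motif to count per window, optionally with its reverse complement."""

    motif: str
    count_reverse_complement: bool = True

    def __post_init__(self):
        self.motif = self.motif.upper()
        if len(self.motif) < 2 or not set(self.motif) <= set("ACGT"):
            raise ValueError(f"motif must be >=2 bases over ACGT: {self.motif!r}")


@dataclass
class FeatureTrack:
    """One named per-window signal — a bedgraph in memory."""

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"track {self.name!r} contains non-finite values")


# ---------------------------------------------------------------------------
# scalar per-window features


def _counts(codes: np.ndarray) -> np.ndarray:
    return np.bincount(codes, minlength=5)


def effective_length(seq: str) -> int:
    """Number of non-N bases in the window."""
    return int((encode(seq) != 4).sum())


def gc_percentage(seq: str) -> float:
    """100·(G+C)/(A+C+G+T); 0 for an all-N window."""
    c = _counts(encode(seq))
    denom = c[:4].sum()
    if denom == 0:
        return 0.0
    return 100.0 * (c[1] + c[2]) / denom


def gc_skew(seq: str) -> float:
    """(G−C)/(G+C); 0 when no G or C present."""
    c = _counts(encode(seq))
    denom = c[2] + c[1]
    if denom == 0:
        return 0.0
    return float(c[2] - c[1]) / denom


def at_skew(seq: str) -> float:
    """(A−T)/(A+T); 0 when no A or T present."""
    c = _counts(encode(seq))
    denom = c[0] + c[3]
    if denom == 0:
        return 0.0
    return float(c[0] - c[3]) / denom


def n_percentage(seq: str) -> float:
    if len(seq) == 0:
        return 0.0
    return 100.0 * float((encode(seq) == 4).sum()) / len(seq)


def cpg_percentage(seq: str) -> float:
    """Overlapping CG dinucleotides per 100 dinucleotide positions.

    The denominator is effective length − 1 (the number of dinucleotide
    start positions among informative bases); windows shorter than 2 give 0.
    """
    codes = encode(seq)
    eff = int((codes != 4).sum())
    if eff < 2:
        return 0.0
    hits = int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())
    return 100.0 * hits / (eff - 1)


_STOPS = (("T", "A", "A"), ("T", "A", "G"), ("T", "G", "A"))
_STOP_CODES = [tuple(_CODE[ord(c)] for c in s) for s in _STOPS]


def stop_codon_frequency(seq: str) -> float:
    """Forward-strand TAA/TAG/TGA occurrences (any frame) per position.

    Overlapping scan; denominator effective length − 2; 0 for windows
    shorter than 3.
    """
    codes = encode(seq)
    eff = int((codes != 4).sum())
    if eff < 3 or len(codes) < 3:
        return 0.0
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    hits = 0
    for x, y, z in _STOP_CODES:
        hits += int(((a == x) & (b == y) & (c == z)).sum())
    return hits / (eff - 2)


def count_overlapping(seq: str, motif: str) -> int:
    """Occurrences of motif in seq, overlapping allowed, case-insensitive."""
    s = seq.upper()
    m = motif.upper()
    n = 0
    i = s.find(m)
    while i != -1:
        n += 1
        i = s.find(m, i + 1)
    return n


def motif_frequency(seq: str, spec: MotifSpec) -> float:
    """Overlapping motif matches (plus reverse complement if configured)
    per 100 bp of effective length."""
    eff = effective_length(seq)
    if eff == 0:
        return 0.0
    hits = count_overlapping(seq, spec.motif)
    if spec.count_reverse_complement:
        rc = reverse_complement(spec.motif)
        if rc != spec.motif:
            hits += count_overlapping(seq, rc)
    return 100.0 * hits / eff


# ---------------------------------------------------------------------------
# k-mer deviation


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all k-mers fully inside the sequence; N-containing skipped."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(len(codes) - k + 1, dtype=np.int64)
    valid = np.ones(len(codes) - k + 1, dtype=bool)
    for j in range(k):
        sub = codes[j : len(codes) - k + 1 + j]
        vals = vals * 4 + sub
        valid &= sub != 4
    return vals[valid]


def kmer_profile(seqs: Sequence[str], k: int) -> np.ndarray:
    """Normalised k-mer frequency vector over all sequences, forward strand,
    N-containing k-mers skipped. Sums to 1 (uniform if no k-mer observed)."""
    total = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        codes = encode(seq)
        km = _kmer_codes(codes, k)
        # codes of N-containing k-mers can exceed 4**k bounds? no: valid only
        total += np.bincount(km, minlength=4**k)
    s = total.sum()
    if s == 0:
        return np.full(4**k, 1.0 / 4**k)
    return total / s


def kmer_deviation(seq: str, k: int, genome_profile: np.ndarray) -> float:
    """Euclidean distance between the window's normalised k-mer frequency
    vector and the assembly-wide profile; 0 (flagged) when the window has
    fewer than k informative bases."""
    km = _kmer_codes(encode(seq), k)
    if len(km) == 0:
        return 0.0
    prof = np.bincount(km, minlength=4**k) / len(km)
    return float(np.linalg.norm(prof - genome_profile))


# ---------------------------------------------------------------------------
# low complexity (DUST-style)


def low_complexity_fraction(
    seq: str, score_threshold: float = 20.0, scan_window: int = 64, step: int = 16
) -> float:
    """Fraction of the window masked by triplet-repetition scoring.

    Sliding ``scan_window``-bp frames (step ``step``) are scored as
    10·Σ c_t(c_t−1)/2 / (T−1), where c_t counts each of the 64 triplets in
    the frame and T is the number of informative triplets; frames scoring
    above ``score_threshold`` are masked entirely and overlapping masks are
    merged. High-entropy sequence scores ~5, homopolymers ~310.
    """
    codes = encode(seq)
    n = len(codes)
    if n < 3:
        return 0.0
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a != 4) & (b != 4) & (c != 4)
    trip = (a.astype(np.int64) * 16 + b * 4 + c)
    trip[~valid] = 64  # sentinel bin, excluded from scoring
    mask = np.zeros(n, dtype=bool)
    starts = list(range(0, max(n - scan_window, 0) + 1, step))
    if starts and starts[-1] != n - scan_window and n > scan_window:
        starts.append(n - scan_window)
    if not starts:
        starts = [0]
    for s in starts:
        frame = trip[s : min(s + scan_window, n) - 2]
        if len(frame) == 0:
            continue
        cnt = np.bincount(frame, minlength=65)[:64]
        t = cnt.sum()
        if t < 2:
            continue
        score = 10.0 * float((cnt * (cnt - 1) // 2).sum()) / (t - 1)
        if score > score_threshold:
            mask[s : min(s + scan_window, n)] = True
    return float(mask.mean())


# ---------------------------------------------------------------------------
# tandem repeats


def tandem_repeat_fraction(seq: str, max_unit: int = 12) -> float:
    """Fraction of the window covered by maximal perfect tandem runs.

    For every unit length u in 1..max_unit, positions where
    seq[i] == seq[i−u] sustained so that the repeated region spans at least
    2u consecutive bases are marked (both unit copies included); overlapping
    runs from all unit lengths are merged.
    """
    codes = encode(seq)
    n = len(codes)
    if n == 0:
        return 0.0
    mask = np.zeros(n, dtype=bool)
    for u in range(1, min(max_unit, n - 1) + 1):
        eq = (codes[u:] == codes[:-u]) & (codes[u:] != 4)
        if not eq.any():
            continue
        # run-length encode eq
        d = np.diff(eq.astype(np.int8))
        run_starts = np.flatnonzero(d == 1) + 1
        run_ends = np.flatnonzero(d == -1) + 1
        if eq[0]:
            run_starts = np.r_[0, run_starts]
        if eq[-1]:
            run_ends = np.r_[run_ends, len(eq)]
        for rs, re_ in zip(run_starts, run_ends):
            if re_ - rs >= u:  # repeated span (re_-rs)+u >= 2u
                mask[rs : re_ + u] = True
    return float(mask.mean())


# ---------------------------------------------------------------------------
# mappability surrogate

_P1, _B1 = np.uint64(2147483647), np.uint64(1000003)   # 2^31-1
_P2, _B2 = np.uint64(2147483629), np.uint64(16777259)


def _pow_series(base: np.uint64, p: np.uint64, n: int) -> np.ndarray:
    """[base^0, base^1, ..., base^(n-1)] mod p, by block doubling."""
    out = np.ones(n, dtype=np.uint64)
    if n <= 1:
        return out
    out[1] = base % p
    have = 2
    while have < n:
        take = min(have, n - have)
        out[have : have + take] = (out[:take] * out[have - 1]) % p
        out[have : have + take] = (out[have : have + take] * out[1]) % p
        have += take
    return out


def _window_hashes(codes: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """(combined 62-bit hash keys, validity mask) for every length-L window.

    Polynomial rolling hash, two independent moduli combined into one
    uint64 key; windows containing N are invalid.
    """
    n = len(codes)
    if n < L:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    m = n - L + 1
    s = codes.astype(np.int64)
    keys = []
    for p, b in ((_P1, _B1), (_P2, _B2)):
        pw = _pow_series(b, p, n)
        inv_b = np.uint64(pow(int(b), int(p) - 2, int(p)))
        ipw = _pow_series(inv_b, p, m)
        terms = (s % int(p)) * pw.astype(np.int64)
        pref = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(terms, out=pref[1:])
        pref %= int(p)
        raw = (pref[L : L + m] - pref[:m]) % int(p)
        h = (raw.astype(np.uint64) * ipw) % p
        keys.append(h)
    nmask = codes == 4
    bad = np.convolve(nmask.astype(np.int64), np.ones(L, dtype=np.int64), "valid") > 0
    return (keys[0] << np.uint64(31)) | keys[1], ~bad


def mappability_depth(
    records: Sequence[SequenceRecord],
    grid: WindowGrid,
    fragment_length: int = 150,
    fold: int = 10,
) -> np.ndarray:
    """Deterministic surrogate for simulated-read mapping coverage.

    Error-free fragments of ``fragment_length`` are tiled genome-wide every
    fragment_length/fold bp; each fragment adds 1/(number of exact
    full-length match loci in the assembly, both strands) to per-base depth
    across its footprint. The window value is the mean depth over the
    window's bases, bounded by [0, fold]. Scaffolds shorter than the
    fragment length contribute no fragments and their windows score 0.
    """
    L = fragment_length
    step = max(1, L // fold)
    fwd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rev: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_keys = []
    for rec in records:
        codes = encode(rec.seq)
        k, v = _window_hashes(codes, L)
        fwd[rec.id] = (k, v)
        rc_codes = np.where(codes[::-1] == 4, np.uint8(4), 3 - codes[::-1])
        rk, rv = _window_hashes(rc_codes.astype(np.uint8), L)
        rev[rec.id] = (rk, rv)
        if len(k):
            all_keys.append(k[v])
    if not all_keys:
        return np.zeros(len(grid))
    table = np.concatenate(all_keys)
    uniq, counts = np.unique(table, return_counts=True)

    def lookup(keys: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(uniq, keys)
        idx = np.clip(idx, 0, len(uniq) - 1)
        found = uniq[idx] == keys
        out = np.where(found, counts[idx], 0)
        return out

    depths: dict[str, np.ndarray] = {}
    for rec in records:
        n = rec.length
        diff = np.zeros(n + 1)
        fk, fv = fwd[rec.id]
        rk, rv = rev[rec.id]
        if len(fk):
            starts = np.arange(0, n - L + 1, step)
            fkeys, fvalid = fk[starts], fv[starts]
            # rc fragment of [i, i+L) sits at position n-L-i of the rc strand
            rpos = n - L - starts
            rkeys = rk[rpos]
            mult = lookup(fkeys) + lookup(rkeys)
            ok = fvalid & (mult > 0)
            w = np.zeros(len(starts))
            w[ok] = 1.0 / mult[ok]
            np.add.at(diff, starts, w)
            np.add.at(diff, starts + L, -w)
        depths[rec.id] = np.cumsum(diff[:-1])

    values = np.zeros(len(grid))
    names = grid.scaffold_names()
    for i, (name, s, e) in enumerate(zip(names, grid.start, grid.end)):
        values[i] = depths[str(name)][s:e].mean()
    return np.clip(values, 0.0, float(fold))


# ---------------------------------------------------------------------------
# assembly-level driver


@dataclass
class SeqFeatureConfig:
    telomere_motif: str = DEFAULT_TELOMERE_MOTIF
    cag_motif: str = "CAG"
    kmer_sizes: tuple[int, ...] = (3, 4)
    fragment_length: int = 150
    mappability_fold: int = 10
    include_mappability: bool = True


def extract_seq_features(
    records: Sequence[SequenceRecord],
    grid: WindowGrid,
    config: SeqFeatureConfig | None = None,
) -> list[FeatureTrack]:
    """Compute the full sequence-derived feature set on the window grid."""
    cfg = config or SeqFeatureConfig()
    seqs = {r.id: r.seq for r in records}
    windows = [
        seqs[str(name)][s:e]
        for name, s, e in zip(grid.scaffold_names(), grid.start, grid.end)
    ]
    profiles = {k: kmer_profile([r.seq for r in records], k) for k in cfg.kmer_sizes}
    tel = MotifSpec(cfg.telomere_motif, count_reverse_complement=True)
    cag = MotifSpec(cfg.cag_motif, count_reverse_complement=True)

    scalar_features: list[tuple[str, str, callable]] = [
        ("gc_percentage", "%", gc_percentage),
        ("at_skew", "", at_skew),
        ("gc_skew", "", gc_skew),
        ("cpg_percentage", "% of dinucleotide positions", cpg_percentage),
        ("stop_codon_freq", "count per position", stop_codon_frequency),
        ("telomere_freq", "count per 100 bp", lambda s: motif_frequency(s, tel)),
        ("cag_freq", "count per 100 bp", lambda s: motif_frequency(s, cag)),
        ("N_percentage", "%", n_percentage),
        ("low_complexity_fraction", "fraction", low_complexity_fraction),
        ("tandem_repeat_fraction", "fraction", tandem_repeat_fraction),
    ]
    tracks = [
        FeatureTrack(name, np.array([f(w) for w in windows]), units)
        for name, units, f in scalar_features
    ]
    for k in cfg.kmer_sizes:
        tracks.append(
            FeatureTrack(
                f"kmer_deviation_kmer_size_{k}",
                np.array([kmer_deviation(w, k, profiles[k]) for w in windows]),
                "euclidean distance",
            )
        )
    if cfg.include_mappability:
        tracks.append(
            FeatureTrack(
                "mappability_depth",
                mappability_depth(
                    records, grid, cfg.fragment_length, cfg.mappability_fold
                ),
                "fold",
            )
        )
    return tracks
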