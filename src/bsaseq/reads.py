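"""Read cleaning and bisulfite-aware alignment for amplicon data.

Implements the four processing stages between raw paired FASTQ and the
per-site pileup: error-tolerant primer demultiplexing, quality trimming
(leading/trailing floor then sliding-window cut), overlap merging of read
pairs, and semi-global alignment against the converted strand references.

Amplicons are a few hundred bases and read counts are in the thousands, so
alignment is direct (no index/seeding): a vectorised ungapped scan over all
offsets, with an affine-gap dynamic program as fallback for reads the
ungapped scan cannot place.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np

from .reference import ConvertedReference, ReferenceLocus, PrimerPair, reverse_complement

__all__ = [
    "SequenceRead",
    "AlignedRead",
    "DemuxResult",
    "demultiplex_by_primer",
    "quality_trim",
    "merge_pairs",
    "align_to_converted_reference",
    "read_fastq",
    "write_fastq",
]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class SequenceRead:
    """One sequencing read: bases plus per-base Phred qualities."""

    id: str
    bases: str
    qualities: np.ndarray  # int array, same length as bases

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.qualities)} qualities"
            )
        if len(self.qualities) and (self.qualities.min() < 0 or self.qualities.max() > 60):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRead":
        rc = self.bases.encode().translate(_COMPLEMENT)[::-1].decode()
        return SequenceRead(self.id, rc, self.qualities[::-1].copy())


@dataclass
class AlignedRead:
    """A read placed on one converted strand of one locus.

    ``read_to_ref`` maps each read index to a reference index (-1 where the
    read base is an insertion); it is strictly increasing over aligned
    positions. ``cpg_calls`` maps each covered CpG site — keyed by the
    top-strand seq_index of its cytosine — to the read base observed there
    (OB-strand evidence is C/T in OB coordinates already, so no remapping of
    the base letter is needed; only the position maps back).
    """

    locus: str
    strand: str  # "OT" or "OB"
    ref_start: int
    score: float
    read_to_ref: np.ndarray
    query_bases: str = ""
    cpg_calls: dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Demultiplexing


@dataclass
class DemuxResult:
    locus: str | None  # None = unassigned
    trimmed: SequenceRead | None
    edit_distance: int | None = None
    ambiguous: bool = False


def demultiplex_by_primer(
    read: SequenceRead,
    primers: dict[str, str],
    max_error_rate: float,
) -> DemuxResult:
    """Assign a read to a locus by its 5' primer and trim the primer off.

    Each primer is matched semi-globally against the read prefix
    (substitutions and indels all cost 1); a primer is acceptable when its
    edit distance is at most floor(max_error_rate * primer_length). The
    lowest-distance primer wins; a tie between two primers leaves the read
    unassigned (ambiguous).
    """
    if not 0 <= max_error_rate < 1:
        raise ValueError("max_error_rate must be in [0, 1)")
    if not primers:
        raise ValueError("empty primer table")
    best: tuple[int, str, int] | None = None  # (distance, locus, prefix_end)
    tied = False
    for locus, primer in primers.items():
        if not primer:
            raise ValueError(f"empty primer for locus {locus!r}")
        limit = int(max_error_rate * len(primer))
        res = edlib.align(primer, read.bases, mode="SHW", task="locations", k=limit)
        dist = res["editDistance"]
        if dist < 0:  # beyond k: no acceptable match
            continue
        end = max(loc[1] for loc in res["locations"]) + 1
        if best is None or dist < best[0]:
            best = (dist, locus, end)
            tied = False
        elif dist == best[0]:
            tied = True
    if best is None:
        return DemuxResult(None, None)
    if tied:
        return DemuxResult(None, None, edit_distance=best[0], ambiguous=True)
    dist, locus, end = best
    trimmed = SequenceRead(read.id, read.bases[end:], read.qualities[end:].copy())
    return DemuxResult(locus, trimmed, edit_distance=dist)


# ---------------------------------------------------------------------------
# Quality trimming


def quality_trim(
    read: SequenceRead,
    end_q: int = 20,
    window: int = 5,
    window_mean_q: float = 30.0,
) -> SequenceRead:
    """Trim low-quality ends, then cut at the first failing sliding window.

    Leading then trailing bases with Q < ``end_q`` are removed; the
    remainder is scanned 5'->3' with a ``window``-base sliding window and
    truncated at the start of the first window (complete windows only)
    whose mean quality is below ``window_mean_q``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = read.qualities
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < end_q:
        lo += 1
    while hi > lo and q[hi - 1] < end_q:
        hi -= 1
    q = q[lo:hi]
    cut = len(q)
    if len(q) >= window:
        means = np.convolve(q, np.ones(window), mode="valid") / window
        failing = np.nonzero(means < window_mean_q)[0]
        if failing.size:
            cut = int(failing[0])
    return SequenceRead(read.id, read.bases[lo : lo + cut], q[:cut].copy())


# ---------------------------------------------------------------------------
# Pair merging


def _encode(bases: str) -> np.ndarray:
    return np.frombuffer(bases.encode(), dtype=np.uint8)


def merge_pairs(
    r1: SequenceRead,
    r2: SequenceRead,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
) -> SequenceRead | None:
    """Merge a read pair by its 3' overlap, or return None if none admissible.

    r2 is reverse-complemented, then every overlap length from
    ``min_overlap`` up to min(len1, len2) is scored as matches - mismatches;
    overlaps whose mismatch density exceeds ``max_mismatch_density`` are
    inadmissible. The best-scoring admissible overlap wins, ties going to
    the longer overlap. Consensus: at matches keep the base with quality
    max(q1, q2); at mismatches keep the higher-quality base with quality
    |q1 - q2| (r1 wins quality ties).
    """
    if len(r1) == 0 or len(r2) == 0:
        return None
    r2c = r2.reverse_complement()
    a, b = _encode(r1.bases), _encode(r2c.bases)
    n1, n2 = len(a), len(b)
    max_ov = min(n1, n2)
    if max_ov < min_overlap:
        return None
    # matches(ov) for all ov at once via one-hot cross-correlation:
    # overlap ov aligns a[n1-ov + k] with b[k].
    ovs = np.arange(min_overlap, max_ov + 1)
    matches = np.zeros(len(ovs))
    for base in b"ACGT":
        ia = (a == base).astype(np.float64)
        ib = (b == base).astype(np.float64)
        # full cross-correlation; overlap ov aligns a at offset n1-ov with
        # b at 0, which is index (n1-ov) + n2 - 1 of the 'full' output
        corr = np.correlate(ia, ib, mode="full")  # length n1+n2-1
        matches += corr[n1 + n2 - 1 - ovs]
    mismatches = ovs - matches
    scores = matches - mismatches
    admissible = mismatches <= max_mismatch_density * ovs
    if not admissible.any():
        return None
    best_score = scores[admissible].max()
    candidates = ovs[admissible & (scores == best_score)]
    ov = int(candidates.max())  # tie -> longer overlap

    tail = a[n1 - ov :]
    head = b[:ov]
    q1 = r1.qualities[n1 - ov :]
    q2 = r2c.qualities[:ov]
    eq = tail == head
    take1 = eq | (q1 >= q2)
    cons = np.where(take1, tail, head)
    consq = np.where(eq, np.maximum(q1, q2), np.abs(q1 - q2))
    bases = r1.bases[: n1 - ov] + cons.tobytes().decode() + r2c.bases[ov:]
    quals = np.concatenate([r1.qualities[: n1 - ov], consq, r2c.qualities[ov:]])
    return SequenceRead(r1.id, bases, quals)


# ---------------------------------------------------------------------------
# Bisulfite-aware alignment

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0


def _strand_arrays(ref: ConvertedReference) -> tuple[np.ndarray, np.ndarray]:
    seq = _encode(ref.sequence)
    cpg = np.zeros(len(seq), dtype=bool)
    cpg[list(ref.cpg_c_indices)] = True
    return seq, cpg


def _ungapped_scores(read_b: np.ndarray, ref_b: np.ndarray, cpg: np.ndarray) -> np.ndarray:
    """Score of the read at every ungapped offset in the reference.

    A position matches when the bases are identical, or when the reference
    position held a CpG cytosine (now T on the converted reference) and the
    read shows C — the methylated-base case bisulfite-aware scoring must
    accept. The reverse (read C at an ordinary converted position) stays a
    mismatch.
    """
    L, R = len(read_b), len(ref_b)
    if R < L:
        return np.empty(0)
    matches = np.zeros(R - L + 1)
    for base in b"ACGT":
        matches += np.correlate((ref_b == base).astype(np.float64), (read_b == base).astype(np.float64), mode="valid")
    matches += np.correlate(cpg.astype(np.float64), (read_b == ord("C")).astype(np.float64), mode="valid")
    return MATCH * matches + MISMATCH * (L - matches)


def _affine_glocal(read_b: np.ndarray, ref_b: np.ndarray, cpg: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Affine-gap semi-global DP: read global, reference free at both ends.

    Returns (score, read_to_ref map, ref_start). Used only as fallback for
    reads with indels; O(len_read * len_ref).
    """
    L, R = len(read_b), len(ref_b)
    neg = -1e18
    # M[i,j]: read[:i] aligned ending with read[i-1]~ref[j-1]
    M = np.full((L + 1, R + 1), neg)
    X = np.full((L + 1, R + 1), neg)  # gap in read (ref consumed)
    Y = np.full((L + 1, R + 1), neg)  # gap in ref (read consumed)
    M[0, :] = 0.0  # free leading reference
    ptr = np.zeros((L + 1, R + 1), dtype=np.uint8)  # 1=M diag, 2=X left, 3=Y up
    sub = np.where(
        (ref_b[None, :] == read_b[:, None]) | (cpg[None, :] & (read_b[:, None] == ord("C"))),
        MATCH,
        MISMATCH,
    )
    for i in range(1, L + 1):
        diag_prev = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
        M[i, 1:] = diag_prev + sub[i - 1]
        Y[i, :] = np.maximum(M[i - 1, :] + GAP_OPEN, Y[i - 1, :] + GAP_EXTEND)
        # X[i,j] = max(M[i,j-1] + open, X[i,j-1] + extend): left-to-right scan
        x_prev = neg
        Mi = M[i]
        Xi = X[i]
        for j in range(1, R + 1):
            x_prev = max(Mi[j - 1] + GAP_OPEN, x_prev + GAP_EXTEND)
            Xi[j] = x_prev
    end = np.maximum(M[L, :], Y[L, :])  # trailing reference free: take best j
    j_end = int(np.argmax(end))
    score = float(end[j_end])
    # traceback
    read_to_ref = np.full(L, -1, dtype=np.int64)
    i, j = L, j_end
    state = "M" if M[L, j_end] >= Y[L, j_end] else "Y"
    while i > 0:
        if state == "M":
            read_to_ref[i - 1] = j - 1
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if prev == M[i - 1, j - 1]:
                state = "M"
            elif prev == X[i - 1, j - 1]:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "Y":  # read base consumed, gap in reference
            read_to_ref[i - 1] = -1
            state = "M" if M[i - 1, j] + GAP_OPEN >= Y[i - 1, j] + GAP_EXTEND else "Y"
            i -= 1
        else:  # X: reference consumed
            state = "M" if M[i, j - 1] + GAP_OPEN >= X[i, j - 1] + GAP_EXTEND else "X"
            j -= 1
    aligned = read_to_ref[read_to_ref >= 0]
    ref_start = int(aligned[0]) if aligned.size else 0
    return score, read_to_ref, ref_start


def _cpg_calls(
    read_bases: str, read_to_ref: np.ndarray, ref: ConvertedReference, locus: ReferenceLocus
) -> dict[int, str]:
    """Base calls at covered CpG positions, keyed by top-strand seq_index."""
    n = len(locus.sequence)
    cpg_set = {}
    for top_i in locus.cpg_indices:
        strand_i = top_i if ref.strand == "OT" else n - top_i - 2
        cpg_set[strand_i] = top_i
    calls: dict[int, str] = {}
    ref_pos_to_read = {int(r): k for k, r in enumerate(read_to_ref) if r >= 0}
    for strand_i, top_i in cpg_set.items():
        k = ref_pos_to_read.get(strand_i)
        if k is not None:
            calls[top_i] = read_bases[k]
    return calls


def align_to_converted_reference(
    read: SequenceRead,
    refs: tuple[ConvertedReference, ConvertedReference],
    locus: ReferenceLocus,
    min_score_fraction: float = 0.8,
) -> AlignedRead | None:
    """Place a trimmed read on the better-scoring converted strand.

    Ungapped placement is attempted at every offset first; if no offset
    reaches ``min_score_fraction * len(read)`` the affine-gap semi-global
    DP is run. Equal best scores on both strands leave the read unaligned
    (ambiguous strand).
    """
    if len(read) == 0:
        return None
    read_b = _encode(read.bases)
    threshold = min_score_fraction * len(read)
    results = []
    for ref in refs:
        ref_b, cpg = _strand_arrays(ref)
        scores = _ungapped_scores(read_b, ref_b, cpg)
        best_ungapped = float(scores.max()) if scores.size else -np.inf
        if best_ungapped >= threshold:
            off = int(np.argmax(scores))
            r2r = np.arange(off, off + len(read_b), dtype=np.int64)
            results.append((best_ungapped, ref, r2r, off))
        elif best_ungapped > 0:
            # real homology but indels: worth the full dynamic program;
            # wrong-strand or junk reads score well below zero ungapped
            score, r2r, off = _affine_glocal(read_b, ref_b, cpg)
            if score >= threshold:
                results.append((score, ref, r2r, off))
    if not results:
        return None
    if len(results) == 2 and results[0][0] == results[1][0]:
        return None  # ambiguous strand
    score, ref, r2r, off = max(results, key=lambda t: t[0])
    return AlignedRead(
        locus=locus.name,
        strand=ref.strand,
        ref_start=off,
        score=score,
        read_to_ref=r2r,
        query_bases=read.bases,
        cpg_calls=_cpg_calls(read.bases, r2r, ref, locus),
    )


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, gzip by extension)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    from Bio import SeqIO

    with _open_text(path, "r") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield SequenceRead(
                record.id,
                str(record.seq).upper(),
                np.asarray(record.letter_annotations["phred_quality"], dtype=np.int64),
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    n = 0
    with _open_text(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n
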