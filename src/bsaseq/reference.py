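"""Promoter reference model for targeted bisulfite amplicon sequencing.

A :class:`ReferenceLocus` holds one promoter amplicon, its transcription
start site (TSS) anchor and the CpG sites discovered in it.  CpG sites are
labelled by TSS-relative coordinates: the base immediately 5' of the TSS is
-1, the next -2 and so on; there is no position 0, and bases at or after the
TSS are labelled +1, +2, ...  Sites are always identified by the cytosine of
the CpG dinucleotide on the top strand.

Bisulfite treatment deaminates unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine is protected.  Because conversion acts on each
strand independently, the two strands of a converted molecule are no longer
complementary; downstream alignment therefore works against the two
converted strand references (OT = original top, OB = original bottom)
produced by :func:`converted_strands`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "CpGSite",
    "ReferenceLocus",
    "ConvertedReference",
    "PrimerPair",
    "PrimerValidation",
    "find_cpg_sites",
    "bisulfite_convert",
    "converted_strands",
    "validate_primer_pair",
    "reverse_complement",
    "load_reference_fasta",
    "write_reference_fasta",
    "load_primer_table",
    "write_primer_table",
]

_DNA = set("ACGT")


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def _check_dna(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in _DNA:
            raise ValueError(f"non-ACGT character {base!r} at position {i}")


def tss_relative_position(seq_index: int, tss_index: int) -> int:
    """TSS-relative label of a base: upstream bases are -1, -2, ...; no 0."""
    if seq_index < tss_index:
        return seq_index - tss_index
    return seq_index - tss_index + 1


@dataclass(frozen=True)
class CpGSite:
    """The cytosine of one CpG dinucleotide, in both coordinate systems."""

    locus: str
    seq_index: int
    tss_position: int

    @property
    def label(self) -> str:
        return f"{self.locus}:{self.tss_position}"


@dataclass
class ReferenceLocus:
    """A promoter amplicon with TSS anchor and discovered CpG sites."""

    name: str
    sequence: str
    tss_index: int
    cpg_sites: list[CpGSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        _check_dna(self.sequence)
        if not 0 <= self.tss_index <= len(self.sequence):
            raise ValueError(
                f"tss_index {self.tss_index} outside [0, {len(self.sequence)}] for {self.name}"
            )
        if not self.cpg_sites:
            self.cpg_sites = find_cpg_sites(self)

    @property
    def site_labels(self) -> list[str]:
        return [s.label for s in self.cpg_sites]

    @property
    def cpg_indices(self) -> list[int]:
        return [s.seq_index for s in self.cpg_sites]


def find_cpg_sites(locus: ReferenceLocus) -> list[CpGSite]:
    """Discover every CG dinucleotide, ordered 5'->3' on the top strand."""
    seq = locus.sequence
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            sites.append(
                CpGSite(
                    locus=locus.name,
                    seq_index=i,
                    tss_position=tss_relative_position(i, locus.tss_index),
                )
            )
    return sites


def bisulfite_convert(sequence: str, methylated_indices: set[int] | frozenset[int] = frozenset()) -> str:
    """Convert every cytosine outside ``methylated_indices`` to T.

    ``methylated_indices`` must point at cytosines of CpG dinucleotides:
    only those can be protected by methylation in this model.
    """
    sequence = sequence.upper()
    _check_dna(sequence)
    for i in methylated_indices:
        if not (0 <= i < len(sequence) - 1 and sequence[i] == "C" and sequence[i + 1] == "G"):
            raise ValueError(f"methylated index {i} does not point at a CpG cytosine")
    out = [
        "T" if (b == "C" and i not in methylated_indices) else b
        for i, b in enumerate(sequence)
    ]
    return "".join(out)


@dataclass(frozen=True)
class ConvertedReference:
    """One fully-converted (all-unmethylated) strand reference.

    The sequence has *every* cytosine converted to T, including CpG
    cytosines — the all-unmethylated extreme.  ``cpg_c_indices`` records, in
    this strand's own coordinates, where CpG cytosines sat before
    conversion: at those positions a read C means methylated and a read T
    means unmethylated, and bisulfite-aware alignment scores both as a
    match.
    """

    locus: str
    strand: str  # "OT" or "OB"
    sequence: str
    cpg_c_indices: tuple[int, ...]


def converted_strands(locus: ReferenceLocus) -> tuple[ConvertedReference, ConvertedReference]:
    """Fully-converted OT and OB strand references for a locus.

    The OB strand carries the CpG evidence of the same top-strand sites: the
    bottom-strand cytosine of the CpG at top index i sits at OB index
    len - i - 2.
    """
    top = locus.sequence
    n = len(top)
    ot = ConvertedReference(locus.name, "OT", bisulfite_convert(top), tuple(locus.cpg_indices))
    ob_cpg = tuple(sorted(n - i - 2 for i in locus.cpg_indices))
    ob = ConvertedReference(
        locus.name, "OB", bisulfite_convert(reverse_complement(top)), ob_cpg
    )
    return ot, ob


@dataclass(frozen=True)
class PrimerPair:
    locus: str
    forward: str
    reverse: str
    forward_contains_cpg: bool = False
    reverse_contains_cpg: bool = False


@dataclass
class PrimerValidation:
    """Where (if anywhere) a primer pair binds on the converted strands."""

    locus: str
    found: bool
    strand: str | None = None  # strand the forward primer binds
    forward_contains_cpg: bool | None = None
    reverse_contains_cpg: bool | None = None
    amplicon_start: int | None = None  # in the bound strand's coordinates
    amplicon_end: int | None = None  # exclusive
    message: str = ""


def _footprint_overlaps_cpg(start: int, end: int, strand_len: int, locus: ReferenceLocus, strand: str) -> bool:
    """Does a primer footprint (strand coords, [start, end)) touch a CpG?

    A CpG at top index i occupies top indices {i, i+1} on either strand
    (C and G on top; the paired G and C on the bottom).
    """
    for site in locus.cpg_sites:
        i = site.seq_index
        if strand == "OT":
            lo, hi = i, i + 1
        else:
            lo, hi = strand_len - i - 2, strand_len - i - 1
        if start <= lo < end or start <= hi < end:
            return True
    return False


def validate_primer_pair(
    pair: PrimerPair,
    refs: tuple[ConvertedReference, ConvertedReference],
    locus: ReferenceLocus,
) -> PrimerValidation:
    """Check a primer pair against both converted strand references.

    The forward primer is searched directly; the reverse primer anneals to
    the other end of the amplicon so its reverse complement is searched on
    the same strand. Exact matching only — primer design against a clean
    reference should be exact; mismatch-tolerant matching belongs to read
    demultiplexing, not design validation.
    """
    if not pair.forward or not pair.reverse:
        raise ValueError("primers must be non-empty")
    for ref in refs:
        seq = ref.sequence
        f_at = seq.find(pair.forward)
        if f_at < 0:
            continue
        rc_rev = reverse_complement(pair.reverse)
        r_at = seq.find(rc_rev, f_at + len(pair.forward))
        if r_at < 0:
            continue
        amp_start, amp_end = f_at, r_at + len(rc_rev)
        n = len(seq)
        return PrimerValidation(
            locus=pair.locus,
            found=True,
            strand=ref.strand,
            forward_contains_cpg=_footprint_overlaps_cpg(
                f_at, f_at + len(pair.forward), n, locus, ref.strand
            ),
            reverse_contains_cpg=_footprint_overlaps_cpg(
                r_at, r_at + len(rc_rev), n, locus, ref.strand
            ),
            amplicon_start=amp_start,
            amplicon_end=amp_end,
        )
    return PrimerValidation(locus=pair.locus, found=False, message="no binding site")


# ---------------------------------------------------------------------------
# I/O


def load_reference_fasta(fasta_path: str | Path, tss_table: str | Path | None = None) -> list[ReferenceLocus]:
    """Read promoter references from FASTA.

    TSS anchors come either from a ``tss=<int>`` key in each record's
    description, or from a sidecar TSV with columns
    (locus_name, tss_index_0based). The sidecar wins if both are given.
    """
    tss_map: dict[str, int] = {}
    if tss_table is not None:
        with open(tss_table) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                tss_map[row["locus_name"]] = int(row["tss_index_0based"])
    loci = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        name = record.id
        if name in tss_map:
            tss = tss_map[name]
        else:
            tss = None
            for token in record.description.split():
                if token.startswith("tss="):
                    tss = int(token[4:])
            if tss is None:
                raise ValueError(f"no TSS annotation for locus {name!r} (need tss= key or sidecar TSV)")
        loci.append(ReferenceLocus(name=name, sequence=str(record.seq), tss_index=tss))
    return loci


def write_reference_fasta(loci: list[ReferenceLocus], fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.name} tss={locus.tss_index}\n")
            seq = locus.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def load_primer_table(path: str | Path) -> dict[str, PrimerPair]:
    pairs = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs[row["locus"]] = PrimerPair(
                locus=row["locus"],
                forward=row["forward"].upper(),
                reverse=row["reverse"].upper(),
            )
    return pairs


def write_primer_table(pairs: dict[str, PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tforward\treverse\n")
        for p in pairs.values():
            fh.write(f"{p.locus}\t{p.forward}\t{p.reverse}\n")
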