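"""Raw paired reads -> barcoded, genome-mapped transposon junctions.

Read 1 carries the 16-base cell barcode at its start; read 2 carries the
transposon tag (inverted-repeat end sequence) followed by genomic flank
beginning at the junction TA.  Processing extracts the barcode, isolates
and trims tagged reads, places the genomic fragment on the reference by
unique exact match, and snaps the junction coordinate onto a TA.

Mapping is exact k-mer seeding with full-length verification: the
contract is a unique, full-length, exact placement, which is what the
downstream per-cell compilation consumes.  An external aligner can be
substituted behind :class:`GenomeIndex` for real data.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import Genome
from .simulate import revcomp

BARCODE_LENGTH = 16


@dataclass(frozen=True)
class BarcodedFragment:
    """A read pair reduced to its cell barcode and untrimmed read-2 sequence."""

    cell_barcode: str
    genomic_seq: str
    mate_id: str


@dataclass(frozen=True)
class MappedJunction:
    """A transposon-genome junction assigned to a cell.

    ``orientation`` '+' means the tag-to-genome junction reads into
    increasing reference coordinates; the reference dinucleotide at
    ``ta_position`` is always TA.
    """

    cell_barcode: str
    contig: str
    ta_position: int
    orientation: str
    mate_id: str = ""


def correct_barcode(barcode: str, whitelist: set[str]) -> str | None:
    """Exact match, else unique <=1-mismatch whitelist correction."""
    if barcode in whitelist:
        return barcode
    hit = None
    for wl in whitelist:
        if sum(a != b for a, b in zip(barcode, wl)) <= 1:
            if hit is not None:
                return None  # ambiguous
            hit = wl
    return hit


def extract_barcode(
    read1_seq: str,
    read2_seq: str,
    mate_id: str = "",
    whitelist: set[str] | None = None,
) -> BarcodedFragment | None:
    """Take the first 16 bases of read 1 as the cell barcode.

    Returns ``None`` (rejected) if read 1 is shorter than 16 bases or the
    barcode cannot be corrected against a supplied whitelist.
    """
    if len(read1_seq) < BARCODE_LENGTH:
        return None
    barcode = read1_seq[:BARCODE_LENGTH].upper()
    if whitelist is not None:
        barcode = correct_barcode(barcode, whitelist)
        if barcode is None:
            return None
    return BarcodedFragment(barcode, read2_seq.upper(), mate_id)


def isolate_and_trim(
    seq: str,
    transposon_tag: str,
    max_mismatch: int = 1,
    search_window: int = 5,
) -> tuple[str | None, bool]:
    """Trim the transposon tag from the read-2 start.

    The tag is searched at offsets ``0..search_window`` with up to
    ``max_mismatch`` substitutions; the first qualifying occurrence is
    trimmed.  Returns ``(genomic sequence, multiple_hits_flag)`` or
    ``(None, False)`` for tagless reads.
    """
    tag = transposon_tag.upper()
    seq = seq.upper()
    hits = []
    for off in range(0, search_window + 1):
        window = seq[off : off + len(tag)]
        if len(window) < len(tag):
            break
        mism = sum(a != b for a, b in zip(window, tag))
        if mism <= max_mismatch:
            hits.append(off)
    if not hits:
        return None, False
    return seq[hits[0] + len(tag) :], len(hits) > 1


class GenomeIndex:
    """Exact k-mer seed index over the forward strand of the genome."""

    def __init__(self, genome: Genome, k: int = 20):
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((name, i))

    def _placements(self, frag: str) -> list[tuple[str, int]]:
        out = []
        for contig, start in self._seeds.get(frag[: self.k], ()):
            if self.genome.contigs[contig][start : start + len(frag)] == frag:
                out.append((contig, start))
        return out

    def map_fragment(self, genomic_seq: str):
        """Unique full-length exact placement on either strand.

        Returns ``("unique", contig, start, strand)`` or
        ``("multi" | "no_hit" | "too_short",)``.  A '-' strand hit means
        the fragment matches the reverse complement of the reference at
        ``[start, start + len)``.
        """
        if len(genomic_seq) < self.k:
            return ("too_short",)
        fwd = self._placements(genomic_seq)
        rev = self._placements(revcomp(genomic_seq))
        total = len(fwd) + len(rev)
        if total == 0:
            return ("no_hit",)
        if total > 1:
            return ("multi",)
        if fwd:
            contig, start = fwd[0]
            return ("unique", contig, start, "+")
        contig, start = rev[0]
        return ("unique", contig, start, "-")


def snap_to_ta(
    genome: Genome,
    contig: str,
    start: int,
    strand: str,
    frag_len: int,
    snap_tolerance: int = 2,
) -> int | None:
    """Locate the junction TA at the fragment's transposon-proximal end.

    For a '+' placement the junction is at the alignment start; for '-'
    it is at the alignment end minus 2 (the fragment reads leftward).  If
    the candidate does not sit on a TA, the nearest TA within
    ``snap_tolerance`` bases is taken; otherwise the fragment is rejected.
    """
    seq = genome.contigs[contig]
    candidate = start if strand == "+" else start + frag_len - 2
    offsets = sorted(range(-snap_tolerance, snap_tolerance + 1), key=abs)
    for d in offsets:
        p = candidate + d
        if 0 <= p <= len(seq) - 2 and seq[p : p + 2] == "TA":
            return p
    return None


def _open_fastq(path: str | Path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def read_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (mate_id, read1_seq, read2_seq) from paired FASTQ files."""
    with _open_fastq(r1_path) as f1, _open_fastq(r2_path) as f2:
        for (id1, seq1, _), (id2, seq2, _) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            mid1 = id1.split()[0]
            mid2 = id2.split()[0]
            if mid1 != mid2:
                raise ValueError(f"read pair mismatch: {mid1!r} vs {mid2!r}")
            yield mid1, seq1, seq2


def process_read_pairs(
    pairs: Iterable[tuple[str, str, str]],
    genome: Genome,
    transposon_tag: str,
    *,
    index: GenomeIndex | None = None,
    whitelist: set[str] | None = None,
    max_tag_mismatch: int = 1,
    tag_search_window: int = 5,
    min_mappable_length: int = 20,
    snap_tolerance: int = 2,
) -> tuple[list[MappedJunction], Counter]:
    """Run the full read-processing chain; audit counts every rejection.

    The audit categories (kept + rejections by reason) sum to the number
    of input read pairs.
    """
    if index is None:
        index = GenomeIndex(genome, k=min_mappable_length)
    audit: Counter = Counter()
    junctions: list[MappedJunction] = []
    for mate_id, seq1, seq2 in pairs:
        frag = extract_barcode(seq1, seq2, mate_id, whitelist)
        if frag is None:
            audit["barcode_rejected"] += 1
            continue
        genomic, multi_tag = isolate_and_trim(
            frag.genomic_seq, transposon_tag, max_tag_mismatch, tag_search_window
        )
        if genomic is None:
            audit["no_tag"] += 1
            continue
        if multi_tag:
            # informational flag, not part of the kept/rejected partition
            audit["multi_tag_flagged"] += 1
        result = index.map_fragment(genomic)
        if result[0] != "unique":
            audit[f"unmapped_{result[0]}"] += 1
            continue
        _, contig, start, strand = result
        ta_pos = snap_to_ta(genome, contig, start, strand, len(genomic), snap_tolerance)
        if ta_pos is None:
            audit["no_ta"] += 1
            continue
        junctions.append(MappedJunction(frag.cell_barcode, contig, ta_pos, strand, mate_id))
        audit["kept"] += 1
    return junctions, audit


def write_junctions(junctions: Iterable[MappedJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_barcode\tcontig\tta_position\torientation\tmate_id\n")
        for j in junctions:
            fh.write(
                f"{j.cell_barcode}\t{j.contig}\t{j.ta_position}\t{j.orientation}\t{j.mate_id}\n"
            )


def read_junctions(path: str | Path) -> list[MappedJunction]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
        for line in fh:
            bc, contig, pos, orient, mate = line.rstrip("\n").split("\t")
            out.append(MappedJunction(bc, contig, int(pos), orient, mate))
    return out
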