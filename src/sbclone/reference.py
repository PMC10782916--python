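"""Reference genome handling, TA-site indexing and site-to-gene annotation.

Sleeping Beauty transposons integrate exclusively into TA dinucleotides, so
the reference layer exposes two indices: the positions of every TA in the
genome (the sampling frame for the permutation null) and an interval index
mapping genomic coordinates to genes, optionally extended by a promoter
window upstream of each gene's transcription start (default 40 kb).

Coordinates are 0-based half-open throughout; GFF3's 1-based closed
intervals are converted on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree
from scipy import sparse

logger = logging.getLogger(__name__)

_VALID_ALPHABET = frozenset("ACGTN")


@dataclass
class Genome:
    """An ordered collection of named contigs (uppercase DNA, N allowed)."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]


def load_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased).

    Raises ``ValueError`` on an empty file, a duplicate contig name, or a
    record whose sequence contains characters outside ``{A,C,G,T,N}``.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate contig name in FASTA: {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {record.id!r} has an empty sequence")
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"FASTA record {record.id!r} contains invalid characters: {sorted(bad)}"
            )
        contigs[record.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(contigs)


@dataclass
class TASiteIndex:
    """Sorted 0-based positions of every TA dinucleotide, per contig.

    Position ``p`` is indexed iff ``sequence[p:p+2] == "TA"``; dinucleotides
    containing N are never indexed.  TA cannot overlap itself, so positions
    are automatically >= 2 apart is *not* guaranteed (TATA yields 0 and 2,
    which are 2 apart) but they are strictly increasing.
    """

    positions: dict[str, np.ndarray]

    @property
    def total_count(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def flat(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Concatenated (contig names, per-site contig index, positions)."""
        names = list(self.positions)
        if not names:
            return names, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        cidx = np.concatenate(
            [np.full(len(self.positions[n]), i, dtype=np.int64) for i, n in enumerate(names)]
        )
        pos = np.concatenate([self.positions[n] for n in names])
        return names, cidx, pos

    def site_at(self, flat_index: int) -> tuple[str, int]:
        for name, arr in self.positions.items():
            if flat_index < len(arr):
                return name, int(arr[flat_index])
            flat_index -= len(arr)
        raise IndexError("flat TA index out of range")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\n")
            for name, arr in self.positions.items():
                for p in arr:
                    fh.write(f"{name}\t{p}\n")


def build_ta_index(genome: Genome) -> TASiteIndex:
    """Index every TA occurrence in the genome (vectorised byte scan)."""
    positions: dict[str, np.ndarray] = {}
    for name, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        hits = np.flatnonzero((arr[:-1] == ord("T")) & (arr[1:] == ord("A")))
        positions[name] = hits.astype(np.int64)
    return TASiteIndex(positions)


@dataclass(frozen=True)
class GeneModel:
    """One gene as a single genomic interval (0-based half-open)."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end ({self.end}) <= start ({self.start})"
            )


def _load_bed(path: Path) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 required (found {df.shape[1]} columns)")
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneModel(
                gene_id=str(row[3]),
                contig=str(row[0]),
                strand=str(row[5]),
                start=int(row[1]),
                end=int(row[2]),
            )
        )
    return genes


def _load_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = (
            (attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name") or [feat.id])[0]
        )
        # GFF3 is 1-based closed; convert to 0-based half-open.
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
            )
        )
    return genes


def load_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED6 (0-based half-open) or GFF3 (converted)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _load_bed(path)
    if suffix in (".gff", ".gff3", ".gtf"):
        return _load_gff3(path)
    raise ValueError(f"unrecognised gene-model format: {path.name}")


@dataclass
class AnnotationIndex:
    """Interval index mapping (contig, position) -> gene ids.

    A position maps to gene *g* iff it lies in the gene body
    ``[start, end)`` or within ``promoter_window`` bases upstream of the
    transcription start (strand-aware when ``upstream_only``; symmetric
    around both ends otherwise).
    """

    genes: list[GeneModel]
    promoter_window: int = 40_000
    upstream_only: bool = True
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _warned: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for i, g in enumerate(self.genes):
            lo, hi = self.extended_interval(g)
            self._trees.setdefault(g.contig, IntervalTree()).addi(lo, hi, i)

    def extended_interval(self, gene: GeneModel) -> tuple[int, int]:
        w = self.promoter_window
        if self.upstream_only:
            if gene.strand == "+":
                return max(0, gene.start - w), gene.end
            return gene.start, gene.end + w
        return max(0, gene.start - w), gene.end + w

    def annotate(self, contig: str, position: int) -> set[str]:
        tree = self._trees.get(contig)
        if tree is None:
            if contig not in self._warned:
                self._warned.add(contig)
                logger.warning("annotate: unknown contig %r", contig)
            return set()
        return {self.genes[iv.data].gene_id for iv in tree.at(position)}

    def ta_membership(
        self, ta_index: TASiteIndex, gene_ids: list[str] | None = None
    ) -> tuple[list[str], sparse.csr_matrix]:
        """Boolean membership of every TA site in every gene's extended interval.

        Returns ``(gene_order, M)`` with ``M`` of shape
        ``(total TA sites, n genes)`` in the flat TA ordering of
        :meth:`TASiteIndex.flat`.  Precomputing this makes per-trial
        annotation in the permutation test a row-slicing operation.
        """
        if gene_ids is None:
            order = sorted({g.gene_id for g in self.genes})
        else:
            order = list(gene_ids)
        col_of = {gid: j for j, gid in enumerate(order)}
        names = list(ta_index.positions)
        offsets = {}
        off = 0
        for n in names:
            offsets[n] = off
            off += len(ta_index.positions[n])
        rows, cols = [], []
        for g in self.genes:
            j = col_of.get(g.gene_id)
            if j is None or g.contig not in offsets:
                continue
            arr = ta_index.positions[g.contig]
            lo, hi = self.extended_interval(g)
            a = int(np.searchsorted(arr, lo, side="left"))
            b = int(np.searchsorted(arr, hi, side="left"))
            if b > a:
                rows.append(np.arange(a, b, dtype=np.int64) + offsets[g.contig])
                cols.append(np.full(b - a, j, dtype=np.int64))
        n_ta = off
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
            data = np.ones(len(r), dtype=np.int8)
            mat = sparse.csr_matrix((data, (r, c)), shape=(n_ta, len(order)))
            mat.sum_duplicates()
            mat.data[:] = 1
        else:
            mat = sparse.csr_matrix((n_ta, len(order)), dtype=np.int8)
        return order, mat


def annotate_site(
    site: tuple[str, int], index: AnnotationIndex
) -> set[str]:
    """All genes whose body-plus-promoter-window contains the position."""
    contig, position = site
    return index.annotate(contig, position)
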