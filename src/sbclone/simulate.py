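"""Synthetic genomes, planted subclonal architectures and barcoded reads.

The generator emulates the structure of a transposon-mutagenised tumour
profiled at single-cell resolution: a genome with a controlled TA-site
density, a set of subclones each defined by a disjoint set of TA insertion
sites, cells carrying their subclone's full site complement with
overdispersed per-site read counts, plus singleton cells carrying unique
never-reused sites and doublet artifacts merging two subclones' sites
under one barcode.  Defaults follow the observed tumour architecture:
6-16 subclones per sample, 2-84 sites per subclone, 19-1250 cells per
subclone, with a small singleton and doublet fraction.

All randomness flows from a single mandatory seed; outputs are
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .calling import CellProfile, InsertionSite
from .reference import Genome, build_ta_index

# non-TA dinucleotide blocks that never start with A, so that no TA can form
# across a block boundary (a boundary TA needs T then A)
_NONTA_BLOCKS = np.array(
    ["CC", "CG", "CT", "CA", "GA", "GC", "GG", "GT", "TC", "TG", "TT"]
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    genome_length: int = 600_000
    n_contigs: int = 3
    ta_enrichment: float = 0.05  # TA sites per base
    n_subclones: tuple[int, int] = (6, 16)
    sites_per_subclone: tuple[int, int] = (2, 84)
    cells_per_subclone: tuple[int, int] = (19, 1250)
    singleton_cell_rate: float = 0.08
    doublet_rate: float = 0.02
    singleton_sites: tuple[int, int] = (2, 3)
    reads_per_site_mean: float = 30.0
    reads_per_site_shape: float | None = 10.0  # None -> constant counts
    junk_read_rate: float = 0.0  # fraction of reads lacking the transposon tag
    flank_length: int = 40
    r1_length: int = 28
    barcode_length: int = 16
    transposon_tag: str = "TCGTTAGAACGCGTAATACG"
    substitution_rate: float = 0.0  # uniform per-base error in the genomic flank

    def __post_init__(self) -> None:
        for name in ("singleton_cell_rate", "doublet_rate", "junk_read_rate",
                     "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_subclones", "sites_per_subclone", "cells_per_subclone",
                     "singleton_sites"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range {lo}..{hi} is empty or invalid")
        if not 0.0 < self.ta_enrichment <= 0.5:
            raise ValueError("ta_enrichment must be in (0, 0.5]")
        if self.barcode_length != 16:
            raise ValueError("cell barcodes are 16 bases in this assay")

    def min_sites_needed(self) -> int:
        """Fewest insertion sites any draw of this configuration can request."""
        return self.n_subclones[0] * self.sites_per_subclone[0]

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "genome": np.random.default_rng(children[0]),
            "plant": np.random.default_rng(children[1]),
            "reads": np.random.default_rng(children[2]),
        }


@dataclass
class SimulationTruth:
    """Planted ground truth: subclone site sets, cell labels, read counts."""

    subclone_sites: dict[str, frozenset[InsertionSite]]
    cell_labels: dict[str, str]  # barcode -> subclone id | SINGLETON | DOUBLET
    cell_site_counts: dict[str, dict[InsertionSite, int]]

    def cell_profiles(self) -> list[CellProfile]:
        """Bridge to the calling layer: truth as noiseless cell profiles."""
        return [
            CellProfile(bc, dict(counts))
            for bc, counts in sorted(self.cell_site_counts.items())
        ]

    def to_tsv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        with open(outdir / "truth_subclones.tsv", "w") as fh:
            fh.write("subclone_id\tsite_key\n")
            for sid in sorted(self.subclone_sites):
                for s in sorted(self.subclone_sites[sid]):
                    fh.write(f"{sid}\t{s.key}\n")
        with open(outdir / "truth_cells.tsv", "w") as fh:
            fh.write("cell_barcode\tlabel\n")
            for bc in sorted(self.cell_labels):
                fh.write(f"{bc}\t{self.cell_labels[bc]}\n")


def simulate_genome(config: SimConfig) -> Genome:
    """Random genome whose TA density matches ``ta_enrichment``.

    Built from dinucleotide blocks: each block is TA with probability
    2 * ta_enrichment, otherwise a non-TA block that never starts with A
    (so no TA forms across block boundaries and density is exact in
    expectation).
    """
    expected_ta = config.ta_enrichment * config.genome_length
    if expected_ta < config.min_sites_needed():
        raise ValueError(
            f"genome too short: ~{expected_ta:.0f} expected TA sites cannot host "
            f"the {config.min_sites_needed()} insertion sites requested"
        )
    rng = config.streams()["genome"]
    per_contig = config.genome_length // config.n_contigs
    contigs: dict[str, str] = {}
    for i in range(config.n_contigs):
        length = per_contig if i < config.n_contigs - 1 else (
            config.genome_length - per_contig * (config.n_contigs - 1)
        )
        n_blocks = length // 2
        is_ta = rng.random(n_blocks) < 2.0 * config.ta_enrichment
        blocks = _NONTA_BLOCKS[rng.integers(0, len(_NONTA_BLOCKS), n_blocks)]
        blocks = np.where(is_ta, "TA", blocks)
        seq = "".join(blocks)
        if length % 2:
            seq += "C"
        contigs[f"chr{i + 1}"] = seq
    return Genome(contigs)


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    alphabet = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(alphabet[rng.integers(0, 4, length)])
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _draw_counts(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    if config.reads_per_site_shape is None:
        return np.full(n, int(round(config.reads_per_site_mean)), dtype=np.int64)
    shape = config.reads_per_site_shape
    p = shape / (shape + config.reads_per_site_mean)
    return np.maximum(1, rng.negative_binomial(shape, p, size=n))


def plant_subclones(genome: Genome, config: SimConfig) -> SimulationTruth:
    """Plant mutually disjoint subclone site sets and populate cells.

    Sites are sampled uniformly without replacement from the TA index
    (away from contig edges so a full genomic flank always exists);
    singleton cells receive unique never-reused sites; doublets merge the
    site sets of two distinct subclones under one barcode.
    """
    ta = build_ta_index(genome)
    if ta.total_count == 0:
        raise ValueError("genome contains no TA sites")
    rng = config.streams()["plant"]

    margin = config.flank_length + 2
    eligible: list[tuple[str, int]] = []
    for name, arr in ta.positions.items():
        limit = len(genome.contigs[name]) - margin
        ok = arr[(arr >= margin) & (arr < limit)]
        eligible.extend((name, int(p)) for p in ok)

    lo, hi = config.n_subclones
    n_sub = int(rng.integers(lo, hi + 1))
    site_counts = rng.integers(
        config.sites_per_subclone[0], config.sites_per_subclone[1] + 1, n_sub
    )
    cell_counts = rng.integers(
        config.cells_per_subclone[0], config.cells_per_subclone[1] + 1, n_sub
    )
    n_assigned = int(cell_counts.sum())
    n_singletons = int(round(config.singleton_cell_rate * n_assigned))
    singleton_site_counts = rng.integers(
        config.singleton_sites[0], config.singleton_sites[1] + 1, n_singletons
    )
    n_needed = int(site_counts.sum() + singleton_site_counts.sum())
    if n_needed > len(eligible):
        raise ValueError(
            f"insufficient TA sites: need {n_needed}, have {len(eligible)} eligible"
        )

    chosen = rng.choice(len(eligible), size=n_needed, replace=False)
    orientations = rng.choice(["+", "-"], size=n_needed)
    pool = [
        InsertionSite(eligible[int(i)][0], eligible[int(i)][1], str(o))
        for i, o in zip(chosen, orientations)
    ]

    subclone_sites: dict[str, frozenset[InsertionSite]] = {}
    cursor = 0
    for s in range(n_sub):
        k = int(site_counts[s])
        subclone_sites[f"s{s + 1}"] = frozenset(pool[cursor : cursor + k])
        cursor += k

    n_doublets = int(round(config.doublet_rate * n_assigned)) if n_sub >= 2 else 0
    barcodes = _random_barcodes(
        rng, n_assigned + n_singletons + n_doublets, config.barcode_length
    )
    bc_iter = iter(barcodes)

    cell_labels: dict[str, str] = {}
    cell_site_counts: dict[str, dict[InsertionSite, int]] = {}

    for s in range(n_sub):
        sid = f"s{s + 1}"
        sites = sorted(subclone_sites[sid])
        for _ in range(int(cell_counts[s])):
            bc = next(bc_iter)
            counts = _draw_counts(rng, len(sites), config)
            cell_labels[bc] = sid
            cell_site_counts[bc] = dict(zip(sites, (int(c) for c in counts)))

    for i in range(n_singletons):
        bc = next(bc_iter)
        k = int(singleton_site_counts[i])
        sites = pool[cursor : cursor + k]
        cursor += k
        counts = _draw_counts(rng, k, config)
        cell_labels[bc] = "SINGLETON"
        cell_site_counts[bc] = dict(zip(sites, (int(c) for c in counts)))

    sub_ids = sorted(subclone_sites)
    for _ in range(n_doublets):
        bc = next(bc_iter)
        a, b = rng.choice(len(sub_ids), size=2, replace=False)
        sites = sorted(subclone_sites[sub_ids[int(a)]] | subclone_sites[sub_ids[int(b)]])
        counts = _draw_counts(rng, len(sites), config)
        cell_labels[bc] = "DOUBLET"
        cell_site_counts[bc] = dict(zip(sites, (int(c) for c in counts)))

    return SimulationTruth(subclone_sites, cell_labels, cell_site_counts)


def _flank(genome: Genome, site: InsertionSite, length: int) -> str:
    """Genomic sequence read from the transposon junction into the genome.

    Starts with the junction TA on either orientation: '+' reads rightward
    from the TA, '-' reads leftward on the reverse complement.
    """
    seq = genome.contigs[site.contig]
    if site.orientation == "+":
        return seq[site.position : site.position + length]
    return revcomp(seq[site.position + 2 - length : site.position + 2])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def emit_reads(
    truth: SimulationTruth,
    genome: Genome,
    config: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> dict:
    """Write paired FASTQ: R1 = barcode + filler, R2 = tag + genomic flank.

    Per-(cell, site) mate-pair counts are the planted read counts.  A
    ``junk_read_rate`` fraction of additional reads carry a valid barcode
    but a random genomic fragment without the transposon tag.
    """
    rng = config.streams()["reads"]
    alphabet = np.array(list("ACGT"))
    filler_len = config.r1_length - config.barcode_length

    def open_out(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    n_signal = 0
    n_junk = 0
    barcodes = sorted(truth.cell_site_counts)
    with open_out(r1_path) as r1, open_out(r2_path) as r2:
        mate = 0
        for bc in barcodes:
            for site in sorted(truth.cell_site_counts[bc]):
                count = truth.cell_site_counts[bc][site]
                flank = _flank(genome, site, config.flank_length)
                for _ in range(count):
                    mate += 1
                    rid = f"sim{mate}"
                    filler = "".join(alphabet[rng.integers(0, 4, filler_len)])
                    seq2 = config.transposon_tag + _mutate(
                        rng, flank, config.substitution_rate
                    )
                    _write_fastq(r1, rid, bc + filler)
                    _write_fastq(r2, rid, seq2)
                    n_signal += 1
        if config.junk_read_rate > 0.0 and n_signal:
            n_junk = int(round(
                config.junk_read_rate / (1.0 - config.junk_read_rate) * n_signal
            ))
            contig_names = list(genome.contigs)
            for _ in range(n_junk):
                mate += 1
                rid = f"junk{mate}"
                bc = barcodes[int(rng.integers(0, len(barcodes)))]
                filler = "".join(alphabet[rng.integers(0, 4, filler_len)])
                cname = contig_names[int(rng.integers(0, len(contig_names)))]
                cseq = genome.contigs[cname]
                start = int(rng.integers(0, max(1, len(cseq) - config.flank_length)))
                seq2 = "".join(alphabet[rng.integers(0, 4, len(config.transposon_tag))])
                seq2 += cseq[start : start + config.flank_length]
                _write_fastq(r1, rid, bc + filler)
                _write_fastq(r2, rid, seq2)
    return {"n_signal_pairs": n_signal, "n_junk_pairs": n_junk}


def _write_fastq(fh, read_id: str, seq: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
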