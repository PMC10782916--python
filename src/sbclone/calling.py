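"""Per-cell insertion profiles, QC filtering and sample assembly.

A cell's genotype is the map from insertion sites to supporting read
counts.  The QC rule keeps a cell only if it carries at least two sites
supported by more than 9 reads each; sites below the read threshold are
dropped from downstream analysis but preserved in an audit layer.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple


class InsertionSite(NamedTuple):
    """A transposon insertion: TA coordinate plus integration orientation."""

    contig: str
    position: int
    orientation: str

    @property
    def coordinate(self) -> tuple[str, int]:
        """Orientation-collapsed (contig, position) key.

        Both integration orientations at one TA share a coordinate; gene
        annotation and co-occurrence analysis operate at coordinate level.
        """
        return (self.contig, self.position)

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.orientation}"


@dataclass
class CellProfile:
    """One barcoded cell's insertion sites with supporting read counts."""

    cell_barcode: str
    site_counts: dict[InsertionSite, int] = field(default_factory=dict)

    def qualifying_sites(self, min_reads_per_site: int = 10) -> set[InsertionSite]:
        return {s for s, c in self.site_counts.items() if c >= min_reads_per_site}


def aggregate_cells(junctions: Iterable) -> list[CellProfile]:
    """Compile mapped junctions into one profile per distinct barcode.

    The read count of a site within a cell is the number of junction
    records for that (barcode, site) pair.  Profiles are returned in
    sorted barcode order for determinism.
    """
    counts: dict[str, dict[InsertionSite, int]] = defaultdict(lambda: defaultdict(int))
    for j in junctions:
        site = InsertionSite(j.contig, j.ta_position, j.orientation)
        counts[j.cell_barcode][site] += 1
    return [
        CellProfile(bc, dict(counts[bc])) for bc in sorted(counts)
    ]


def qc_filter(
    cells: Iterable[CellProfile],
    min_reads_per_site: int = 10,
    min_sites: int = 2,
    keep_low_count_sites: bool = False,
) -> list[CellProfile]:
    """Remove poor-quality cells: fewer than ``min_sites`` sites with at
    least ``min_reads_per_site`` reads (the ">9 reads" rule with defaults).

    Kept cells retain only their qualifying sites unless
    ``keep_low_count_sites`` is set; the filter is idempotent either way.
    """
    kept = []
    for cell in cells:
        qual = cell.qualifying_sites(min_reads_per_site)
        if len(qual) < min_sites:
            continue
        if keep_low_count_sites:
            kept.append(CellProfile(cell.cell_barcode, dict(cell.site_counts)))
        else:
            kept.append(
                CellProfile(
                    cell.cell_barcode,
                    {s: c for s, c in cell.site_counts.items() if s in qual},
                )
            )
    return kept


@dataclass
class SampleDataset:
    """A QC-passed sample: cells, the nonredundant site set, and audit."""

    sample_id: str
    cells: list[CellProfile]
    nonredundant_sites: tuple[InsertionSite, ...]
    audit: dict

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def build_sample(
    cells: Iterable[CellProfile],
    sample_id: str,
    min_reads_per_site: int = 10,
    min_sites: int = 2,
    keep_low_count_sites: bool = False,
) -> SampleDataset:
    """QC-filter raw profiles and derive the sample's nonredundant site set."""
    raw = list(cells)
    passed = qc_filter(
        raw,
        min_reads_per_site=min_reads_per_site,
        min_sites=min_sites,
        keep_low_count_sites=keep_low_count_sites,
    )
    audit = {
        "sample_id": sample_id,
        "n_cells_raw": len(raw),
        "n_cells_pass": len(passed),
        "min_reads_per_site": min_reads_per_site,
        "min_sites": min_sites,
    }
    if not passed:
        raise ValueError(f"no cells pass QC for sample {sample_id!r}: audit={audit}")
    sites: set[InsertionSite] = set()
    for cell in passed:
        sites.update(cell.qualifying_sites(min_reads_per_site))
    nonredundant = tuple(sorted(sites))
    audit["n_nonredundant_sites"] = len(nonredundant)
    return SampleDataset(sample_id, passed, nonredundant, audit)
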