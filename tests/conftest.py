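import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sbclone.calling import CellProfile, InsertionSite, build_sample
from sbclone.reference import AnnotationIndex, GeneModel, Genome
from sbclone.simulate import SimConfig, plant_subclones, simulate_genome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    # chr1 has TAs at 0, 4, 10; chrM is TA-free
    return Genome({"chr1": "TACCTAGGGGTACCCGGGAA", "chrM": "GGCCGGCC"})


@pytest.fixture(scope="session")
def plus_gene_annotation() -> AnnotationIndex:
    gene = GeneModel("geneA", "chr1", "+", 100_000, 150_000)
    return AnnotationIndex([gene], promoter_window=40_000)


def make_sample(cell_sites: dict[str, dict], sample_id: str = "s", **kw):
    """Build a SampleDataset from {barcode: {InsertionSite: reads}}."""
    cells = [CellProfile(bc, dict(sites)) for bc, sites in cell_sites.items()]
    return build_sample(cells, sample_id, **kw)


def site(pos: int, contig: str = "chr1", orientation: str = "+") -> InsertionSite:
    return InsertionSite(contig, pos, orientation)


def fig4_config(seed: int, **overrides) -> SimConfig:
    """The observed-tumour regime: 6-16 subclones, 2-84 sites, 19-1250 cells."""
    kw = dict(
        seed=seed,
        genome_length=600_000,
        n_contigs=3,
        n_subclones=(6, 16),
        sites_per_subclone=(2, 84),
        cells_per_subclone=(19, 1250),
        singleton_cell_rate=0.08,
        doublet_rate=0.02,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def profile_level_run(config: SimConfig):
    """Planted truth -> QC'd sample, bypassing FASTQ emission."""
    genome = simulate_genome(config)
    truth = plant_subclones(genome, config)
    sample = build_sample(truth.cell_profiles(), f"sim{config.seed}")
    return genome, truth, sample
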