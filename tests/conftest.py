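import numpy as np
import pytest

from promark import (
    EnrichmentArchitecture,
    GeneModel,
    SyntheticGenomeSpec,
    Tag,
    make_gene_models,
)


def mk_tag(chrom="chr1", start=0, length=36, strand="+", unique=True) -> Tag:
    return Tag(chrom, start, start + length, strand, unique)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticGenomeSpec:
    return SyntheticGenomeSpec(
        chrom_sizes={"chrA": 400_000},
        n_genes=10,
        min_gene_length=2_000,
        max_gene_length=6_000,
        intergenic_gap_min=5_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genes(small_spec) -> list[GeneModel]:
    return make_gene_models(small_spec)


@pytest.fixture(scope="session")
def default_arch() -> EnrichmentArchitecture:
    return EnrichmentArchitecture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)


def random_tags(
    rng: np.random.Generator,
    n: int,
    genome_bp: int = 10_000,
    chrom: str = "chr1",
    length: int = 36,
) -> list[Tag]:
    """Uniform random tags on a small genome (always in bounds)."""
    starts = rng.integers(0, max(genome_bp - length, 1), size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [Tag(chrom, int(s), int(s) + length, str(st)) for s, st in zip(starts, strands)]
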