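import pytest

from lnccat.annotation import GeneModel, GenomicInterval
from lnccat.simulate import SyntheticConfig, simulate_dataset


def spectrum_sets(counts_by_multiplicity: dict[int, int], n_sets: int = 4) -> dict[str, set[str]]:
    """Gene sets realizing a target multiplicity spectrum {k: count}."""
    sets: dict[str, set[str]] = {c: set() for c in "abcd"[:n_sets]}
    names = list(sets)
    g = 0
    for k, count in counts_by_multiplicity.items():
        for i in range(count):
            gid = f"g{g}"
            g += 1
            for j in range(k):  # rotate hosting sets so genes spread around
                sets[names[(i + j) % n_sets]].add(gid)
    return sets


def mk_gene(gene_id, chrom, strand, exons, biotype="lncRNA_candidate"):
    """Terse gene-model builder for fixtures: exons as (start, end) tuples."""
    return GeneModel(
        gene_id,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default synthetic bundle (seed 1), shared across the session."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_dataset(SyntheticConfig(seed=1), out)
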