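import numpy as np
import pytest

from sweepscan import CohortLabels, GenotypeMatrix, HaplotypePanel, MarkerMap


def make_map(positions, chrom="1", allele1="A", allele2="G"):
    positions = np.asarray(positions)
    if isinstance(chrom, str):
        chrom = [chrom] * len(positions)
    n = len(positions)
    return MarkerMap(np.array([f"m{i}" for i in range(n)], dtype=object),
                     np.array(chrom, dtype=object),
                     positions.astype(np.int64),
                     np.full(n, allele1, dtype=object),
                     np.full(n, allele2, dtype=object))


def make_panel(alleles, positions=None, chrom="1", coding="raw",
               sample_ids=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    if positions is None:
        positions = (np.arange(alleles.shape[1]) + 1) * 10_000
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(alleles.shape[0] // 2)]
    return HaplotypePanel(sample_ids, make_map(positions, chrom), alleles,
                          coding=coding)


def make_genotypes(dosage, positions=None, chrom="1", samples=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    if positions is None:
        positions = (np.arange(dosage.shape[1]) + 1) * 10_000
    if samples is None:
        samples = [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(samples, make_map(positions, chrom), dosage)


@pytest.fixture
def toy_labels():
    """Three populations: heavy/north, light/south, unclassified."""
    population = {}
    for k in range(4):
        population[f"P1_{k}"] = "P1"
        population[f"P2_{k}"] = "P2"
        population[f"P3_{k}"] = "P3"
    return CohortLabels(population,
                        {"P1": "heavy", "P2": "light", "P3": "none"},
                        {"P1": "north", "P2": "south", "P3": "none"})
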