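"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from pirna_dimorph import synthetic as syn
from pirna_dimorph.config import Config
from pirna_dimorph.genome import Genome


@pytest.fixture(scope="session")
def cfg():
    return Config()


@pytest.fixture(scope="session")
def small_truth():
    """A reduced toy genome: 60 male / 30 female / 60 NE loci."""
    genome, truth = syn.build_toy_genome(
        n_male=60, n_female=30, n_ne=60, seed=11)
    return genome, truth


@pytest.fixture(scope="session")
def tiny_genome():
    """A hand-built two-chromosome genome for coordinate-level tests."""
    rng = np.random.default_rng(7)
    chr1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    chr2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    return Genome({"chrI": chr1, "chrII": chr2})


def make_reads(rows):
    """rows: (chrom, start, end, strand, weight, n_hits)"""
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "weight", "n_hits"])


def make_loci(rows):
    """rows: (id, chrom, start, end, strand, sex_class)"""
    return pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "strand", "sex_class"])
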