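"""Shared fixtures: tiny deterministic genomes, toy fragment maps and one
session-scoped small simulation reused by read-only tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialqtl.config import small_config
from spatialqtl.simulate import generate_all


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One small simulated bundle, written to disk once per session."""
    out_dir = tmp_path_factory.mktemp("sim") / "bundle"
    return generate_all(small_config(11), out_dir)


@pytest.fixture()
def toy_fragments() -> pd.DataFrame:
    """Five 4 kb fragments tiling one 20 kb chromosome."""
    rows = [("chr1", i * 4000, (i + 1) * 4000, f"F{i + 1}") for i in range(5)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_id"])


def make_snps(records) -> pd.DataFrame:
    """records: (rsid, chrom, pos, assoc_p, phenotype) tuples."""
    return pd.DataFrame(
        records, columns=["rsid", "chrom", "pos", "assoc_p", "phenotype"]
    )


def make_genes(records) -> pd.DataFrame:
    """records: (gene_id, symbol, chrom, start, end) tuples."""
    return pd.DataFrame(records, columns=["gene_id", "symbol", "chrom", "start", "end"])


def make_contacts(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [(a, b, 1) for a, b in pairs], columns=["frag_a", "frag_b", "count"]
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
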