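from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def tiny_alignment(tmp_path):
    """Two-species FASTA (lengths 12 and 8) with a matching metadata table."""
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(
        ">A1 some description\nACGTACGTACGT\n"
        ">A2\nACGTACGAACGT\n"
        ">A3\nACGTACGTACGT\n"
        ">B1\nTTTTCCCC\n"
        ">B2\nTTTTCCCA\n"
        ">B3\nTTTTCCCC\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text(
        "accession\tspecies_id\tlatitude\tlongitude\n"
        "A1\tspA\t-23.5667\t-45.1\n"
        "A2\tspA\t-23.2\t-45.0\n"
        "A3\tspA\t-22.8\t-44.9\n"
        "B1\tspB\t5.4\t-52.0\n"
        "B2\tspB\t5.9\t-52.1\n"
        "B3\tspB\t6.2\t-52.2\n"
    )
    return fasta, meta


def random_haplotype_sample(rng, n_max=12, L=20):
    """Random HaplotypeSample for estimator oracle checks."""
    from latdiv.seqdata import collapse_haplotypes

    n = int(rng.integers(2, n_max + 1))
    n_haps = int(rng.integers(1, min(n, 5) + 1))
    pool = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n_haps)]
    seqs = [pool[int(rng.integers(n_haps))] for _ in range(n)]
    return collapse_haplotypes(seqs, "spX", 0)
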