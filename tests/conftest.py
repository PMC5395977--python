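import numpy as np
import pysam
import pytest

from mtp9.sites import default_sites
from mtp9.synthetic import SimulationConfig, build_truth, sam_header


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def header():
    return sam_header()


@pytest.fixture
def make_read(header):
    """Factory for pysam alignment records with sensible defaults."""

    counter = {"n": 0}

    def _make(
        pos,
        seq,
        flag=99,
        mapq=60,
        qual=40,
        cigar=None,
        qname=None,
    ):
        counter["n"] += 1
        a = pysam.AlignedSegment(header)
        a.query_name = qname or f"r{counter['n']}"
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos - 1  # 1-based in tests
        a.mapping_quality = mapq
        a.cigarstring = cigar or f"{len(seq)}M"
        a.query_sequence = seq
        if isinstance(qual, int):
            qual = [qual] * len(seq)
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(33 + q) for q in qual)
        )
        a.next_reference_id = 0
        a.next_reference_start = a.reference_start
        a.template_length = len(seq)
        return a

    return _make


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_patients=8,
        coverage_mean=80.0,
        n_snps=10,
        n_genes=30,
        n_mito_genes=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
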