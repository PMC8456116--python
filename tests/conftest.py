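import numpy as np
import pytest

from inco.genomic_data import CnvPanel, CombinedGeneMatrix, GeneAnnotation, SnvPanel
from inco.region_test import fit_null


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_snv_panel(rng, n=100, q=6, chrom="1", span=(1, 10_000), maf=None):
    maf = np.full(q, 0.25) if maf is None else np.asarray(maf)
    return SnvPanel(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"snv{j}" for j in range(q)],
        chromosomes=[chrom] * q,
        positions=np.sort(rng.integers(span[0], span[1] + 1, q)),
        genotypes=rng.binomial(2, maf, (n, q)).astype(float),
    )


def make_cnv_panel(rng, n=100, q=3, chrom="1", span=(1, 10_000), carrier=0.1):
    starts = rng.integers(span[0], span[1] - 500, q)
    return CnvPanel(
        sample_ids=[f"s{i}" for i in range(n)],
        segment_ids=[f"seg{j}" for j in range(q)],
        chromosomes=[chrom] * q,
        starts=starts,
        ends=starts + rng.integers(100, 500, q),
        status=rng.binomial(1, carrier, (n, q)).astype(np.int8),
    )


def make_matrix(rng, n=100, q1=4, q2=2, unit_id="g", span=(1, 10_000), maf=None):
    snv = make_snv_panel(rng, n, q1, span=span, maf=maf)
    cnv = make_cnv_panel(rng, n, q2, span=span)
    return CombinedGeneMatrix(
        unit_id=unit_id,
        chromosome="1",
        start=span[0],
        end=span[1],
        sample_ids=snv.sample_ids,
        snv_block=snv.genotypes,
        cnv_block=cnv.status,
        snv_ids=snv.marker_ids,
        snv_positions=snv.positions,
        cnv_ids=cnv.segment_ids,
        cnv_starts=cnv.starts,
        cnv_ends=cnv.ends,
    )


@pytest.fixture
def balanced_binary_null():
    y = np.zeros(100)
    y[:30] = 1.0
    return y, fit_null(y, None, "binary")


@pytest.fixture
def snv_panel(rng):
    return make_snv_panel(rng)


@pytest.fixture
def cnv_panel(rng):
    return make_cnv_panel(rng)
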