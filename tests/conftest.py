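import numpy as np
import pandas as pd
import pytest

from snpkin import GenomeModel, GenotypeTable, scenario


@pytest.fixture(scope="session")
def desk_genome():
    """~50k markers over 22 autosomes at 10% human lengths."""
    return GenomeModel.desk_scale()


@pytest.fixture(scope="session")
def sparse_genome():
    """Same chromosome lengths, far fewer markers: fast gene-dropping when
    only the realized IBD truth matters (truth depends on bp lengths, not
    marker density)."""
    return GenomeModel.from_scaled_human(5_000, scale=0.10)


@pytest.fixture(scope="session")
def sib_pairs(desk_genome):
    """20 gene-dropped full-sibling pairs (default noise), reused across tests."""
    return [scenario("full_sib", desk_genome, seed=100 + i) for i in range(20)]


def make_table(rows, samples):
    """Build a GenotypeTable from (marker_id, chrom, pos, calls...) rows."""
    markers = pd.DataFrame(
        [(r[0], r[1], r[2]) for r in rows],
        columns=["marker_id", "chromosome", "position"],
    )
    code = {"AA": 0, "AB": 1, "BA": 1, "BB": 2, "NC": -1}
    calls = np.array([[code[c] for c in r[3:]] for r in rows], dtype=np.int8)
    return GenotypeTable(markers, list(samples), calls)


@pytest.fixture
def tiny_table():
    """Five markers, two samples, hand-checkable IBS states."""
    return make_table(
        [
            ("m1", "1", 100, "AA", "AA"),
            ("m2", "1", 200, "AB", "AB"),
            ("m3", "1", 300, "AA", "BB"),
            ("m4", "2", 100, "AA", "AB"),
            ("m5", "2", 200, "AB", "NC"),
        ],
        ["s1", "s2"],
    )
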