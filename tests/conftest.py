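"""Shared fixtures: the published-style population panel and a seeded
default synthetic scenario reused across test modules."""

import numpy as np
import pytest

from repadapt import io_tables, synthetic

# Population phenotyping table: id, proportion surviving field-rate
# glyphosate, and which study arm used it (E = candidate-gene sequencing,
# P = population genomics).
PANEL_TSV = """population\tsurvival\tusage
SH4\t0.1\tE,P
CR\t0.21\tE
IN12\t0.25\tE
MA1\t0.25\tE
SN\t0.5\tE
RB\t0.18\tP
HA\t0.15\tP
FL\t0.20\tP
MC\t0.67\tE
CL1\t0.73\tE
VA2\t0.82\tE
WG\t0.83\tE,P
BI\t1\tE,P
DW\t1\tE,P
SPC\t0.71\tP
"""


@pytest.fixture(scope="session")
def panel_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("panel") / "panel.tsv"
    p.write_text(PANEL_TSV)
    return p


@pytest.fixture(scope="session")
def study_panel(panel_path):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SN sits exactly at 0.5
        return io_tables.read_panel(panel_path)


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario (genotypes, panel, annotation, truth)."""
    return synthetic.make_default_scenario(seed=11)


@pytest.fixture()
def tiny_gm():
    """Hand-sized genotype matrix: 2 populations x 3 diploids, 6 sites."""
    G = np.array(
        [
            [0, 1, 2, 0, 0, 1],
            [2, 2, 2, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 0, 2, 2, 2],
            [0, 0, 1, 0, 1, 0],
            [2, 1, 2, 2, 2, 1],
        ],
        dtype=np.int16,
    )  # 6 sites x 6 samples
    samples = [f"A_{i}" for i in range(1, 4)] + [f"B_{i}" for i in range(1, 4)]
    return io_tables.GenotypeMatrix(
        samples=samples,
        populations={s: s.split("_")[0] for s in samples},
        chrom=np.array(["chr1"] * 6, dtype=object),
        pos=np.arange(100, 700, 100),
        ref=np.array(["A"] * 6, dtype=object),
        alt=np.array(["T"] * 6, dtype=object),
        G=G,
        ancestral=np.array(["A"] * 6, dtype=object),
    )
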