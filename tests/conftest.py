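"""Shared fixtures: small simulated panels and a toy HapMap file."""

import numpy as np
import pandas as pd
import pytest

from haplogs import (SimConfig, apply_field_layout, simulate_phenotypes,
                     simulate_population)
from haplogs.genio import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, cluster_sizes=(40, 30, 30), n_chromosomes=3,
                     markers_per_chromosome=(60,) * 3, n_qtl=20,
                     field_rows=10, field_cols=10)


@pytest.fixture(scope="session")
def small_pop(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_pheno(small_pop, small_config):
    pheno = simulate_phenotypes(small_pop, small_config)
    return apply_field_layout(pheno, small_config)


@pytest.fixture()
def toy_genotypes():
    """Three lines, four markers, hand-written dosages with one het."""
    dosages = np.array([
        [2, 2, 0, 1],
        [2, 0, 2, 0],
        [0, 0, 2, 2],
    ], dtype=np.int8)
    return GenotypeMatrix(
        line_ids=["L1", "L2", "L3"],
        marker_ids=["m1", "m2", "m3", "m4"],
        dosages=dosages,
        allele_labels=[("A", "T"), ("C", "G"), ("G", "A"), ("A", "T")],
    )


@pytest.fixture()
def toy_hapmap(tmp_path):
    """A hand-written HapMap file exercising call dialects."""
    header = ("rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID"
              "\tassayLSID\tpanelLSID\tQCcode\tL1\tL2\tL3")
    rows = [
        "m1\tA/T\t1\t1.5\t+\tNA\tNA\tNA\tNA\tNA\tNA\tA\tA\tT",       # 2,2,0
        "m2\tA/T\t1\t3.0\t+\tNA\tNA\tNA\tNA\tNA\tNA\tW\tAA\tNN",     # 1,2,-1
        "m3\tC/G\t2\t0.25\t+\tNA\tNA\tNA\tNA\tNA\tNA\tCG\tGG\tC",    # 1,0,2
    ]
    path = tmp_path / "toy.hmp.txt"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def make_flat_field(rows=12, cols=12, trial="t1", fill=0.0):
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return pd.DataFrame({
        "line_id": [f"L{i}" for i in range(rows * cols)],
        "trial": trial,
        "row": rr.ravel().astype(float),
        "col": cc.ravel().astype(float),
        "y": float(fill),
    })
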