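"""Shared fixtures: toy ontologies, association tables, small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from goglm.nbsim import SimParams
from goglm.ontology import parse_associations, parse_obo, propagate

CHAIN_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002 ! mid
"""

# diamond: leaf has two parents sharing a grandparent; one edge is part_of
DIAMOND_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: left parent
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: right parent
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: diamond child
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000003
"""

SELF_LOOP_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: loop
namespace: biological_process
is_a: GO:0000001
"""

CYCLE_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: a
namespace: biological_process
is_a: GO:0000002

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0000001
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


@pytest.fixture
def diamond_obo(tmp_path):
    path = tmp_path / "diamond.obo"
    path.write_text(DIAMOND_OBO)
    return path


@pytest.fixture
def self_loop_obo(tmp_path):
    path = tmp_path / "self_loop.obo"
    path.write_text(SELF_LOOP_OBO)
    return path


@pytest.fixture
def cycle_obo(tmp_path):
    path = tmp_path / "cycle.obo"
    path.write_text(CYCLE_OBO)
    return path


@pytest.fixture
def chain_dag(chain_obo):
    return parse_obo(chain_obo)


@pytest.fixture
def chain_annotation(tmp_path, chain_dag):
    path = tmp_path / "assoc.tsv"
    path.write_text("g1\tGO:0000003\ng2\tGO:0000002\n")
    ann = parse_associations(path, dag=chain_dag)
    return propagate(chain_dag, ann)


@pytest.fixture
def small_sim_params():
    """A small, fast simulation design for unit tests."""
    sizes = (101, 110, 120, 130, 135, 140, 150, 154)  # sums to 1040
    return SimParams(
        n_genes=1040,
        n_categories=8,
        category_sizes=np.array(sizes),
        enriched_category_count=3,
        enriched_categories=(2, 5, 7),
        enriched_log2_fc_grid=(1.0, 0.7, 0.5),
        median_gene_mean=20.0,
    )


def make_table_universe(n11: int, n12: int, n21: int, n22: int):
    """Gene universe + DE flags + member set realizing a given 2x2 table."""
    n = n11 + n12 + n21 + n22
    gene_ids = np.array([f"g{i}" for i in range(n)])
    de = np.concatenate(
        [np.ones(n11), np.zeros(n12), np.ones(n21), np.zeros(n22)]
    ).astype(int)
    members = set(gene_ids[: n11 + n12])
    universe = pd.DataFrame({"gene_id": gene_ids, "length": np.ones(n)})
    return universe, de, members
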