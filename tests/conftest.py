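import numpy as np
import pytest

from facsex.degeneracy_filter import build_site_table, filter_complete_sites, annotate_degeneracy
from facsex.polarize import DerivedMatrix, build_ancestral_sequence, build_derived_matrix, polarize_all
from facsex.synthetic_data import simulate_two_lineages


@pytest.fixture(scope="session")
def two_lineage():
    """One fixed two-lineage dataset with recorded truth."""
    return simulate_two_lineages(seed=11, latitude_effect=2e-5)


@pytest.fixture(scope="session")
def pipeline(two_lineage):
    """The dataset pushed through polarization and annotation."""
    ds = two_lineage
    table = build_site_table(ds.genomes, ds.models)
    table = filter_complete_sites(table, ds.genomes)
    pol = polarize_all(ds.genomes, table, "EU", "FE")
    anc = build_ancestral_sequence(pol, ds.genomes)
    table = annotate_degeneracy(anc, ds.models, table)
    derived = build_derived_matrix(pol, ds.genomes, "EU", "FE")
    return {
        "dataset": ds,
        "table": table,
        "polarized": pol,
        "ancestral": anc,
        "derived": derived,
    }


def make_derived_matrix(mat, pop="P"):
    """Wrap a plain 0/1 array as a DerivedMatrix for unit tests."""
    mat = np.asarray(mat, dtype=np.uint8)
    ids = [f"s{i}" for i in range(mat.shape[0])]
    return DerivedMatrix(
        matrix=mat,
        strain_ids=ids,
        population={s: pop for s in ids},
        site_coords=np.arange(mat.shape[1]),
        status=np.array(["polymorphic_popA"] * mat.shape[1], dtype=object),
    )
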