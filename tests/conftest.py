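import numpy as np
import pytest

from saelgmda.io_formats import AssociationMatrix
from saelgmda.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Planted-block dataset small enough for fast end-to-end plumbing."""
    return generate_fixture(
        FixtureSpec(
            n_diseases=10,
            n_microbes=20,
            n_blocks=4,
            within_block_density=0.6,
            background_density=0.04,
            genes_per_disease=6,
            block_pool_genes=12,
            seed=11,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_assoc(rng):
    """Random 6x8 association matrix with at least one association."""
    values = (rng.random((6, 8)) < 0.3).astype(np.int8)
    values[0, 0] = 1
    return AssociationMatrix(
        values,
        tuple(f"d{i}" for i in range(6)),
        tuple(f"m{j}" for j in range(8)),
    )


@pytest.fixture()
def edge_file(tmp_path):
    def write(rows, name="edges.tsv", header=False):
        path = tmp_path / name
        lines = ["disease_id\tmicrobe_id"] if header else []
        lines += ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
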