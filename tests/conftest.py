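import numpy as np
import pandas as pd
import pytest

from hippomaturity.deg_io import DEGList
from hippomaturity.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for unit tests: same structure, smaller numbers."""
    return SimulationConfig(
        n_genes_universe=4000,
        signature_size=200,
        n_models=6,
        concordance_grid=(0.9, 0.6, 0.3, 0.0, -0.5, -0.9),
        n_background_degs=150,
        seed=11,
    )


def toy_deg(rows, dataset_id="toy", **kwargs) -> DEGList:
    """Build a DEGList from (gene_id, log2fc, pvalue) tuples."""
    records = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
    return DEGList(dataset_id=dataset_id, records=records, **kwargs)


def random_deg(rng, n, universe_size=20000, dataset_id="rand") -> DEGList:
    """An unstructured DEG list: random genes, signs, magnitudes."""
    genes = rng.choice(universe_size, size=n, replace=False)
    rows = [
        (f"G{g:05d}", float(s * m), float(p))
        for g, s, m, p in zip(
            genes,
            rng.choice([1, -1], n),
            rng.uniform(0.3, 2.0, n),
            rng.uniform(1e-4, 0.05, n),
        )
    ]
    return toy_deg(rows, dataset_id=dataset_id)
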