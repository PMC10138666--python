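import logging

import pytest

from metacross import decompose_pathway, gen_metabolic_pathway, make_study

logging.getLogger("metacross").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def chain_pathway():
    """Smallest acyclic chain: M1 -> R1 -> M2 -> R2 -> M3."""
    return gen_metabolic_pathway(n_metabolites=3, n_reactions=2,
                                 reversible_frac=0, loop_frac=0,
                                 genes_per_reaction=1, seed=1)


@pytest.fixture(scope="session")
def chain_subpathways(chain_pathway):
    return decompose_pathway(chain_pathway)


@pytest.fixture(scope="session")
def small_study():
    """Compact planted study shared by read-only tests."""
    return make_study(n_pathways=2, n_metabolites=4, n_reactions=3,
                      n_circuits=3, circuit_nodes=4, n_pairs=20, seed=42)
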