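"""Shared fixtures: one demo proteome and its search results, computed once.

The demo mirrors the package's reference scenario: one 20-member 7-TM family
at divergence 0.5, 200 globular decoys and 10 N-half proteins, searched from
a 3-member seed alignment.
"""
import pytest

from pqloop.search import SearchConfig, iterate_search
from pqloop.synthetic import FamilySpec, make_proteome


@pytest.fixture(scope="session")
def demo_proteome():
    spec = FamilySpec(seed=0)
    proteome, truth = make_proteome([spec], n_decoys=200, n_half_proteins=10,
                                    seed=11)
    return proteome, truth


@pytest.fixture(scope="session")
def demo_seed_msa(demo_proteome):
    _, truth = demo_proteome
    members = truth.family_records["fam0"]
    return truth.family_truths["fam0"].induced_alignment(members[:3])


@pytest.fixture(scope="session")
def strict_result(demo_proteome, demo_seed_msa):
    proteome, _ = demo_proteome
    return iterate_search(demo_seed_msa, proteome, SearchConfig(), seed=11)


@pytest.fixture(scope="session")
def loose_result(demo_proteome, demo_seed_msa):
    proteome, _ = demo_proteome
    config = SearchConfig(require_all_segments=False)
    return iterate_search(demo_seed_msa, proteome, config, seed=11)
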