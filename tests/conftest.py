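import pytest

import gensi as G

ACYL_IDS = ["acylst_c", "acylpa_c", "acylol_c", "acyloc_c"]
POOLED_IDS = ["rtot2_c", "rtot3_c"]


@pytest.fixture(scope="session")
def toy_config():
    return G.ToyConfig()


@pytest.fixture(scope="session")
def toy_gem(toy_config):
    return G.make_toy_gem(toy_config)


@pytest.fixture(scope="session")
def toy_expression(toy_config):
    return G.make_toy_expression(toy_config)


@pytest.fixture(scope="session")
def media_panel(toy_config):
    return G.make_media_panel(toy_config)


@pytest.fixture(scope="session")
def toy_ras(toy_gem, toy_expression):
    """RAS table from the full preprocessing pipeline."""
    rnaseq, microarray = toy_expression
    adjusted = G.zero_adjust(rnaseq, microarray)
    genes = set()
    for expr in toy_gem.gprs.values():
        genes |= G.gpr_genes(expr)
    matched, _ = G.match_genes(genes, adjusted)
    return G.compute_ras(toy_gem, matched)


@pytest.fixture(scope="session")
def gensi_models(toy_gem, toy_expression, media_panel):
    """GEM-RAS-MUR models for all six media at alpha = 10 (the high-α
    plateau, where only the medium limits growth)."""
    rnaseq, microarray = toy_expression
    return {
        m.name: G.build_gensi_model(toy_gem, rnaseq, m, alpha=10.0,
                                    microarray=microarray)
        for m in media_panel
    }


@pytest.fixture(scope="session")
def mini_fixtures():
    return G.make_mini_fixtures()
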