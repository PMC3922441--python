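import pytest

from snapanel.fixtures import build_toy_genome, load_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixtures()


@pytest.fixture(scope="session")
def toy_genome(fixture_set):
    return build_toy_genome(fixture_set, seed=1)


@pytest.fixture(scope="session")
def bcl_panel(fixture_set):
    return fixture_set.panel("BCL11A")


@pytest.fixture(scope="session")
def hbs_panel(fixture_set):
    return fixture_set.panel("HBS1L-MYB")


@pytest.fixture(scope="session")
def toy_designed_panel(toy_genome):
    """A 16-plex panel freshly designed on the toy genome, so all
    same-dye products honour the 4 nt stagger."""
    from snapanel.core import PanelDesign, PcrPrimerPair
    from snapanel.minidesign import build_extension_panel

    targets = [t for t in toy_genome.targets if t.locus_label == "HBS1L-MYB"]
    result = build_extension_panel(targets, toy_genome.contexts())
    assert not result.failures
    pairs = [
        PcrPrimerPair([t.rsid for t in targets], "A" * 20, "C" * 20, "A", 700)
    ]
    return PanelDesign("toy16", targets, pairs, result.primers)
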