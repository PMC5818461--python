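import pytest

from crckit.simulate import InsertionEvent, make_background, plant_elements
from crckit.templates import default_family_templates, nonautonomous_templates


@pytest.fixture(scope="session")
def families():
    return default_family_templates()


@pytest.fixture(scope="session")
def nonauto():
    return nonautonomous_templates()


@pytest.fixture(scope="session")
def small_genome(families):
    """300-kb genome with a handful of planted elements of mixed age/decay."""
    bg = make_background(300_000, 0.38, 11)
    events = [
        InsertionEvent("A", 20_000, age_years=0.0, event_id="e_a0"),
        InsertionEvent("B", 70_000, age_years=1e6, event_id="e_b1"),
        InsertionEvent("H", 130_000, age_years=2e6, event_id="e_h2"),
        InsertionEvent("C", 190_000, age_years=3e6, event_id="e_c3"),
        InsertionEvent("E", 250_000, age_years=0.5e6, decay="fragment", fragment_fraction=0.3, event_id="e_frag"),
    ]
    genome, truth = plant_elements(bg, families, events, seed=11, genome_id="chrT")
    return genome, truth
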