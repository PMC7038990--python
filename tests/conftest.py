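import numpy as np
import pytest

from cascreen import simulate as sim


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_locus():
    """Toy CRISPR locus: 10 repeats / 9 spacers, tracrRNA region, planted
    crRNA and tracrRNA species, plus a 30-nt species for filter tests."""
    return sim.make_toy_locus(seed=3, add_short_species=True)


@pytest.fixture(scope="session")
def planted_screen_counts():
    """Molecule-level planted screen (G required at 5, A preferred at 7)
    at 100x mean depth, one fixed seed."""
    model = sim.planted_nnnngna_model()
    exp, ctrl, truth = sim.simulate_screen_counts(
        model, 1_638_400, 1_638_400, seed=1)
    return exp, ctrl, truth
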