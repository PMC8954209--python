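import numpy as np
import pytest

from vftriage import VagueNumber, load_case_study

# Weight vectors as published with the bundled case study (2-decimal).
PUBLISHED_EXPERT_WEIGHTS = [0.12, 0.19, 0.16, 0.30, 0.23]
PUBLISHED_CRITERIA_WEIGHTS = [0.21, 0.39, 0.09, 0.16, 0.15]

# Published per-expert and per-criterion scores feeding the normalizations.
PUBLISHED_EXPERT_SCORES = [0.33, 0.54, 0.46, 0.83, 0.64]
PUBLISHED_CRITERIA_SCORES = [0.37, 0.70, 0.16, 0.28, 0.27]

# Published collective matrix (criteria x patients) and patient aggregates.
PUBLISHED_COLLECTIVE = [
    [(0.444, 0.679), (0.685, 0.852), (0.402, 0.848), (0.611, 0.709), (0.767, 0.871)],
    [(0.575, 0.939), (0.593, 0.736), (0.591, 0.878), (0.547, 0.929), (0.540, 0.786)],
    [(0.640, 0.766), (0.352, 0.787), (0.672, 0.771), (0.486, 0.864), (0.603, 0.725)],
    [(0.566, 0.764), (0.632, 0.860), (0.414, 0.847), (0.634, 0.847), (0.554, 0.916)],
    [(0.489, 0.537), (0.390, 0.773), (0.551, 0.804), (0.633, 0.796), (0.665, 0.890)],
]
PUBLISHED_AGGREGATES = [
    (0.536, 0.766),
    (0.553, 0.789),
    (0.515, 0.845),
    (0.580, 0.840),
    (0.608, 0.832),
]
PUBLISHED_RANKING = ("P5", "P4", "P3", "P2", "P1")


@pytest.fixture(scope="session")
def case_study():
    return load_case_study()


def random_vague(rng: np.random.Generator) -> VagueNumber:
    """A uniformly random valid vague number (upper bound, then t below it)."""
    u = rng.uniform(0.0, 1.0)
    t = rng.uniform(0.0, u)
    return VagueNumber(t, u)


def random_weights(rng: np.random.Generator, n: int) -> list[float]:
    w = rng.dirichlet(np.ones(n))
    return list(w / w.sum())
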