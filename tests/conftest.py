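import random

import pytest

import relgraph as rg

GREEN = (0, 255, 0)
RED = (255, 0, 0)


@pytest.fixture
def food_space():
    return rg.TermSpace("foods", "food", GREEN, ("pepper", "milk", "yogurt", "oat"))


@pytest.fixture
def disease_space():
    return rg.TermSpace(
        "diseases", "disease", RED, ("stroke", "diabetes", "high cholesterol")
    )


@pytest.fixture
def planted_corpus(food_space, disease_space):
    """Small corpus with known pair counts, plus noise."""
    spec = rg.PlantedSpec(
        pair_counts={
            ("pepper", "stroke"): 5,
            ("milk", "diabetes"): 2,
            ("yogurt", "high cholesterol"): 3,
        },
        noise_docs=4,
        seed=11,
    )
    return rg.generate_synthetic_corpus(spec, food_space, disease_space), spec


def make_planted_replicate(seed: int, n_a: int = 8, n_b: int = 8, n_pairs: int = 22,
                           noise: int = 40):
    """Seeded planted corpus spanning counts 1-200, total size <= 500 docs."""
    rng = random.Random(seed)
    space_a = rg.TermSpace(
        "foods", "food", GREEN, tuple(f"fooditem{i}" for i in range(n_a))
    )
    space_b = rg.TermSpace(
        "conds", "disease", RED, tuple(f"condition{i}" for i in range(n_b))
    )
    all_pairs = [(a, b) for a in space_a.terms for b in space_b.terms]
    chosen = rng.sample(all_pairs, n_pairs)
    pairs = {chosen[0]: 200, chosen[1]: rng.randint(80, 120)}
    for a, b in chosen[2:]:
        pairs[(a, b)] = rng.randint(1, 8)
    spec = rg.PlantedSpec(pair_counts=pairs, noise_docs=noise, seed=seed)
    corpus = rg.generate_synthetic_corpus(spec, space_a, space_b)
    return corpus, spec, space_a, space_b
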