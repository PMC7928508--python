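import numpy as np
import pytest

from pedigreml.pedigree import UNKNOWN, Pedigree, build_pedigree


def random_pedigree(rng, n_animals, n_founders=None, p_unknown=0.1):
    """Random valid pedigree: parents drawn from earlier animals."""
    n_founders = n_founders or max(4, n_animals // 5)
    recs = [(f"F{i}", None, None, 0, "M" if i % 2 else "F")
            for i in range(n_founders)]
    gen = {f"F{i}": 0 for i in range(n_founders)}
    for i in range(n_founders, n_animals):
        pool = [r[0] for r in recs]
        s = d = None
        if rng.random() > p_unknown:
            s = pool[rng.integers(len(pool))]
        if rng.random() > p_unknown:
            d = pool[rng.integers(len(pool))]
            if d == s:
                d = None
        g = 1 + max([gen[p] for p in (s, d) if p is not None], default=-1)
        name = f"X{i}"
        gen[name] = g
        recs.append((name, s, d, g, None))
    return build_pedigree(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def trio():
    """Two unrelated founders and one offspring."""
    return build_pedigree([("s", None, None, 0, "M"),
                           ("d", None, None, 0, "F"),
                           ("x", "s", "d", 1, None)])


@pytest.fixture
def fullsib_mating():
    """Full sibs mated: their offspring has F = 0.25."""
    return build_pedigree([("s", None, None, 0), ("d", None, None, 0),
                           ("b1", "s", "d", 1), ("b2", "s", "d", 1),
                           ("o", "b1", "b2", 2)])
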