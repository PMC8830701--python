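import numpy as np
import pytest

from crninfer.library import AnsatzLibrary, SpeciesSet, parse_reaction


@pytest.fixture(scope="session")
def decay_library():
    """4-candidate toy library around a single linear conversion A -> B."""
    sp = SpeciesSet(("A", "B"))
    return AnsatzLibrary(
        sp, [parse_reaction(s, sp) for s in ("A -> B", "A -> 0", "B -> 0", "B -> A")]
    )


@pytest.fixture(scope="session")
def decay_truth():
    """True rate vector for the decay toy: only A -> B at rate 0.5."""
    return np.array([0.5, 0.0, 0.0, 0.0])


def mean_abs_log_error(a, b, floor=1e-10):
    """Mean |log a - log b| over matching arrays of positive values."""
    a = np.maximum(np.asarray(a, dtype=float), floor)
    b = np.maximum(np.asarray(b, dtype=float), floor)
    return float(np.mean(np.abs(np.log(a) - np.log(b))))
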