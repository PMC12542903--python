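import numpy as np
import pytest

from hivbia import paper_fixture, run_model


@pytest.fixture(scope="session")
def paper_bundle():
    """Reference bundle; calibration runs once per session."""
    return paper_fixture()


@pytest.fixture(scope="session")
def paper_result(paper_bundle):
    return run_model(paper_bundle)


def loop_prevalent(size0, age0, mortality, baseline, young, old, threshold,
                   reduction, n_years, rule="at-risk"):
    """Independent per-cycle reference for the prevalent-count recurrence.

    Deliberately written as a plain sequential loop with scalar state and
    explicit band selection, not sharing any code with the engine.
    """
    out = [baseline]
    alive, prev, age = float(size0), float(baseline), float(age0)
    for k in range(n_years - 1):
        rate = old if age >= threshold else young
        rate = rate * (1.0 - reduction) ** k
        if rule == "at-risk":
            incident = rate * (alive - prev)
        else:
            incident = rate * alive
        alive = alive * (1.0 - mortality)
        prev = min((prev + incident) * (1.0 - mortality), alive)
        age += 1.0
        out.append(prev)
    return np.array(out)


@pytest.fixture
def loop_oracle():
    return loop_prevalent
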