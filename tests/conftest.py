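import numpy as np
import pytest

from btxrisk.exposure import DoseGroup


def make_groups(family_probs, n_per_group, doses, rng=None, analyte="benzene"):
    """Dose groups with cases drawn (or set exactly) from given probabilities."""
    groups = []
    for i, (d, p) in enumerate(zip(doses, family_probs)):
        if rng is None:
            cases = int(round(n_per_group * p))
        else:
            cases = int(rng.binomial(n_per_group, p))
        groups.append(
            DoseGroup(analyte=analyte, index=i, low=0.0, high=0.0, dose=float(d),
                      n=n_per_group, cases=cases)
        )
    return groups


@pytest.fixture
def multistage_groups():
    """8-group one-stage multistage design (g=0.05, b1=0.1), n=100/group."""
    doses = np.array([0.1, 0.3, 0.6, 1.0, 1.5, 2.2, 3.0, 4.5])
    g, b1 = 0.05, 0.1
    probs = g + (1 - g) * (1 - np.exp(-b1 * doses))
    rng = np.random.default_rng(42)
    return make_groups(probs, 100, doses, rng)
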