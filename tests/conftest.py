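import numpy as np
import pytest

from oxibalance import SimulationConfig, simulate_cohort
from oxibalance.pipeline import demo_config


@pytest.fixture(scope="session")
def demo_cohort():
    """A mid-sized cohort with planted genetic and exposure effects."""
    return simulate_cohort(demo_config(seed=11, n=700))


@pytest.fixture(scope="session")
def null_cohort():
    """A small cohort with every planted effect null."""
    return simulate_cohort(SimulationConfig(n_participants=180, seed=5))


def exact_hwe_pvalues(n_genotypes: int, n_minor: int):
    """Independent enumeration oracle in exact integer arithmetic.

    Weights w(h) = multinomial(n; hom_rare, h, hom_common) * 2^h are exact
    Python integers; p-values are correctly rounded ratios of integer
    sums.  The tie rule (include w_j <= w * (1 + 1e-9)) is evaluated as
    the exact integer inequality w_j * 10^9 <= w * (10^9 + 1).
    """
    from math import comb

    h_min = n_minor % 2
    h_max = min(n_minor, 2 * n_genotypes - n_minor)
    hets = list(range(h_min, h_max + 1, 2))
    ws = []
    for h in hets:
        hom_r = (n_minor - h) // 2
        ws.append(comb(n_genotypes, hom_r) * comb(n_genotypes - hom_r, h) * (1 << h))
    total = sum(ws)
    ws_sorted = sorted(ws)
    prefix = [0]
    for w in ws_sorted:
        prefix.append(prefix[-1] + w)
    pv = []
    for w in ws:
        bound = w * 1000000001
        lo, hi = 0, len(ws_sorted)
        while lo < hi:  # largest j with ws_sorted[j-1]*1e9 <= bound
            mid = (lo + hi) // 2
            if ws_sorted[mid] * 1000000000 <= bound:
                lo = mid + 1
            else:
                hi = mid
        pv.append(min(prefix[lo] / total, 1.0))
    return np.array(hets), np.array(pv)
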