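import numpy as np
import pytest

from antagmap.sumstats_io import SumstatsRecord, TargetSnp
from antagmap.synthetic_data import table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The published-grid fixture with FDR adjusted at m = 869."""
    fx = table1_fixture()
    fx.grid.adjust(alpha=0.05)
    return fx


@pytest.fixture
def rs9329221_target():
    return TargetSnp(
        snp_id="rs9329221", chrom="8", pos=10240202,
        risk_allele="T", other_allele="G",
        disorder_risk="SCZ", disorder_protective="ASD",
    )


@pytest.fixture
def rs9329221_record():
    """The published superior-temporal SA association, harmonized to T."""
    return SumstatsRecord(
        snp_id="rs9329221", chrom="8", pos=10240202,
        effect_allele="T", other_allele="G",
        effect=-12.496, pvalue=7.93e-12,
    )


def bruteforce_bh(pvalues, m=None):
    """O(m^2) direct implementation of the step-up definition.

    adjusted_i = min over j with p_(j) >= p_(i) of min(1, m * p_(j) / rank(j)),
    with the padded tests at p = 1 occupying the trailing ranks.
    """
    p = list(pvalues)
    k = len(p)
    m = k if m is None else m
    order = sorted(range(k), key=lambda i: p[i])
    adj = [None] * k
    for pos_i, i in enumerate(order):
        best = 1.0  # the padded p = 1 entries give m*1/rank >= 1 for every rank
        for pos_j, j in enumerate(order):
            if p[j] >= p[i]:
                best = min(best, min(1.0, m * p[j] / (pos_j + 1)))
        adj[i] = best
    return np.array(adj)


def assert_matches_printed(computed, printed, sig_figs=3):
    """Agreement with a printed value at its precision.

    The printed raw inputs are themselves rounded to ``sig_figs`` significant
    figures, so the recomputed value may legitimately differ from the printed
    one by one unit in the last printed digit; anything larger fails.
    """
    import math

    ulp = 10.0 ** (math.floor(math.log10(abs(printed))) - (sig_figs - 1))
    rounded = float(f"{computed:.{sig_figs - 1}e}")
    assert abs(rounded - printed) <= ulp * 1.000001, (
        f"computed {computed!r} (rounds to {rounded!r}) vs printed {printed!r}"
    )
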