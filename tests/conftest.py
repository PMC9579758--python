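import itertools
import math

import pytest
from hypothesis import settings

from codprov.panel_io import (
    AlleleCountTable,
    InversionLocus,
    ReferencePanel,
    SNPSite,
)
from codprov.simulate import SimConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def toy_panel(f_lg1=(0.0, 1.0)) -> ReferencePanel:
    """Two-population panel with 2 genome-wide sites per cluster and one
    diagnostic site per inversion."""
    gw = [SNPSite("LG03", 1000, "A", "G"), SNPSite("LG03", 2000, "C", "T")]
    clusters = {
        "western_atlantic": {gw[0]: 0.1, gw[1]: 0.2},
        "eastern_atlantic": {gw[0]: 0.9, gw[1]: 0.8},
        "baltic": {gw[0]: 0.9, gw[1]: 0.2},
    }
    pops = ["popA", "popB"]
    inversions = {}
    for i, name in enumerate(("LG1", "LG2", "LG7", "LG12")):
        lg = {"LG1": "LG01", "LG2": "LG02", "LG7": "LG07", "LG12": "LG12"}[name]
        site = SNPSite(lg, 500, "A", "G")
        if name == "LG1":
            freqs = {"popA": f_lg1[0], "popB": f_lg1[1]}
        else:
            freqs = {"popA": 0.2 + 0.1 * i, "popB": 0.8 - 0.1 * i}
        inversions[name] = InversionLocus(name, [site], freqs)
    return ReferencePanel(
        clusters=clusters,
        inversions=inversions,
        candidate_populations=pops,
        population_clusters={"popA": "eastern_atlantic", "popB": "eastern_atlantic"},
    )


@pytest.fixture
def two_pop_panel() -> ReferencePanel:
    return toy_panel()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-conditions fixture: 3 clusters, 12 populations,
    50 genome-wide sites, depth lambda 5, err 0.01, 200 specimens, seed 42."""
    return simulate_cohort(SimConfig())


# ---------------------------------------------------------------------------
# independent oracles


def enumeration_site_log_prob(alt_count: int, depth: int, q: float) -> float:
    """P(alt_count | depth, q) by enumerating every per-read outcome
    sequence — independent of any binomial pmf implementation."""
    total = 0.0
    for reads in itertools.product((0, 1), repeat=depth):
        if sum(reads) != alt_count:
            continue
        p = 1.0
        for r in reads:
            p *= q if r == 1 else (1.0 - q)
        total += p
    if total == 0.0:
        return -math.inf
    return math.log(total)


def enumeration_cluster_loglik(counts, freqs, err):
    """Per-read enumeration analogue of cluster_log_likelihood."""
    ll = 0.0
    for site, f in freqs.items():
        ref_n, alt_n = counts.counts.get(site, (0, 0))
        depth = ref_n + alt_n
        if depth == 0:
            continue
        q = f * (1 - err) + (1 - f) * err
        ll += enumeration_site_log_prob(alt_n, depth, q)
    return ll


def enumeration_inversion_posterior(counts, err):
    """Per-read enumeration analogue of inversion_genotype_posterior.

    ``counts`` is a list of (ref, alt) pairs at diagnostic sites.
    """
    liks = []
    for d in (0, 1, 2):
        q = (d / 2) * (1 - 2 * err) + err
        ll = 0.0
        for ref_n, alt_n in counts:
            depth = ref_n + alt_n
            if depth == 0:
                continue
            ll += enumeration_site_log_prob(alt_n, depth, q)
        liks.append(ll)
    m = max(liks)
    if m == -math.inf:
        return (1 / 3, 1 / 3, 1 / 3)
    w = [math.exp(l - m) for l in liks]
    s = sum(w)
    return tuple(x / s for x in w)


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration over all
    tables with the observed margins, summing probabilities <= the
    observed table's (1e-12 relative slack on the comparison)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def hyper(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = hyper(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        hyper(x) for x in range(lo, hi + 1) if hyper(x) <= p_obs * (1 + 1e-12)
    )


def make_counts(specimen_id, sites_counts):
    """AlleleCountTable from {SNPSite: (ref, alt)}."""
    return AlleleCountTable(specimen_id, dict(sites_counts))
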