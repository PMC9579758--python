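"""Hierarchical genome-wide cluster assignment.

Each specimen is first assigned between the western and eastern Atlantic
clusters from genome-wide (inversion-excluded) allele counts; specimens
favouring the eastern cluster are then tested for a Baltic Sea origin.

The classifier is a per-site binomial allele-frequency likelihood: at a
site with population alt-allele frequency *f* and per-read error *err*,
each read reports the alt allele with probability

    q = f (1 - err) + (1 - f) err

and the observed alt count at depth *n* is Binomial(n, q). Sites are
treated as independent (linkage between panel sites is ignored, a
documented approximation), and reads within a site as independent draws.
Posteriors are the softmax of the per-cluster log-likelihoods plus log
priors. Numerical equivalence with PCA-database assignment software is not
claimed; the contract — posterior membership in the three clusters — is
what downstream stages consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import binom

from .panel_io import AlleleCountTable, ReferencePanel, SNPSite

DEFAULT_ERR = 0.01

WESTERN = "western_atlantic"
EASTERN = "eastern_atlantic"
BALTIC = "baltic"
EASTERN_NONBALTIC = "eastern_nonbaltic"


@dataclass
class ClusterAssignment:
    """Two-stage posterior cluster membership for one specimen.

    ``stage2`` is present only when stage 1 favours the eastern cluster.
    ``uninformative`` flags a specimen with zero depth at every panel site,
    whose posteriors are just the priors.
    """

    specimen_id: str
    stage1: dict[str, float]
    stage2: dict[str, float] | None
    n_informative_sites: int
    uninformative: bool = False

    @property
    def assigned_cluster(self) -> str:
        """Final cluster label: western_atlantic, baltic, or
        eastern_atlantic (eastern, non-Baltic)."""
        if self.stage1[WESTERN] > self.stage1[EASTERN]:
            return WESTERN
        if self.stage2 is not None and self.stage2[BALTIC] > self.stage2[EASTERN_NONBALTIC]:
            return BALTIC
        return EASTERN


def cluster_log_likelihood(
    counts: AlleleCountTable,
    freqs: Mapping[SNPSite, float],
    err: float = DEFAULT_ERR,
) -> tuple[float, int]:
    """Log-likelihood of the observed counts under one cluster's per-site
    alt-allele frequencies.

    Returns ``(log_likelihood, n_informative_sites)``; sites with zero depth
    (or absent from the table) contribute nothing. A fully uncovered table
    yields (0.0, 0).
    """
    if not 0.0 <= err < 0.5:
        raise ValueError(f"err must be in [0, 0.5), got {err}")
    loglik = 0.0
    n_informative = 0
    for site, f in freqs.items():
        ref_n, alt_n = counts.counts.get(site, (0, 0))
        depth = ref_n + alt_n
        if depth == 0:
            continue
        n_informative += 1
        q = f * (1.0 - err) + (1.0 - f) * err
        loglik += binom.logpmf(alt_n, depth, q)
    return float(loglik), n_informative


def assign_stage(
    counts: AlleleCountTable,
    panel: ReferencePanel,
    clusters: tuple[str, str],
    err: float = DEFAULT_ERR,
    prior: tuple[float, float] = (0.5, 0.5),
) -> tuple[dict[str, float], int, bool]:
    """Posterior over a pair of clusters: softmax of log-likelihood + log prior.

    Returns ``(posterior map, n_informative_sites, uninformative flag)``.
    With no informative site the posterior equals the prior.
    """
    if not math.isclose(sum(prior), 1.0, abs_tol=1e-9):
        raise ValueError("prior must sum to 1")
    for c in clusters:
        if c not in panel.clusters:
            raise KeyError(f"cluster {c!r} not in panel")
    logliks = []
    n_info = 0
    for c, p in zip(clusters, prior):
        ll, n = cluster_log_likelihood(counts, panel.clusters[c], err)
        logliks.append(ll + (math.log(p) if p > 0 else -math.inf))
        n_info = max(n_info, n)
    if n_info == 0:
        return dict(zip(clusters, prior)), 0, True
    arr = np.array(logliks)
    arr -= arr.max()
    w = np.exp(arr)
    w /= w.sum()
    return dict(zip(clusters, w.tolist())), n_info, False


def hierarchical_assign(
    counts: AlleleCountTable,
    panel: ReferencePanel,
    err: float = DEFAULT_ERR,
    stage2_threshold: float = 0.5,
) -> ClusterAssignment:
    """Stage 1 (western vs eastern Atlantic) always runs; stage 2 (Baltic vs
    non-Baltic eastern) runs iff P(eastern) >= ``stage2_threshold``."""
    for c in (WESTERN, EASTERN, BALTIC):
        if c not in panel.clusters:
            raise KeyError(f"panel lacks cluster {c!r}")
    stage1, n_info, uninformative = assign_stage(counts, panel, (WESTERN, EASTERN), err)
    stage2 = None
    if not uninformative and stage1[EASTERN] >= stage2_threshold:
        post2, _, flag2 = assign_stage(counts, panel, (BALTIC, EASTERN), err)
        if not flag2:
            stage2 = {BALTIC: post2[BALTIC], EASTERN_NONBALTIC: post2[EASTERN]}
    return ClusterAssignment(
        specimen_id=counts.specimen_id,
        stage1=stage1,
        stage2=stage2,
        n_informative_sites=n_info,
        uninformative=uninformative,
    )
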