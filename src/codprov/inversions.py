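"""Inversion genotype calling from diagnostic-site read counts.

Each of the four large inversions (LG1, LG2, LG7, LG12) is a biallelic
super-locus: a specimen carries 0, 1 or 2 copies of the inverted
arrangement. All diagnostic SNPs inside one inversion share that dosage
(recombination is suppressed inside the inversion), and each is oriented so
its alt allele tags the inverted arrangement.

For dosage d the expected alt-read fraction is

    q_d = (d/2) (1 - 2 err) + err

so homozygotes read the error rate off 0 or 1 and heterozygotes read 1/2
regardless of err. The likelihood is a product of per-site binomials in
q_d; the posterior uses a *uniform* prior over the three dosages so that
calling stays population-agnostic — population arrangement frequencies
enter only in the downstream affinity statistic, which avoids counting the
same frequency information twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .panel_io import INVERSION_NAMES, AlleleCountTable, InversionLocus, ReferencePanel

DOSAGES = (0, 1, 2)
DEFAULT_CALL_THRESHOLD = 0.75


@dataclass
class InversionCall:
    posterior: tuple[float, float, float]
    call: int | None  # dosage, or None when uncalled


@dataclass
class CompositeGenotype:
    """Per-inversion dosage posteriors and hard calls for one specimen."""

    specimen_id: str
    per_inversion: dict[str, InversionCall]

    @property
    def n_called(self) -> int:
        return sum(1 for c in self.per_inversion.values() if c.call is not None)

    def posteriors(self) -> list[tuple[float, float, float]]:
        return [c.posterior for c in self.per_inversion.values()]

    def calls(self) -> dict[str, int]:
        """Called loci only, as inversion name -> dosage."""
        return {n: c.call for n, c in self.per_inversion.items() if c.call is not None}


def inversion_genotype_posterior(
    counts: AlleleCountTable,
    locus: InversionLocus,
    err: float = 0.01,
) -> tuple[float, float, float]:
    """Posterior over dosage {0, 1, 2} at one inversion.

    Only counts at the locus's diagnostic sites may appear in ``counts``;
    zero total depth returns the uniform (1/3, 1/3, 1/3).
    """
    if not 0.0 <= err < 0.5:
        raise ValueError(f"err must be in [0, 0.5), got {err}")
    site_keys = locus.site_keys
    for site in counts.counts:
        if site.key not in site_keys:
            raise KeyError(
                f"site {site.linkage_group}:{site.position} is not a diagnostic "
                f"site of inversion {locus.name}"
            )
    depths = []
    alts = []
    for site, (ref_n, alt_n) in counts.counts.items():
        d = ref_n + alt_n
        if d > 0:
            depths.append(d)
            alts.append(alt_n)
    if not depths:
        return (1 / 3, 1 / 3, 1 / 3)
    depths_arr = np.array(depths)
    alts_arr = np.array(alts)
    loglik = np.empty(3)
    for d in DOSAGES:
        q = (d / 2.0) * (1.0 - 2.0 * err) + err
        loglik[d] = binom.logpmf(alts_arr, depths_arr, q).sum()
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    return tuple(post.tolist())


def call_genotype(
    posterior: tuple[float, float, float],
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> int | None:
    """Hard dosage call: argmax if its posterior strictly exceeds the
    threshold, else missing. Ties at the maximum also go missing."""
    m = max(posterior)
    if m <= threshold:
        return None
    top = [d for d in DOSAGES if posterior[d] == m]
    if len(top) > 1:
        return None
    return top[0]


def genotype_all_inversions(
    counts: AlleleCountTable,
    panel: ReferencePanel,
    err: float = 0.01,
    threshold: float = DEFAULT_CALL_THRESHOLD,
) -> CompositeGenotype:
    """Posterior and hard call at each inversion present in the panel.

    Loci with no diagnostic coverage get the uniform posterior and a
    missing call.
    """
    per_inversion: dict[str, InversionCall] = {}
    for name in INVERSION_NAMES:
        locus = panel.inversions.get(name)
        if locus is None:
            continue
        sub = counts.subset(locus.site_keys)
        post = inversion_genotype_posterior(sub, locus, err)
        per_inversion[name] = InversionCall(post, call_genotype(post, threshold))
    return CompositeGenotype(counts.specimen_id, per_inversion)
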