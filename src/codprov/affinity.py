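"""Composite-genotype affinity toward candidate modern populations.

A specimen's called inversion dosages form its composite genotype. Under
Hardy–Weinberg equilibrium, a population with inverted-arrangement
frequency f produces dosage d with probability C(2,d) f^d (1-f)^(2-d);
since the four inversions sit on different chromosomes the loci are
independent and the composite probability is the product over called loci.
That probability is the specimen's affinity toward the population; shares
are obtained by normalizing over the candidate set, so they are explicitly
conditional on which candidates are offered.

Reporting then merges ecotypes (e.g. the two Icelandic ecotypes into a
single Iceland share), aggregates eastern candidates into the northernmost
(Northeast Arctic + Iceland) and north-central (Norwegian Coast, North
Sea, Irish Sea, Øresund) haplogroups, and reports near-ties in the top
share as joint putative origins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .inversions import CompositeGenotype
from .panel_io import ReferencePanel

DEFAULT_TIE_TOLERANCE = 0.01


@dataclass
class AffinityResult:
    specimen_id: str
    raw: dict[str, float]
    normalized: dict[str, float]
    merged: dict[str, float]
    haplogroup: dict[str, float]
    putative_origin: list[str]
    loci_used: list[str]
    no_compatible_source: bool = False
    notes: list[str] = field(default_factory=list)


def hwe_genotype_probability(f: float, d: int) -> float:
    """P(dosage d | arrangement frequency f) under HWE: C(2,d) f^d (1-f)^(2-d)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency {f} outside [0, 1]")
    if d not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1 or 2, got {d}")
    if d == 0:
        return (1.0 - f) ** 2
    if d == 1:
        return 2.0 * f * (1.0 - f)
    return f * f


def composite_probability(
    genotype: CompositeGenotype | Mapping[str, int],
    population_freqs: Mapping[str, float],
) -> float:
    """Probability of the composite genotype under one population's
    arrangement frequencies: product over *called* loci (missing loci are
    marginalized out by skipping them).

    A zero probability is a legal output when a population is fixed (f = 0
    or 1) against a called dosage.
    """
    calls = genotype.calls() if isinstance(genotype, CompositeGenotype) else dict(genotype)
    if not calls:
        raise ValueError("no called loci; composite probability undefined")
    prob = 1.0
    for locus, dosage in calls.items():
        if locus not in population_freqs:
            raise KeyError(f"population lacks a frequency for locus {locus!r}")
        prob *= hwe_genotype_probability(population_freqs[locus], dosage)
    return prob


def normalize_affinities(
    raw: Mapping[str, float],
    candidates: Sequence[str],
) -> dict[str, float]:
    """Shares over the candidate set: raw_p / sum(raw). All-zero raw values
    mean no offered candidate can produce the genotype; the result is empty
    (callers flag "no compatible source")."""
    total = sum(raw[p] for p in candidates)
    if total == 0.0:
        return {}
    return {p: raw[p] / total for p in candidates}


def merge_ecotypes(
    shares: Mapping[str, float],
    merges: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Replace each merge's component populations by one summed label.

    Components must be disjoint across merges; total share is conserved.
    """
    seen: set[str] = set()
    for merged, members in merges.items():
        for pop in members:
            if pop in seen:
                raise ValueError(f"population {pop!r} appears in more than one merge")
            seen.add(pop)
    out: dict[str, float] = {}
    for pop, share in shares.items():
        if pop not in seen:
            out[pop] = share
    for merged, members in merges.items():
        present = [p for p in members if p in shares]
        if present:
            out[merged] = sum(shares[p] for p in present)
    return out


def aggregate_haplogroups(
    shares: Mapping[str, float],
    haplogroups: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Group shares, re-scaled over grouped populations only, so the group
    shares remain comparable when ungrouped candidates (e.g. western
    populations) carry part of the mass."""
    membership: dict[str, str] = {}
    for group, members in haplogroups.items():
        for pop in members:
            if pop in membership:
                raise ValueError(f"population {pop!r} assigned to two haplogroups")
            membership[pop] = group
    sums = {group: 0.0 for group in haplogroups}
    grouped_total = 0.0
    for pop, share in shares.items():
        group = membership.get(pop)
        if group is not None:
            sums[group] += share
            grouped_total += share
    if grouped_total == 0.0:
        return {}
    return {group: s / grouped_total for group, s in sums.items()}


def report_putative_origin(
    shares: Mapping[str, float],
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> list[str]:
    """The top-share population, plus every population whose share is within
    ``tie_tolerance`` of the top; ordered by share descending then label."""
    if not shares:
        return []
    top = max(shares.values())
    tied = [p for p, s in shares.items() if top - s <= tie_tolerance + 1e-15]
    return sorted(tied, key=lambda p: (-shares[p], p))


def compute_affinity(
    genotype: CompositeGenotype,
    panel: ReferencePanel,
    candidates: Sequence[str] | None = None,
    tie_tolerance: float = DEFAULT_TIE_TOLERANCE,
) -> AffinityResult:
    """Full affinity computation for one gated specimen.

    ``candidates`` defaults to the panel's whole candidate set; the pipeline
    conditions it on the genome-wide cluster assignment (eastern specimens
    are compared against eastern candidates only).
    """
    candidates = list(candidates if candidates is not None else panel.candidate_populations)
    if not candidates:
        raise ValueError("empty candidate set")
    calls = genotype.calls()
    raw: dict[str, float] = {}
    for pop in candidates:
        freqs = {
            name: locus.per_population_freq[pop]
            for name, locus in panel.inversions.items()
            if pop in locus.per_population_freq
        }
        usable = {k: v for k, v in calls.items() if k in freqs}
        raw[pop] = composite_probability(usable, freqs) if usable else 0.0
    normalized = normalize_affinities(raw, candidates)
    if not normalized:
        return AffinityResult(
            specimen_id=genotype.specimen_id,
            raw=raw,
            normalized={},
            merged={},
            haplogroup={},
            putative_origin=[],
            loci_used=sorted(calls),
            no_compatible_source=True,
            notes=["no compatible source among offered candidates"],
        )
    merged = merge_ecotypes(normalized, panel.ecotype_merges)
    haplogroup = aggregate_haplogroups(normalized, panel.haplogroups)
    return AffinityResult(
        specimen_id=genotype.specimen_id,
        raw=raw,
        normalized=normalized,
        merged=merged,
        haplogroup=haplogroup,
        putative_origin=report_putative_origin(merged, tie_tolerance),
        loci_used=sorted(calls),
    )


def shares_sum_to_one(shares: Mapping[str, float], tol: float = 1e-9) -> bool:
    return math.isclose(sum(shares.values()), 1.0, abs_tol=tol)
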