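"""Synthetic reference panels and ancient-specimen read counts with known
truth, so every pipeline stage can be exercised and its recovery measured
without any external data.

The generator emulates the study design end-to-end: three genome-wide
clusters (western Atlantic, eastern Atlantic, Baltic Sea) separated by
divergent allele frequencies at inversion-excluded SNPs; candidate modern
populations, each with its own inverted-arrangement frequency at the four
inversions (LG1, LG2, LG7, LG12); and low-coverage specimens whose
inversion dosages are drawn from HWE, whose per-site depth is Poisson, and
whose reads carry a per-read error plus an optional damage-like excess
error on a configurable fraction of sites (a deamination proxy — the
pipeline consumes counts, not reads, so positional C→T structure is out of
scope but the same failure mode is stressed).

Default population frequencies mirror the qualitative geography of the
system: northernmost populations (Northeast Arctic, the two Icelandic
ecotypes) carry the inverted arrangements at high frequency, north-central
populations (Norwegian Coast, North Sea, Irish Sea, Øresund) at low
frequency, with Iceland distinguished from the Northeast Arctic mainly at
LG1; western-Atlantic populations sit at intermediate frequencies. Exact
values are configurable.

All randomness flows from one integer seed through
``numpy.random.default_rng``; integer draws only, so cohorts are
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .affinity import AffinityResult
from .cluster import BALTIC, EASTERN, WESTERN, ClusterAssignment
from .inversions import CompositeGenotype
from .panel_io import (
    INVERSION_NAMES,
    AlleleCountTable,
    InversionLocus,
    ReferencePanel,
    SNPSite,
    SpecimenMeta,
)
from .qc import LibraryQC

# inverted-arrangement frequency per population, (LG1, LG2, LG7, LG12)
DEFAULT_INVERSION_FREQS: dict[str, tuple[float, float, float, float]] = {
    "Northeast Arctic": (0.90, 0.85, 0.80, 0.85),
    "Iceland coastal": (0.30, 0.80, 0.85, 0.80),
    "Iceland frontal": (0.45, 0.88, 0.80, 0.85),
    "Norwegian Coast Lofoten": (0.15, 0.20, 0.15, 0.20),
    "Norwegian Coast southwest": (0.12, 0.15, 0.18, 0.15),
    "North Sea": (0.05, 0.10, 0.12, 0.08),
    "Irish Sea": (0.08, 0.08, 0.10, 0.12),
    "Øresund": (0.10, 0.25, 0.20, 0.25),
    "Baltic Sea": (0.05, 0.30, 0.25, 0.35),
    "Placentia Bay": (0.70, 0.50, 0.45, 0.50),
    "Gulf of St Lawrence": (0.75, 0.55, 0.50, 0.45),
    "Southern Newfoundland": (0.35, 0.40, 0.35, 0.30),
}

DEFAULT_POPULATION_CLUSTERS: dict[str, str] = {
    "Northeast Arctic": EASTERN,
    "Iceland coastal": EASTERN,
    "Iceland frontal": EASTERN,
    "Norwegian Coast Lofoten": EASTERN,
    "Norwegian Coast southwest": EASTERN,
    "North Sea": EASTERN,
    "Irish Sea": EASTERN,
    "Øresund": EASTERN,
    "Baltic Sea": BALTIC,
    "Placentia Bay": WESTERN,
    "Gulf of St Lawrence": WESTERN,
    "Southern Newfoundland": WESTERN,
}

DEFAULT_ECOTYPE_MERGES = {"Iceland": ["Iceland coastal", "Iceland frontal"]}

DEFAULT_HAPLOGROUPS = {
    "northernmost": ["Northeast Arctic", "Iceland coastal", "Iceland frontal"],
    "north_central": [
        "Norwegian Coast Lofoten",
        "Norwegian Coast southwest",
        "North Sea",
        "Irish Sea",
        "Øresund",
    ],
}

_DATE_TEXTS = (
    "early eleventh century",
    "mid thirteenth century",
    "late fourteenth century",
    "late fifteenth–early sixteenth centuries",
    "seventeenth century",
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 3 clusters, 12 candidate populations (8 eastern, 1 Baltic,
    3 western), 50 genome-wide sites with cluster divergence 0.6, 5
    diagnostic sites per inversion, Poisson depth with mean 5 reads/site and
    1% per-read error — a low-coverage regime comparable to the data the
    pipeline targets.
    """

    inversion_freqs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INVERSION_FREQS)
    )
    population_clusters: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_CLUSTERS)
    )
    ecotype_merges: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ECOTYPE_MERGES.items()}
    )
    haplogroups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_HAPLOGROUPS.items()}
    )
    cluster_divergence: float = 0.6     # |Δf| at each diagnostic genome-wide site
    n_genomewide_sites: int = 50
    n_diagnostic_sites_per_inversion: int = 5
    depth_lambda: float = 5.0           # mean reads per site
    err: float = 0.01                   # per-read error
    damage_excess: float = 0.0          # extra error on damaged site class
    damage_fraction: float = 0.1        # fraction of sites in the damaged class
    n_specimens: int = 200
    element_origin_association: float = 0.0  # 0 = independent, 1 = deterministic
    seed: int = 42

    def __post_init__(self) -> None:
        for pop, freqs in self.inversion_freqs.items():
            if len(freqs) != len(INVERSION_NAMES):
                raise ValueError(f"population {pop!r} needs {len(INVERSION_NAMES)} frequencies")
            if any(not 0.0 <= f <= 1.0 for f in freqs):
                raise ValueError(f"frequency outside [0,1] for {pop!r}")
            if pop not in self.population_clusters:
                raise ValueError(f"population {pop!r} has no cluster assignment")
        if self.depth_lambda < 0:
            raise ValueError("depth_lambda must be >= 0")
        if not 0.0 <= self.err < 0.5:
            raise ValueError("err must be in [0, 0.5)")
        if not 0.0 <= self.damage_fraction <= 1.0:
            raise ValueError("damage_fraction must be in [0, 1]")
        if not 0.0 <= self.cluster_divergence <= 0.8:
            raise ValueError("cluster_divergence must be in [0, 0.8]")

    @property
    def populations(self) -> list[str]:
        return list(self.inversion_freqs)


@dataclass
class SimTruthEntry:
    true_cluster: str
    true_population: str
    dosages: tuple[int, int, int, int]  # (LG1, LG2, LG7, LG12)

    def __post_init__(self) -> None:
        if any(d not in (0, 1, 2) for d in self.dosages):
            raise ValueError("dosages must be in {0, 1, 2}")


@dataclass
class SimTruth:
    entries: dict[str, SimTruthEntry] = field(default_factory=dict)

    def __getitem__(self, sid: str) -> SimTruthEntry:
        return self.entries[sid]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SimCohort:
    panel: ReferencePanel
    counts: list[AlleleCountTable]
    truth: SimTruth
    qc: list[LibraryQC]
    meta: list[SpecimenMeta]
    damaged_site_keys: frozenset[tuple[str, int]]


def _genomewide_sites(n: int) -> list[SNPSite]:
    # LG03 carries no large inversion; positions spaced arbitrarily
    return [SNPSite("LG03", 1000 * (i + 1), "A", "G") for i in range(n)]


def _diagnostic_sites(name: str, n: int) -> list[SNPSite]:
    lg = {"LG1": "LG01", "LG2": "LG02", "LG7": "LG07", "LG12": "LG12"}[name]
    return [SNPSite(lg, 500 * (i + 1), "A", "G") for i in range(n)]


def simulate_reference_panel(config: SimConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Build a panel honouring the configured divergence; deterministic given
    the config seed.

    Half the genome-wide sites separate western from eastern+Baltic, the
    other half separate Baltic from the Atlantic clusters, each by
    ``cluster_divergence`` on top of a low base frequency.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sites = _genomewide_sites(config.n_genomewide_sites)
    clusters: dict[str, dict[SNPSite, float]] = {WESTERN: {}, EASTERN: {}, BALTIC: {}}
    for i, site in enumerate(sites):
        base = float(rng.integers(5, 20)) / 100.0
        high = base + config.cluster_divergence
        if i % 2 == 0:  # west-vs-east diagnostic
            clusters[WESTERN][site] = base
            clusters[EASTERN][site] = high
            clusters[BALTIC][site] = high
        else:           # Baltic-vs-Atlantic diagnostic
            clusters[WESTERN][site] = base
            clusters[EASTERN][site] = base
            clusters[BALTIC][site] = high
    inversions = {
        name: InversionLocus(
            name,
            _diagnostic_sites(name, config.n_diagnostic_sites_per_inversion),
            {pop: float(config.inversion_freqs[pop][k]) for pop in config.inversion_freqs},
        )
        for k, name in enumerate(INVERSION_NAMES)
    }
    return ReferencePanel(
        clusters=clusters,
        inversions=inversions,
        candidate_populations=config.populations,
        population_clusters=dict(config.population_clusters),
        ecotype_merges={k: list(v) for k, v in config.ecotype_merges.items()},
        haplogroups={k: list(v) for k, v in config.haplogroups.items()},
    )


def _draw_damaged_sites(
    panel: ReferencePanel, config: SimConfig, rng: np.random.Generator
) -> frozenset[tuple[str, int]]:
    keys = sorted(panel.known_site_keys())
    n_damaged = int(round(config.damage_fraction * len(keys)))
    if n_damaged == 0 or config.damage_excess == 0.0:
        return frozenset()
    idx = rng.choice(len(keys), size=n_damaged, replace=False)
    return frozenset(keys[i] for i in idx)


def _read_counts_for_genotype(
    g: int, depth: int, err: float, rng: np.random.Generator
) -> tuple[int, int]:
    q = (g / 2.0) * (1.0 - 2.0 * err) + err
    alt = int(rng.binomial(depth, q))
    return depth - alt, alt


def simulate_specimen(
    population: str,
    panel: ReferencePanel,
    config: SimConfig,
    rng: np.random.Generator,
    specimen_id: str,
    damaged_sites: frozenset[tuple[str, int]] = frozenset(),
) -> tuple[AlleleCountTable, SimTruthEntry]:
    """Draw one specimen: HWE inversion dosages from the population's
    arrangement frequencies, genome-wide genotypes from its cluster's site
    frequencies, Poisson per-site depth, and per-read error (plus the damage
    excess on damaged sites)."""
    if population not in panel.candidate_populations:
        raise KeyError(f"population {population!r} not in panel")
    cluster = panel.population_clusters[population]
    counts: dict[SNPSite, tuple[int, int]] = {}

    for site, f in panel.clusters[cluster].items():
        g = int(rng.binomial(2, f))
        depth = int(rng.poisson(config.depth_lambda))
        if depth > 0:
            e = config.err + (config.damage_excess if site.key in damaged_sites else 0.0)
            counts[site] = _read_counts_for_genotype(g, depth, e, rng)

    dosages = []
    for name in INVERSION_NAMES:
        locus = panel.inversions[name]
        f = locus.per_population_freq[population]
        d = int(rng.binomial(2, f))
        dosages.append(d)
        for site in locus.diagnostic_sites:
            depth = int(rng.poisson(config.depth_lambda))
            if depth > 0:
                e = config.err + (config.damage_excess if site.key in damaged_sites else 0.0)
                counts[site] = _read_counts_for_genotype(d, depth, e, rng)

    table = AlleleCountTable(specimen_id, counts)
    truth = SimTruthEntry(cluster, population, tuple(dosages))
    return table, truth


def _simulate_qc(
    specimen_id: str, table: AlleleCountTable, rng: np.random.Generator
) -> LibraryQC:
    # comfortably above the gates; the QC module's own tests craft failures
    total = table.total_depth()
    return LibraryQC(
        specimen_id=specimen_id,
        aligned_reads=2500 + 25 * total + int(rng.integers(0, 5000)),
        endogenous_pct=float(rng.integers(100, 3000)) / 100.0,
        nuclear_coverage=float(rng.integers(5, 200)) / 1000.0,
    )


def _negative_controls(rng: np.random.Generator) -> list[LibraryQC]:
    return [
        LibraryQC(
            specimen_id=f"CTRL{i}",
            aligned_reads=int(rng.integers(50, 500)),
            endogenous_pct=float(rng.integers(1, 10)) / 1000.0,
            nuclear_coverage=float(rng.integers(1, 10)) / 100000.0,
            is_negative_control=True,
        )
        for i in range(2)
    ]


def simulate_cohort(config: SimConfig) -> SimCohort:
    """End-to-end reproducible fixture: panel, specimen counts, QC metrics,
    metadata and hidden truth.

    Specimens cycle round-robin through the candidate populations. Bone
    elements follow the true origin with configurable strength s:
    specimens from the near-catchment populations (North Sea, Irish Sea)
    are cranial with probability (1+s)/2, all others with (1-s)/2, so s=0
    is independence and s=1 a deterministic association.
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_reference_panel(config, rng)
    damaged = _draw_damaged_sites(panel, config, rng)
    local_set = {"North Sea", "Irish Sea"}

    counts: list[AlleleCountTable] = []
    truth = SimTruth()
    qc: list[LibraryQC] = []
    meta: list[SpecimenMeta] = []
    pops = config.populations
    for i in range(config.n_specimens):
        sid = f"SIM{i:04d}"
        pop = pops[i % len(pops)]
        table, entry = simulate_specimen(pop, panel, config, rng, sid, damaged)
        counts.append(table)
        truth.entries[sid] = entry
        qc.append(_simulate_qc(sid, table, rng))
        s = config.element_origin_association
        p_cranial = (1.0 + s) / 2.0 if pop in local_set else (1.0 - s) / 2.0
        element = "cranial" if rng.random() < p_cranial else "postcranial"
        meta.append(
            SpecimenMeta(
                specimen_id=sid,
                site_name="synthetic",
                bone_element=element,
                date_text=_DATE_TEXTS[i % len(_DATE_TEXTS)],
            )
        )
    qc.extend(_negative_controls(rng))
    return SimCohort(panel, counts, truth, qc, meta, damaged)


@dataclass
class RecoveryMetrics:
    """Per-stage recovery of the generator's hidden truth."""

    n_specimens: int
    cluster_accuracy: float
    genotype_accuracy: float            # among called loci
    high_confidence_call_fraction: float  # called loci with posterior > 0.95
    top_population_accuracy: float      # true (merged) population among putative origins
    haplogroup_accuracy: float          # argmax group == true group (eastern specimens)
    haplogroup_confident_rate: float    # true-group share > 0.75, fully-called eastern
    n_called_loci: int
    n_fully_called_eastern: int


def evaluate_recovery(
    truth: SimTruth,
    cluster_assignments: Mapping[str, ClusterAssignment],
    genotypes: Mapping[str, CompositeGenotype] | None = None,
    affinities: Mapping[str, AffinityResult] | None = None,
    panel: ReferencePanel | None = None,
    group_share_threshold: float = 0.75,
) -> RecoveryMetrics:
    """Confusion-style accuracies of pipeline outputs against the truth.

    Every output specimen id must exist in the truth; stages may cover
    subsets of specimens (gated-out specimens simply do not contribute to
    that stage's accuracy).
    """
    for mapping in (cluster_assignments, genotypes or {}, affinities or {}):
        unknown = set(mapping) - set(truth.entries)
        if unknown:
            raise KeyError(f"outputs for unknown specimens: {sorted(unknown)[:3]}")

    cluster_hits = sum(
        1 for sid, a in cluster_assignments.items()
        if a.assigned_cluster == truth[sid].true_cluster
    )
    cluster_acc = cluster_hits / len(cluster_assignments) if cluster_assignments else float("nan")

    geno_hits = geno_total = high_conf = 0
    if genotypes:
        for sid, cg in genotypes.items():
            true_d = dict(zip(INVERSION_NAMES, truth[sid].dosages))
            for name, call in cg.per_inversion.items():
                if call.call is None:
                    continue
                geno_total += 1
                if call.call == true_d[name]:
                    geno_hits += 1
                if max(call.posterior) > 0.95:
                    high_conf += 1
    geno_acc = geno_hits / geno_total if geno_total else float("nan")
    high_frac = high_conf / geno_total if geno_total else float("nan")

    top_hits = top_total = 0
    hg_hits = hg_total = 0
    hg_conf = hg_conf_total = 0
    if affinities:
        merge_of = {}
        group_of = {}
        if panel is not None:
            for merged, members in panel.ecotype_merges.items():
                for pop in members:
                    merge_of[pop] = merged
            for group, members in panel.haplogroups.items():
                for pop in members:
                    group_of[pop] = group
        for sid, aff in affinities.items():
            if aff.no_compatible_source:
                continue
            true_pop = truth[sid].true_population
            true_label = merge_of.get(true_pop, true_pop)
            if aff.putative_origin:
                top_total += 1
                if true_label in aff.putative_origin:
                    top_hits += 1
            true_group = group_of.get(true_pop)
            if true_group is not None and aff.haplogroup:
                hg_total += 1
                best = max(aff.haplogroup, key=aff.haplogroup.get)
                if best == true_group:
                    hg_hits += 1
                cg = genotypes.get(sid) if genotypes else None
                if cg is not None and cg.n_called == len(INVERSION_NAMES):
                    hg_conf_total += 1
                    if aff.haplogroup[true_group] > group_share_threshold:
                        hg_conf += 1
    return RecoveryMetrics(
        n_specimens=len(truth),
        cluster_accuracy=cluster_acc,
        genotype_accuracy=geno_acc,
        high_confidence_call_fraction=high_frac,
        top_population_accuracy=top_hits / top_total if top_total else float("nan"),
        haplogroup_accuracy=hg_hits / hg_total if hg_total else float("nan"),
        haplogroup_confident_rate=hg_conf / hg_conf_total if hg_conf_total else float("nan"),
        n_called_loci=geno_total,
        n_fully_called_eastern=hg_conf_total,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of the config with a different seed (all else identical)."""
    return replace(config, seed=int(seed))
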