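"""Reference-panel and specimen-data I/O.

The interchange formats are plain TSV plus a small YAML/JSON panel config:

* **Panel TSV** — columns ``population, linkage_group, position, ref, alt,
  alt_freq, class`` where ``class`` is ``genomewide`` (cluster-diagnostic
  sites, one row per cluster) or one of the four inversion loci (``LG1``,
  ``LG2``, ``LG7``, ``LG12``; one row per candidate population giving the
  inverted-arrangement frequency at each diagnostic site).
* **Panel config** (YAML or JSON) — ``candidate_populations``,
  ``population_clusters``, ``ecotype_merges``, ``haplogroups``.
* **Counts TSV** — columns ``specimen_id, linkage_group, position,
  ref_count, alt_count``.

Coordinates are 1-based and VCF-convention throughout. Only biallelic
sites are supported; strand is not tracked, so panel and counts must share
one reference orientation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

INVERSION_NAMES = ("LG1", "LG2", "LG7", "LG12")
CLUSTER_NAMES = ("western_atlantic", "eastern_atlantic", "baltic")

PANEL_COLUMNS = ["population", "linkage_group", "position", "ref", "alt", "alt_freq", "class"]
COUNT_COLUMNS = ["specimen_id", "linkage_group", "position", "ref_count", "alt_count"]

_NUCLEOTIDES = frozenset("ACGT")


class PanelValidationError(ValueError):
    """A panel or count table violates a structural invariant."""


@dataclass(frozen=True, order=True)
class SNPSite:
    """A biallelic SNP locus on the reference assembly (1-based position)."""

    linkage_group: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PanelValidationError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise PanelValidationError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.linkage_group}:{self.position}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _NUCLEOTIDES:
                raise PanelValidationError(
                    f"allele {allele!r} at {self.linkage_group}:{self.position} is not "
                    "a single nucleotide; multi-allelic or indel rows are rejected"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.linkage_group, self.position)


@dataclass
class InversionLocus:
    """One of the four large chromosomal inversions, treated as a biallelic
    super-locus with dosage 0/1/2 of the inverted arrangement.

    ``diagnostic_sites`` maps each diagnostic SNP to it; sites are oriented
    so the alt allele tags the inverted arrangement. ``per_population_freq``
    holds the inverted-arrangement frequency *f* for each candidate modern
    population.
    """

    name: str
    diagnostic_sites: list[SNPSite]
    per_population_freq: dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in INVERSION_NAMES:
            raise PanelValidationError(
                f"inversion name {self.name!r} not one of {INVERSION_NAMES}"
            )
        if not self.diagnostic_sites:
            raise PanelValidationError(f"inversion {self.name} has no diagnostic sites")
        for pop, f in self.per_population_freq.items():
            _check_freq(f, f"inversion {self.name}, population {pop}")

    @property
    def site_keys(self) -> frozenset[tuple[str, int]]:
        return frozenset(s.key for s in self.diagnostic_sites)


@dataclass
class ReferencePanel:
    """Modern reference panel: genome-wide cluster allele frequencies plus
    per-population inversion arrangement frequencies.

    ``clusters`` maps each of the three genome-wide clusters (western
    Atlantic, eastern Atlantic, Baltic Sea) to per-site alt-allele
    frequencies at inversion-excluded SNPs. ``candidate_populations`` is the
    ordered candidate set for specific assignment; ``population_clusters``
    records which cluster each candidate belongs to so the candidate set can
    be conditioned on the genome-wide assignment.
    """

    clusters: dict[str, dict[SNPSite, float]]
    inversions: dict[str, InversionLocus]
    candidate_populations: list[str]
    population_clusters: dict[str, str] = field(default_factory=dict)
    ecotype_merges: dict[str, list[str]] = field(default_factory=dict)
    haplogroups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.candidate_populations:
            raise PanelValidationError("candidate population set is empty")
        if len(set(self.candidate_populations)) != len(self.candidate_populations):
            raise PanelValidationError("duplicate candidate population labels")
        for cluster in self.clusters:
            if cluster not in CLUSTER_NAMES:
                raise PanelValidationError(f"unknown cluster label {cluster!r}")
        for cluster, freqs in self.clusters.items():
            for site, f in freqs.items():
                _check_freq(f, f"cluster {cluster}, site {site.linkage_group}:{site.position}")
        for name, locus in self.inversions.items():
            if name != locus.name:
                raise PanelValidationError(f"inversion keyed {name!r} but named {locus.name!r}")
        candidates = set(self.candidate_populations)
        for merged, members in self.ecotype_merges.items():
            for pop in members:
                if pop not in candidates:
                    raise PanelValidationError(
                        f"ecotype merge {merged!r} references unknown population {pop!r}"
                    )
        seen: set[str] = set()
        for group, members in self.haplogroups.items():
            for pop in members:
                if pop not in candidates:
                    raise PanelValidationError(
                        f"haplogroup {group!r} references unknown population {pop!r}"
                    )
                if pop in seen:
                    raise PanelValidationError(f"population {pop!r} in two haplogroups")
                seen.add(pop)
        for pop, cluster in self.population_clusters.items():
            if cluster not in CLUSTER_NAMES:
                raise PanelValidationError(
                    f"population {pop!r} mapped to unknown cluster {cluster!r}"
                )
        gw_keys = self.genomewide_site_keys()
        for locus in self.inversions.values():
            overlap = gw_keys & locus.site_keys
            if overlap:
                raise PanelValidationError(
                    f"genome-wide SNP set overlaps {locus.name} diagnostic sites: "
                    f"{sorted(overlap)[:3]}"
                )

    def genomewide_site_keys(self) -> frozenset[tuple[str, int]]:
        keys: set[tuple[str, int]] = set()
        for freqs in self.clusters.values():
            keys.update(site.key for site in freqs)
        return frozenset(keys)

    def known_site_keys(self) -> frozenset[tuple[str, int]]:
        keys = set(self.genomewide_site_keys())
        for locus in self.inversions.values():
            keys.update(locus.site_keys)
        return frozenset(keys)

    def populations_in_cluster(self, cluster: str) -> list[str]:
        """Candidate populations belonging to one genome-wide cluster,
        preserving candidate order. Unmapped populations are never returned."""
        return [
            p for p in self.candidate_populations
            if self.population_clusters.get(p) == cluster
        ]


@dataclass
class AlleleCountTable:
    """Per-site biallelic read counts for one specimen (pileup summary)."""

    specimen_id: str
    counts: dict[SNPSite, tuple[int, int]]

    def __post_init__(self) -> None:
        for site, (ref, alt) in self.counts.items():
            if ref < 0 or alt < 0:
                raise PanelValidationError(
                    f"negative count at {site.linkage_group}:{site.position} "
                    f"for {self.specimen_id}"
                )

    def total_depth(self) -> int:
        return sum(r + a for r, a in self.counts.values())

    def subset(self, keys: frozenset[tuple[str, int]]) -> "AlleleCountTable":
        return AlleleCountTable(
            self.specimen_id,
            {s: c for s, c in self.counts.items() if s.key in keys},
        )


@dataclass
class SpecimenMeta:
    """Archaeological metadata for one specimen.

    Cleithra count as postcranial elements.
    """

    specimen_id: str
    site_name: str = ""
    bone_element: str = ""
    date_text: str = ""
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.bone_element and self.bone_element not in ("cranial", "postcranial"):
            raise PanelValidationError(
                f"bone_element must be 'cranial' or 'postcranial', got "
                f"{self.bone_element!r}"
            )


def _check_freq(f: float, context: str) -> None:
    if not (0.0 <= f <= 1.0):
        raise PanelValidationError(f"frequency {f} outside [0, 1] ({context})")


# ---------------------------------------------------------------------------
# readers / writers


def read_reference_panel(path: str | Path, config_path: str | Path | None = None) -> ReferencePanel:
    """Read a reference panel from TSV plus its YAML/JSON config.

    When ``config_path`` is omitted, looks for ``<path stem>.config.yaml``
    next to the panel TSV.
    """
    path = Path(path)
    if config_path is None:
        config_path = path.with_suffix("").with_suffix(".config.yaml")
        if not Path(config_path).exists():
            raise FileNotFoundError(
                f"panel config not found next to {path}; pass config_path explicitly"
            )
    cfg = _read_config(Path(config_path))

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"linkage_group": str, "population": str},
            float_precision="round_trip",  # lossless write->read for frequencies
        )
    except Exception as exc:  # malformed TSV
        raise PanelValidationError(f"cannot parse panel TSV {path}: {exc}") from exc
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelValidationError(f"panel TSV missing columns: {sorted(missing)}")
    df = df.rename(columns={"class": "site_class"})  # 'class' is a keyword

    clusters: dict[str, dict[SNPSite, float]] = {}
    inv_sites: dict[str, dict[SNPSite, None]] = {n: {} for n in INVERSION_NAMES}
    inv_freqs: dict[str, dict[str, float]] = {n: {} for n in INVERSION_NAMES}

    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            site = SNPSite(str(row.linkage_group), int(row.position), str(row.ref), str(row.alt))
            f = float(row.alt_freq)
        except (TypeError, ValueError) as exc:
            raise PanelValidationError(f"{path} line {idx}: malformed row ({exc})") from exc
        _check_freq(f, f"{path} line {idx}")
        klass = str(row.site_class)
        pop = str(row.population)
        if klass == "genomewide":
            per_site = clusters.setdefault(pop, {})
            if site in per_site:
                raise PanelValidationError(
                    f"{path} line {idx}: duplicate genome-wide site "
                    f"{site.linkage_group}:{site.position} for cluster {pop}"
                )
            per_site[site] = f
        elif klass in INVERSION_NAMES:
            inv_sites[klass].setdefault(site)
            if pop in inv_freqs[klass] and inv_freqs[klass][pop] != f:
                raise PanelValidationError(
                    f"{path} line {idx}: population {pop} has conflicting "
                    f"frequencies for {klass}"
                )
            inv_freqs[klass][pop] = f
        else:
            raise PanelValidationError(
                f"{path} line {idx}: unknown class {klass!r} "
                f"(expected genomewide or one of {INVERSION_NAMES})"
            )

    inversions = {
        name: InversionLocus(name, list(inv_sites[name]), inv_freqs[name])
        for name in INVERSION_NAMES
        if inv_sites[name]
    }
    return ReferencePanel(
        clusters=clusters,
        inversions=inversions,
        candidate_populations=list(cfg["candidate_populations"]),
        population_clusters=dict(cfg.get("population_clusters", {})),
        ecotype_merges={k: list(v) for k, v in cfg.get("ecotype_merges", {}).items()},
        haplogroups={k: list(v) for k, v in cfg.get("haplogroups", {}).items()},
    )


def write_reference_panel(
    panel: ReferencePanel, path: str | Path, config_path: str | Path | None = None
) -> None:
    """Write a panel losslessly: TSV with deterministic row/column order plus
    the YAML config. Frequencies use ``repr`` round-trip precision."""
    path = Path(path)
    if config_path is None:
        config_path = path.with_suffix("").with_suffix(".config.yaml")
    rows: list[dict] = []
    for cluster in sorted(panel.clusters):
        for site in sorted(panel.clusters[cluster]):
            rows.append(_panel_row(cluster, site, panel.clusters[cluster][site], "genomewide"))
    for name in INVERSION_NAMES:
        locus = panel.inversions.get(name)
        if locus is None:
            continue
        for pop in sorted(locus.per_population_freq):
            f = locus.per_population_freq[pop]
            for site in sorted(locus.diagnostic_sites):
                rows.append(_panel_row(pop, site, f, name))
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=None)
    cfg = {
        "candidate_populations": list(panel.candidate_populations),
        "population_clusters": dict(panel.population_clusters),
        "ecotype_merges": {k: list(v) for k, v in panel.ecotype_merges.items()},
        "haplogroups": {k: list(v) for k, v in panel.haplogroups.items()},
    }
    Path(config_path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _panel_row(pop: str, site: SNPSite, f: float, klass: str) -> dict:
    return {
        "population": pop,
        "linkage_group": site.linkage_group,
        "position": site.position,
        "ref": site.ref_allele,
        "alt": site.alt_allele,
        "alt_freq": repr(float(f)),
        "class": klass,
    }


def read_allele_counts(path: str | Path, panel: ReferencePanel) -> list[AlleleCountTable]:
    """Read specimen allele counts, cross-referencing sites against the panel.

    Counts at sites unknown to the panel are skipped with a warning; negative
    counts abort with an error. Returns one table per specimen, in order of
    first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"linkage_group": str, "specimen_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise PanelValidationError(f"counts TSV missing columns: {sorted(missing)}")
    known = panel.known_site_keys()
    site_lookup = _panel_site_lookup(panel)

    tables: dict[str, dict[SNPSite, tuple[int, int]]] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        ref_n, alt_n = int(row.ref_count), int(row.alt_count)
        if ref_n < 0 or alt_n < 0:
            raise PanelValidationError(f"{path} line {idx}: negative count")
        key = (str(row.linkage_group), int(row.position))
        if key not in known:
            msg = f"{path} line {idx}: site {key[0]}:{key[1]} absent from panel; skipped"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        site = site_lookup[key]
        tables.setdefault(str(row.specimen_id), {})[site] = (ref_n, alt_n)
    return [AlleleCountTable(sid, counts) for sid, counts in tables.items()]


def write_allele_counts(tables: Sequence[AlleleCountTable], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": t.specimen_id,
            "linkage_group": s.linkage_group,
            "position": s.position,
            "ref_count": r,
            "alt_count": a,
        }
        for t in tables
        for s, (r, a) in sorted(t.counts.items())
    ]
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_specimen_meta(path: str | Path) -> list[SpecimenMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SpecimenMeta(
                specimen_id=d["specimen_id"],
                site_name=d.get("site_name", ""),
                bone_element=d.get("bone_element", ""),
                date_text=d.get("date_text", ""),
                is_negative_control=str(d.get("is_negative_control", "")).lower()
                in ("1", "true", "yes"),
            )
        )
    return out


def write_specimen_meta(meta: Sequence[SpecimenMeta], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": m.specimen_id,
            "site_name": m.site_name,
            "bone_element": m.bone_element,
            "date_text": m.date_text,
            "is_negative_control": str(m.is_negative_control).lower(),
        }
        for m in meta
    ]
    pd.DataFrame(
        rows,
        columns=["specimen_id", "site_name", "bone_element", "date_text", "is_negative_control"],
    ).to_csv(path, sep="\t", index=False)


def _panel_site_lookup(panel: ReferencePanel) -> dict[tuple[str, int], SNPSite]:
    lookup: dict[tuple[str, int], SNPSite] = {}
    for freqs in panel.clusters.values():
        for site in freqs:
            lookup[site.key] = site
    for locus in panel.inversions.values():
        for site in locus.diagnostic_sites:
            lookup[site.key] = site
    return lookup


def _read_config(path: Path) -> Mapping:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def panels_equal(a: ReferencePanel, b: ReferencePanel, tol: float = 0.0) -> bool:
    """Structural equality of two panels, with optional frequency tolerance."""
    if a.candidate_populations != b.candidate_populations:
        return False
    if a.population_clusters != b.population_clusters:
        return False
    if a.ecotype_merges != b.ecotype_merges or a.haplogroups != b.haplogroups:
        return False
    if set(a.clusters) != set(b.clusters) or set(a.inversions) != set(b.inversions):
        return False
    for cluster in a.clusters:
        fa, fb = a.clusters[cluster], b.clusters[cluster]
        if set(fa) != set(fb):
            return False
        if any(abs(fa[s] - fb[s]) > tol for s in fa):
            return False
    for name in a.inversions:
        la, lb = a.inversions[name], b.inversions[name]
        if set(la.diagnostic_sites) != set(lb.diagnostic_sites):
            return False
        if set(la.per_population_freq) != set(lb.per_population_freq):
            return False
        if any(
            abs(la.per_population_freq[p] - lb.per_population_freq[p]) > tol
            for p in la.per_population_freq
        ):
            return False
    return True
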