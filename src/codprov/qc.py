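"""Library-level QC gates for ancient specimens.

Inclusion for specific genomic assignment requires, relative to the
negative controls of the library sessions:

* more than 2000 aligned reads (strict),
* nuclear coverage at least one order of magnitude (10x) above the
  control baseline,
* endogenous DNA content at least 10x above the control baseline,

and, downstream, confident genotype calls (posterior > 0.75) at three or
more of the four inversions. The baseline is the maximum over the supplied
negative controls — the conservative aggregation. A zero-valued baseline is
treated as an absent contamination floor: any strictly positive specimen
value passes that ratio gate.

All thresholds are exposed as :class:`QCThresholds` fields with these
values as defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class QCThresholds:
    min_aligned_reads: int = 2000       # strict: reads must exceed this
    ratio_over_baseline: float = 10.0   # "one magnitude more"
    call_posterior: float = 0.75        # strict: posterior must exceed this
    min_called_loci: int = 3


@dataclass
class LibraryQC:
    """Per-library sequencing metrics for a specimen or negative control."""

    specimen_id: str
    aligned_reads: int
    endogenous_pct: float
    nuclear_coverage: float
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.aligned_reads < 0 or self.endogenous_pct < 0 or self.nuclear_coverage < 0:
            raise ValueError(f"negative QC metric for {self.specimen_id}")


@dataclass
class QCDecision:
    specimen_id: str
    passes_read_count: bool
    passes_coverage_ratio: bool
    passes_endogenous_ratio: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def eligible_for_specific_assignment(self) -> bool:
        return self.passes_read_count and self.passes_coverage_ratio and self.passes_endogenous_ratio


def _ratio_pass(value: float, baseline: float, ratio: float) -> bool:
    if baseline == 0.0:
        return value > 0.0
    return value >= ratio * baseline


def evaluate_baseline(
    specimen: LibraryQC,
    controls: Sequence[LibraryQC],
    thresholds: QCThresholds | None = None,
) -> QCDecision:
    """Gate one specimen against the negative-control baseline.

    The baseline for each ratio gate is the maximum of that metric over the
    controls; the read-count gate is absolute and strict (> 2000 by default).
    """
    thresholds = thresholds or QCThresholds()
    if not controls:
        raise ValueError("control list is empty")
    if any(not c.is_negative_control for c in controls):
        raise ValueError("all baseline libraries must be flagged as negative controls")

    base_cov = max(c.nuclear_coverage for c in controls)
    base_endo = max(c.endogenous_pct for c in controls)

    passes_reads = specimen.aligned_reads > thresholds.min_aligned_reads
    passes_cov = _ratio_pass(specimen.nuclear_coverage, base_cov, thresholds.ratio_over_baseline)
    passes_endo = _ratio_pass(specimen.endogenous_pct, base_endo, thresholds.ratio_over_baseline)

    reasons = []
    if not passes_reads:
        reasons.append(
            f"aligned reads {specimen.aligned_reads} not greater than "
            f"{thresholds.min_aligned_reads}"
        )
    if not passes_cov:
        reasons.append(
            f"nuclear coverage {specimen.nuclear_coverage:g} below "
            f"{thresholds.ratio_over_baseline:g}x control baseline {base_cov:g}"
        )
    if not passes_endo:
        reasons.append(
            f"endogenous {specimen.endogenous_pct:g}% below "
            f"{thresholds.ratio_over_baseline:g}x control baseline {base_endo:g}%"
        )
    return QCDecision(specimen.specimen_id, passes_reads, passes_cov, passes_endo, reasons)


def gate_specific_assignment(
    posteriors: Iterable[Sequence[float]],
    thresholds: QCThresholds | None = None,
) -> bool:
    """True iff at least ``min_called_loci`` inversions have a maximum
    genotype posterior strictly greater than ``call_posterior``.

    ``posteriors`` holds the available per-inversion 3-vectors; missing loci
    are simply absent and count as uncalled.
    """
    thresholds = thresholds or QCThresholds()
    confident = sum(1 for p in posteriors if p and max(p) > thresholds.call_posterior)
    return confident >= thresholds.min_called_loci


def read_library_qc(path: str | Path) -> list[LibraryQC]:
    """Read QC TSV: specimen_id, aligned_reads, endogenous_pct,
    nuclear_coverage, is_control."""
    df = pd.read_csv(path, sep="\t", dtype={"specimen_id": str})
    return [
        LibraryQC(
            specimen_id=str(r.specimen_id),
            aligned_reads=int(r.aligned_reads),
            endogenous_pct=float(r.endogenous_pct),
            nuclear_coverage=float(r.nuclear_coverage),
            is_negative_control=bool(r.is_control),
        )
        for r in df.itertuples(index=False)
    ]


def write_library_qc(records: Sequence[LibraryQC], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "aligned_reads": r.aligned_reads,
                "endogenous_pct": r.endogenous_pct,
                "nuclear_coverage": r.nuclear_coverage,
                "is_control": r.is_negative_control,
            }
            for r in records
        ],
        columns=["specimen_id", "aligned_reads", "endogenous_pct", "nuclear_coverage", "is_control"],
    ).to_csv(path, sep="\t", index=False)
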