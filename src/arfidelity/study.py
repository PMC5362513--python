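"""End-to-end analysis of the packaged study tables.

Convenience layer tying the modules together on the packaged fixtures: the
deep-sequencing count table (11 mCRPC patients + 2 healthy donors, 5 AR
hotspot loci) and the ddPCR droplet tables (F877L, T878A and W742C assays
after Phusion or SuperFi preamplification, plus the wild-type-genomic-DNA
cycle-number comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ddpcr_quant import DropletData, default_droplet_table_path, read_droplet_table
from .fidelity_analysis import (
    ConcordanceResult,
    FidelityReport,
    LocusComparison,
    classify_concordance,
    compare_locus_rates,
    fidelity_report,
)
from .ngs_caller import (
    FilterConfig,
    VariantCall,
    call_variants,
    default_count_table_path,
    read_count_table,
)
from .amplification_simulator import load_polymerases

__all__ = [
    "PATIENT_SAMPLES",
    "CONTROL_SAMPLES",
    "HEALTHY_CONTROL_EQUIVALENTS",
    "load_ddpcr_tables",
    "run_study_analysis",
    "StudyAnalysis",
]

PATIENT_SAMPLES = tuple(f"JHU Pt {i}" for i in range(1, 12))
CONTROL_SAMPLES = ("Male Control", "Female Control")

#: Healthy-donor NGS controls carry no ddPCR assay of their own; their
#: cross-platform stand-in is the preamplified wild-type genomic DNA control.
HEALTHY_CONTROL_EQUIVALENTS = {
    "Male Control": "Wild-type Genomic DNA",
    "Female Control": "Wild-type Genomic DNA",
}

#: Samples assayed for both F877L and T878A under Phusion (the paired
#: locus-rate comparison).
SHARED_PHUSION_SAMPLES = (
    "JHU Pt 1",
    "JHU Pt 3",
    "JHU Pt 4",
    "JHU Pt 7",
    "JHU Pt 8",
    "JHU Pt 10",
    "JHU Pt 11",
)


def load_ddpcr_tables() -> dict[str, list[DropletData]]:
    """Load the packaged droplet tables keyed by table label (T4–T7)."""
    df = pd.read_csv(default_droplet_table_path(), sep="\t")
    return {
        label: read_droplet_table(group.drop(columns=["table"]))
        for label, group in df.groupby("table", sort=True)
    }


@dataclass(frozen=True)
class StudyAnalysis:
    calls: tuple[VariantCall, ...]
    ddpcr_tables: Mapping[str, Sequence[DropletData]]
    concordance: ConcordanceResult
    locus_comparison: LocusComparison
    report: FidelityReport

    @property
    def called(self) -> tuple[VariantCall, ...]:
        return tuple(c for c in self.calls if c.called)


def _paired_phusion_afs(tables: Mapping[str, Sequence[DropletData]]) -> tuple[list, list]:
    def af_for(table: str, sample: str) -> float:
        for d in tables[table]:
            if d.sample_id == sample and d.polymerase == "Phusion" and d.preamplified:
                from .ddpcr_quant import raw_allelic_fraction

                return raw_allelic_fraction(d)
        raise KeyError((table, sample))

    f877l = [af_for("T4", s) for s in SHARED_PHUSION_SAMPLES]
    t878a = [af_for("T5", s) for s in SHARED_PHUSION_SAMPLES]
    return f877l, t878a


def run_study_analysis(filter_config: FilterConfig | None = None) -> StudyAnalysis:
    """Run the full cross-platform analysis on the packaged tables.

    Applies the filter cascade to the deep-sequencing counts, classifies
    every called candidate against the ddPCR assays (Tables labelled
    T4/T5/T7; the T6 cycle-number rows duplicate the 22-cycle controls and
    are excluded from classification), runs the paired F877L-vs-T878A
    locus-rate comparison, and assembles the fidelity report.
    """
    records = read_count_table(default_count_table_path())
    calls = call_variants(records, filter_config or FilterConfig())
    tables = load_ddpcr_tables()
    assay_data = [d for label in ("T4", "T5", "T7") for d in tables[label]]
    concordance = classify_concordance(
        calls, assay_data, control_equivalents=HEALTHY_CONTROL_EQUIVALENTS
    )
    f877l, t878a = _paired_phusion_afs(tables)
    comparison = compare_locus_rates(f877l, t878a)
    report = fidelity_report(
        calls,
        assay_data,
        polymerases=load_polymerases(),
        patient_samples=PATIENT_SAMPLES,
        control_samples=CONTROL_SAMPLES,
        control_equivalents=HEALTHY_CONTROL_EQUIVALENTS,
    )
    return StudyAnalysis(
        calls=tuple(calls),
        ddpcr_tables=tables,
        concordance=concordance,
        locus_comparison=comparison,
        report=report,
    )
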