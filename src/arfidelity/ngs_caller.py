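"""Deep-sequencing variant-filter cascade for hotspot allele-count tables.

Operates on per-sample, per-locus stranded allele counts (the ingestion
boundary is a count table, not raw reads) and applies, in this order of
reporting:

* ``MIN_ALT``      — fewer than 15 supporting reads
* ``STRAND``       — support on only one sequencing strand
* ``LOW_AF``       — allelic fraction <= 0.15 %
* ``NEXT_ALLELE``  — alt frequency below twice the next-highest
  non-reference allele frequency at the site
* ``HIGH_AF``      — allelic fraction > 50 %
* ``COHORT``       — provisionally called in more than 50 % of cohort
  samples (applied last, over provisional calls)

All filters except ``COHORT`` are conjunctive and order-independent.  The
allelic-fraction convention is ``100 * alt / ref`` (mutant reads over
wild-type reads); ``100 * alt / (alt + ref)`` is available via
``convention="alt_over_total"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .locus_model import LocusSpec, load_loci

__all__ = [
    "AlleleCountRecord",
    "FilterConfig",
    "VariantCall",
    "read_count_table",
    "apply_read_quality_gate",
    "allelic_fraction_percent",
    "round_half_up",
    "call_variants",
    "write_calls",
    "read_calls",
    "CountTableError",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = [
    "sample_id",
    "locus_id",
    "allele",
    "fwd_count",
    "rev_count",
    "mean_base_quality",
    "mean_mapq",
]

READ_COLUMNS = ["sample_id", "locus_id", "read_id", "allele", "strand", "base_quality", "mapq"]


class CountTableError(ValueError):
    """Raised for malformed count tables (missing columns, negative counts,
    duplicate rows, unknown loci)."""


@dataclass(frozen=True)
class AlleleCountRecord:
    """Stranded read counts for one allele at one locus in one sample."""

    sample_id: str
    locus_id: str
    allele: str
    fwd_count: int
    rev_count: int
    mean_base_quality: float = float("nan")
    mean_mapq: float = float("nan")

    def __post_init__(self) -> None:
        if self.fwd_count < 0 or self.rev_count < 0:
            raise CountTableError(
                f"negative count for {self.sample_id}/{self.locus_id}/{self.allele}"
            )

    @property
    def total(self) -> int:
        return self.fwd_count + self.rev_count


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    Boundary semantics: base quality >= ``min_base_quality`` inclusive,
    mapping quality strictly > ``min_mapq_exclusive``, alt reads >=
    ``min_alt_reads`` inclusive, AF strictly > ``min_af_exclusive_percent``
    required (equal is excluded), AF <= ``max_af_percent`` required.
    """

    min_base_quality: float = 25.0
    min_mapq_exclusive: float = 18.0
    min_alt_reads: int = 15
    min_af_exclusive_percent: float = 0.15
    require_both_strands: bool = True
    next_allele_ratio: float = 2.0
    max_cohort_prevalence: float = 0.5  # strict: fail only when exceeded
    max_af_percent: float = 50.0
    af_convention: str = "alt_over_ref"

    def validate(self) -> None:
        if self.min_alt_reads < 0 or self.next_allele_ratio < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.max_cohort_prevalence <= 1:
            raise ValueError("max_cohort_prevalence must be in [0, 1]")
        if self.min_af_exclusive_percent >= self.max_af_percent:
            raise ValueError("min_af_exclusive_percent must be below max_af_percent")
        if self.af_convention not in ("alt_over_ref", "alt_over_total"):
            raise ValueError(f"unknown AF convention {self.af_convention!r}")


@dataclass(frozen=True)
class VariantCall:
    """A candidate variant with its filter outcome.

    ``status`` is ``"CALLED"`` exactly when ``failure_reasons`` is empty;
    the allelic fraction is recomputable from the stored counts.
    """

    sample_id: str
    locus_id: str
    alt_allele: str
    alt_count: int
    ref_count: int
    alt_fwd: int
    alt_rev: int
    allelic_fraction_percent: float
    failure_reasons: frozenset[str] = frozenset()
    saturated: bool = False

    @property
    def status(self) -> str:
        return "CALLED" if not self.failure_reasons else "FILTERED"

    @property
    def called(self) -> bool:
        return not self.failure_reasons


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def allelic_fraction_percent(
    alt_count: int, ref_count: int, convention: str = "alt_over_ref"
) -> float:
    """Allelic fraction in percent.

    Default convention is mutant reads over wild-type reads
    (``100 * alt / ref``), the convention of the packaged count tables;
    ``alt_over_total`` gives ``100 * alt / (alt + ref)``.  A site with
    ``ref_count == 0`` and ``alt_count > 0`` saturates at 100 %; both zero is
    undefined and raises ``ValueError``.
    """
    if alt_count < 0 or ref_count < 0:
        raise ValueError("counts must be non-negative")
    if ref_count == 0:
        if alt_count == 0:
            raise ValueError("allelic fraction undefined: no reads")
        return 100.0
    if convention == "alt_over_ref":
        return 100.0 * alt_count / ref_count
    if convention == "alt_over_total":
        return 100.0 * alt_count / (alt_count + ref_count)
    raise ValueError(f"unknown AF convention {convention!r}")


def _known_loci(loci: Iterable[LocusSpec] | None) -> dict[str, LocusSpec]:
    loci = list(loci) if loci is not None else load_loci()
    return {l.locus_id: l for l in loci}


def read_count_table(
    path: str | Path, loci: Iterable[LocusSpec] | None = None
) -> list[AlleleCountRecord]:
    """Read a delimited allele-count table into validated records.

    Rejects missing columns, negative counts, duplicate
    (sample, locus, allele) rows and unknown loci, naming the offending row
    (1-based, excluding the header).  An empty file yields an empty list
    with a logged warning.
    """
    by_id = _known_loci(loci)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str, "allele": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("count table %s is empty", path)
        return []
    records: list[AlleleCountRecord] = []
    seen: dict[tuple[str, str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.locus_id not in by_id:
            raise CountTableError(f"{path}: row {i}: unknown locus {row.locus_id!r}")
        if row.fwd_count < 0 or row.rev_count < 0:
            raise CountTableError(f"{path}: row {i}: negative count")
        key = (row.sample_id, row.locus_id, row.allele)
        if key in seen:
            raise CountTableError(
                f"{path}: row {i}: duplicate of row {seen[key]} for {key}"
            )
        seen[key] = i
        records.append(
            AlleleCountRecord(
                sample_id=row.sample_id,
                locus_id=row.locus_id,
                allele=row.allele,
                fwd_count=int(row.fwd_count),
                rev_count=int(row.rev_count),
                mean_base_quality=float(row.mean_base_quality),
                mean_mapq=float(row.mean_mapq),
            )
        )
    return records


def apply_read_quality_gate(
    reads: pd.DataFrame | str | Path, config: FilterConfig | None = None
) -> list[AlleleCountRecord]:
    """Gate individual reads by quality, then aggregate to stranded counts.

    A read is retained when base quality >= 25 and mapping quality > 18
    (both thresholds from ``config``).  Input is a per-read table with
    columns ``sample_id, locus_id, read_id, allele, strand ('+'/'-'),
    base_quality, mapq``.
    """
    config = config or FilterConfig()
    if not isinstance(reads, pd.DataFrame):
        reads = pd.read_csv(reads, sep="\t")
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise CountTableError(f"per-read table missing columns {missing}")
    kept = reads[
        (reads["base_quality"] >= config.min_base_quality)
        & (reads["mapq"] > config.min_mapq_exclusive)
    ]
    records = []
    for (sample, locus, allele), grp in kept.groupby(
        ["sample_id", "locus_id", "allele"], sort=True
    ):
        fwd = int((grp["strand"] == "+").sum())
        records.append(
            AlleleCountRecord(
                sample_id=sample,
                locus_id=locus,
                allele=allele,
                fwd_count=fwd,
                rev_count=len(grp) - fwd,
                mean_base_quality=float(grp["base_quality"].mean()),
                mean_mapq=float(grp["mapq"].mean()),
            )
        )
    return records


def call_variants(
    records: Sequence[AlleleCountRecord],
    config: FilterConfig | None = None,
    loci: Iterable[LocusSpec] | None = None,
    cohort_samples: Sequence[str] | None = None,
) -> list[VariantCall]:
    """Apply the filter cascade to a cohort of allele-count records.

    Every non-reference allele with at least one read becomes a candidate
    and receives the full set of applicable failure reasons.  The cohort-
    prevalence filter runs last: a (locus, alt) combination provisionally
    called in strictly more than half of ``cohort_samples`` (default: every
    sample present in ``records``) has all its provisional calls failed with
    ``COHORT``.
    """
    config = config or FilterConfig()
    config.validate()
    by_id = _known_loci(loci)

    per_site: dict[tuple[str, str], dict[str, AlleleCountRecord]] = {}
    for rec in records:
        if rec.locus_id not in by_id:
            raise CountTableError(f"unknown locus {rec.locus_id!r}")
        site = per_site.setdefault((rec.sample_id, rec.locus_id), {})
        if rec.allele in site:
            raise CountTableError(
                f"duplicate allele record {rec.sample_id}/{rec.locus_id}/{rec.allele}"
            )
        site[rec.allele] = rec

    samples = list(dict.fromkeys(cohort_samples or [r.sample_id for r in records]))
    n_cohort = len(samples)

    calls: list[VariantCall] = []
    for (sample, locus_id), site in sorted(per_site.items()):
        ref_base = by_id[locus_id].ref_base
        ref_rec = site.get(ref_base)
        if ref_rec is None:
            raise CountTableError(f"no reference record for {sample}/{locus_id}")
        ref_count = ref_rec.total
        alt_recs = {a: r for a, r in site.items() if a != ref_base and r.total > 0}
        for allele, rec in sorted(alt_recs.items()):
            reasons = set()
            if rec.total < config.min_alt_reads:
                reasons.add("MIN_ALT")
            if config.require_both_strands and (rec.fwd_count == 0 or rec.rev_count == 0):
                reasons.add("STRAND")
            saturated = ref_count == 0
            af = allelic_fraction_percent(rec.total, ref_count, config.af_convention)
            if af <= config.min_af_exclusive_percent:
                reasons.add("LOW_AF")
            if af > config.max_af_percent:
                reasons.add("HIGH_AF")
            others = [r.total for a, r in alt_recs.items() if a != allele]
            if others and rec.total < config.next_allele_ratio * max(others):
                reasons.add("NEXT_ALLELE")
            calls.append(
                VariantCall(
                    sample_id=sample,
                    locus_id=locus_id,
                    alt_allele=allele,
                    alt_count=rec.total,
                    ref_count=ref_count,
                    alt_fwd=rec.fwd_count,
                    alt_rev=rec.rev_count,
                    allelic_fraction_percent=af,
                    failure_reasons=frozenset(reasons),
                    saturated=saturated,
                )
            )

    # cohort-prevalence filter, applied last over provisional calls
    provisional: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        if c.called:
            provisional.setdefault((c.locus_id, c.alt_allele), set()).add(c.sample_id)
    too_common = {
        key
        for key, carriers in provisional.items()
        if n_cohort > 0 and len(carriers) / n_cohort > config.max_cohort_prevalence
    }
    if too_common:
        calls = [
            replace(c, failure_reasons=c.failure_reasons | {"COHORT"})
            if c.called and (c.locus_id, c.alt_allele) in too_common
            else c
            for c in calls
        ]
    return calls


_CALL_COLUMNS = [
    "sample_id",
    "locus_id",
    "alt_allele",
    "alt_count",
    "ref_count",
    "alt_fwd",
    "alt_rev",
    "allelic_fraction_percent",
    "status",
    "failure_reasons",
]


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "locus_id": c.locus_id,
                "alt_allele": c.alt_allele,
                "alt_count": c.alt_count,
                "ref_count": c.ref_count,
                "alt_fwd": c.alt_fwd,
                "alt_rev": c.alt_rev,
                "allelic_fraction_percent": repr(c.allelic_fraction_percent),
                "status": c.status,
                "failure_reasons": ",".join(sorted(c.failure_reasons)) or ".",
            }
            for c in calls
        ],
        columns=_CALL_COLUMNS,
    )


def write_calls(
    calls: Sequence[VariantCall],
    path: str | Path,
    format: str = "tsv",
    loci: Iterable[LocusSpec] | None = None,
) -> None:
    """Write calls as a delimited table or a minimal VCF 4.2 file.

    The VCF output emits one record per candidate; failed candidates carry
    their failure reasons as FILTER codes, called variants are PASS.  The
    allelic fraction (percent) and stranded alt depths are INFO fields.
    """
    path = Path(path)
    if format == "tsv":
        calls_to_frame(calls).to_csv(path, sep="\t", index=False)
        return
    if format != "vcf":
        raise ValueError(f"unknown output format {format!r}")
    by_id = _known_loci(loci)
    reasons_seen = sorted({r for c in calls for r in c.failure_reasons})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=arfidelity",
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">',
        '##INFO=<ID=AFPCT,Number=1,Type=Float,Description="Allelic fraction, percent (100*alt/ref)">',
        '##INFO=<ID=ALTF,Number=1,Type=Integer,Description="Alt reads, forward strand">',
        '##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Alt reads, reverse strand">',
        '##INFO=<ID=REFDP,Number=1,Type=Integer,Description="Reference read depth">',
    ]
    for reason in reasons_seen:
        lines.append(f'##FILTER=<ID={reason},Description="Failed {reason} filter">')
    for chrom in dict.fromkeys(l.chrom for l in by_id.values()):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in calls:
        locus = by_id[c.locus_id]
        filt = "PASS" if c.called else ";".join(sorted(c.failure_reasons))
        sample = c.sample_id.replace(" ", "_")
        info = (
            f"SAMPLE={sample};AFPCT={c.allelic_fraction_percent:.6g};"
            f"ALTF={c.alt_fwd};ALTR={c.alt_rev};REFDP={c.ref_count}"
        )
        lines.append(
            f"{locus.chrom}\t{locus.position}\t{c.locus_id}\t{locus.ref_base}\t"
            f"{c.alt_allele}\t.\t{filt}\t{info}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_calls(path: str | Path) -> list[VariantCall]:
    """Read back a TSV produced by :func:`write_calls` (exact round trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        reasons = frozenset() if row.failure_reasons == "." else frozenset(
            row.failure_reasons.split(",")
        )
        calls.append(
            VariantCall(
                sample_id=row.sample_id,
                locus_id=row.locus_id,
                alt_allele=row.alt_allele,
                alt_count=int(row.alt_count),
                ref_count=int(row.ref_count),
                alt_fwd=int(row.alt_fwd),
                alt_rev=int(row.alt_rev),
                allelic_fraction_percent=float(row.allelic_fraction_percent),
                failure_reasons=reasons,
                saturated=int(row.ref_count) == 0,
            )
        )
    return calls


def default_count_table_path() -> Path:
    """Path of the packaged deep-sequencing count-table fixture."""
    from importlib import resources

    return Path(str(resources.files("arfidelity").joinpath("data/table2_ngs_counts.tsv")))
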