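"""Locus/polymerase error-rate estimation and cross-platform concordance.

Quantifies amplification error from observed artifact fractions, compares
it to vendor-reported polymerase fidelity, tests whether one hotspot is
more artifact-prone than another, and classifies deep-sequencing candidate
mutations as validated or false positive against ddPCR run under multiple
preamplification polymerases.

Error-rate model: under the molecule-duplication branching model the
expected artifact fraction after ``c`` cycles is ``f = c * e / 2`` (half of
all strands at any cycle are newly synthesised), so the inferred
per-base-per-duplication rate from an observed fraction is
``e_hat = 2 * f_obs / c``.  The model factor is configurable (1 for a
strand-level convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.stats import beta

from .amplification_simulator import PolymeraseProfile
from .ddpcr_quant import DropletData, raw_allelic_fraction
from .ngs_caller import VariantCall, round_half_up

__all__ = [
    "ErrorRateEstimate",
    "FoldComparison",
    "LocusComparison",
    "ConcordanceRecord",
    "ConcordanceResult",
    "ControlRequiredError",
    "RunInvalidError",
    "estimate_error_rate",
    "fold_over_reported",
    "compare_locus_rates",
    "classify_concordance",
    "fidelity_report",
    "FidelityReport",
]


class ControlRequiredError(ValueError):
    """Classification refused: required control assays are missing."""


class RunInvalidError(ValueError):
    """A no-template control was positive; the run is contaminated."""


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Inferred amplification error rate at one locus under one polymerase.

    ``f_obs = mut/wt`` is the observed artifact fraction;
    ``e_hat = model_factor * f_obs / cycles`` is the per-base-per-
    duplication rate; the confidence bounds come from an exact
    Clopper–Pearson interval on the proportion ``mut / (mut + wt)`` mapped
    through ``p -> model_factor * (p / (1 - p)) / cycles`` (the same
    transform that carries the point estimate, so
    ``ci_low <= e_hat <= ci_high`` holds identically).
    """

    locus_id: str
    polymerase: str
    mut_count: int
    wt_count: int
    cycles: int
    f_obs: float
    e_hat: float
    ci_low: float
    ci_high: float
    conf: float = 0.95
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        assert self.ci_low <= self.e_hat <= self.ci_high


def estimate_error_rate(
    mut_count: int,
    wt_count: int,
    cycles: int,
    locus_id: str = "",
    polymerase: str = "",
    conf: float = 0.95,
    model_factor: float = 2.0,
) -> ErrorRateEstimate:
    """Estimate the per-base-per-duplication error rate from observed
    mutant/wild-type counts after ``cycles`` amplification cycles.

    Estimates above 1e-2 violate the small-error assumption of the linear
    accumulation model and are flagged ``DEGENERATE``.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if wt_count <= 0:
        raise ValueError("wt_count must be positive")
    if mut_count < 0:
        raise ValueError("mut_count must be non-negative")
    n = mut_count + wt_count
    f_obs = mut_count / wt_count
    e_hat = model_factor * f_obs / cycles
    alpha = 1.0 - conf

    def transform(p: float) -> float:
        if p >= 1.0:
            return math.inf
        return model_factor * (p / (1.0 - p)) / cycles

    p_lo = 0.0 if mut_count == 0 else float(beta.ppf(alpha / 2, mut_count, n - mut_count + 1))
    p_hi = float(beta.ppf(1 - alpha / 2, mut_count + 1, n - mut_count))
    flags = set()
    if e_hat > 1e-2:
        flags.add("DEGENERATE")
    return ErrorRateEstimate(
        locus_id=locus_id,
        polymerase=polymerase,
        mut_count=mut_count,
        wt_count=wt_count,
        cycles=cycles,
        f_obs=f_obs,
        e_hat=e_hat,
        ci_low=transform(p_lo),
        ci_high=transform(p_hi),
        conf=conf,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class FoldComparison:
    """Observed error rate relative to the vendor-reported fidelity.

    ``kind`` is ``"point"`` when the vendor states a numeric rate (then
    ``fold = e_hat / reported``) or ``"bound"`` when only an upper bound is
    claimed (then ``fold`` is the minimum fold implied by the bound, or
    None when the observation is consistent with the claim).
    """

    polymerase: str
    e_hat: float
    kind: str
    fold: float | None
    consistent_with_reported: bool


def fold_over_reported(e_hat: float, polymerase: PolymeraseProfile) -> FoldComparison:
    """Compare an inferred error rate with the vendor-reported one."""
    if e_hat < 0:
        raise ValueError("e_hat must be non-negative")
    if polymerase.reported_error_rate is not None:
        rate = polymerase.reported_error_rate
        if rate <= 0:
            raise ValueError(f"{polymerase.name}: reported rate must be positive")
        fold = e_hat / rate
        return FoldComparison(polymerase.name, e_hat, "point", fold, fold <= 1.0)
    bound = polymerase.reported_rate_bound
    if bound is None or bound <= 0:
        raise ValueError(f"{polymerase.name}: no usable reported fidelity")
    if e_hat <= bound:
        return FoldComparison(polymerase.name, e_hat, "bound", None, True)
    return FoldComparison(polymerase.name, e_hat, "bound", e_hat / bound, False)


@dataclass(frozen=True)
class LocusComparison:
    """Paired comparison of per-sample artifact fractions at two loci."""

    n_pairs: int
    n_positive_differences: int
    wilcoxon_statistic: float
    wilcoxon_p: float
    t_statistic: float
    t_p: float
    no_signal: bool = False


def compare_locus_rates(
    af_locus_a: Sequence[float], af_locus_b: Sequence[float]
) -> LocusComparison:
    """Two-sided paired test of per-sample allelic fractions at two loci
    measured under the same polymerase.

    Primary: Wilcoxon signed-rank, exact for n <= 25 (zero differences are
    dropped, the usual signed-rank convention).  A paired t-test is
    reported alongside.  All-zero differences yield the no-signal result
    p = 1.
    """
    a = np.asarray(af_locus_a, dtype=float)
    b = np.asarray(af_locus_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if len(a) < 5:
        raise ValueError("need at least 5 paired samples")
    diffs = a - b
    n_pos = int((diffs > 0).sum())
    if np.all(diffs == 0):
        return LocusComparison(len(a), 0, float("nan"), 1.0, float("nan"), 1.0, no_signal=True)
    method = "exact" if len(a) <= 25 else "auto"
    w = stats.wilcoxon(a, b, alternative="two-sided", method=method, zero_method="wilcox")
    t = stats.ttest_rel(a, b)
    return LocusComparison(
        n_pairs=len(a),
        n_positive_differences=n_pos,
        wilcoxon_statistic=float(w.statistic),
        wilcoxon_p=float(w.pvalue),
        t_statistic=float(t.statistic),
        t_p=float(t.pvalue),
    )


@dataclass(frozen=True)
class ConcordanceRecord:
    """Cross-platform verdict for one deep-sequencing candidate (or one
    artifact-prone control flag)."""

    sample_id: str
    locus_id: str
    ngs_af_percent: float | None
    ddpcr_af_by_polymerase: Mapping[str, float]
    verdict: str  # VALIDATED | FALSE_POSITIVE | ARTIFACT_PRONE_LOCUS | NOT_ASSESSED


@dataclass(frozen=True)
class ConcordanceResult:
    records: tuple[ConcordanceRecord, ...]
    artifact_prone: frozenset[tuple[str, str]]  # (locus_id, polymerase)

    def verdict(self, sample_id: str, locus_id: str) -> str:
        for r in self.records:
            if r.sample_id == sample_id and r.locus_id == locus_id:
                return r.verdict
        raise KeyError((sample_id, locus_id))


def classify_concordance(
    ngs_calls: Sequence[VariantCall],
    ddpcr_data: Sequence[DropletData],
    control_equivalents: Mapping[str, str] | None = None,
    positive_min_droplets: int = 1,
) -> ConcordanceResult:
    """Classify deep-sequencing candidate mutations by ddPCR concordance.

    Decision rules, applied per called NGS candidate:

    1. Any positive no-template control invalidates the run
       (:class:`RunInvalidError`).
    2. A (locus, polymerase) whose preamplified wild-type control DNA is
       mutant-positive is flagged ``ARTIFACT_PRONE_LOCUS`` for that
       polymerase: positivity under it cannot validate a call.
    3. A call positive by ddPCR under some polymerase whose wild-type
       control is clean at that locus is ``VALIDATED``.
    4. A call negative under every such clean polymerase with data (and
       positive under none) is ``FALSE_POSITIVE``.
    5. Otherwise ``NOT_ASSESSED``.

    Samples sequenced but not assayed by ddPCR may be mapped onto a ddPCR
    control via ``control_equivalents`` (e.g. a healthy-donor NGS control
    onto the preamplified wild-type genomic DNA control); pass an empty
    mapping to disable.  Classification refuses to run without preamplified
    wild-type and no-template controls for every locus/polymerase touched
    (:class:`ControlRequiredError`).
    """
    if control_equivalents is None:
        control_equivalents = {}
    preamp = [d for d in ddpcr_data if d.preamplified]
    ntc_rows = [d for d in ddpcr_data if d.sample_type == "ntc"]
    bad_ntc = [d for d in ntc_rows if d.mut_channel >= positive_min_droplets]
    if bad_ntc:
        offenders = sorted({(d.locus_id, d.polymerase, d.preamplified) for d in bad_ntc})
        raise RunInvalidError(f"positive no-template control(s): {offenders}")

    polys = sorted({d.polymerase for d in preamp})
    loci_assayed = sorted({d.locus_id for d in preamp})
    wt_controls: dict[tuple[str, str], DropletData] = {}
    for d in preamp:
        if d.sample_type == "wt_control":
            wt_controls[(d.locus_id, d.polymerase)] = d
    for locus in loci_assayed:
        for poly in sorted({d.polymerase for d in preamp if d.locus_id == locus}):
            if (locus, poly) not in wt_controls:
                raise ControlRequiredError(
                    f"no preamplified wild-type control for {locus} under {poly}"
                )
            if not any(
                d.locus_id == locus and d.polymerase == poly and d.preamplified
                for d in ntc_rows
            ):
                raise ControlRequiredError(
                    f"no preamplified no-template control for {locus} under {poly}"
                )

    artifact_prone = frozenset(
        key for key, d in wt_controls.items() if d.mut_channel >= positive_min_droplets
    )

    records: list[ConcordanceRecord] = []
    for (locus, poly) in sorted(artifact_prone):
        d = wt_controls[(locus, poly)]
        records.append(
            ConcordanceRecord(
                sample_id=d.sample_id,
                locus_id=locus,
                ngs_af_percent=None,
                ddpcr_af_by_polymerase={poly: raw_allelic_fraction(d)},
                verdict="ARTIFACT_PRONE_LOCUS",
            )
        )

    by_sample_locus: dict[tuple[str, str], dict[str, DropletData]] = {}
    for d in preamp:
        if d.sample_type in ("patient", "wt_control", "healthy_control"):
            by_sample_locus.setdefault((d.sample_id, d.locus_id), {})[d.polymerase] = d

    for call in ngs_calls:
        if not call.called:
            continue
        dd_sample = control_equivalents.get(call.sample_id, call.sample_id)
        assays = by_sample_locus.get((dd_sample, call.locus_id), {})
        if not assays:
            verdict = "NOT_ASSESSED"
            afs: dict[str, float] = {}
        else:
            afs = {poly: raw_allelic_fraction(d) for poly, d in sorted(assays.items())}
            clean = {
                poly: d
                for poly, d in assays.items()
                if (call.locus_id, poly) not in artifact_prone
            }
            pos_clean = [
                poly for poly, d in clean.items() if d.mut_channel >= positive_min_droplets
            ]
            neg_clean = [
                poly for poly, d in clean.items() if d.mut_channel < positive_min_droplets
            ]
            if pos_clean:
                verdict = "VALIDATED"
            elif neg_clean:
                verdict = "FALSE_POSITIVE"
            else:
                verdict = "NOT_ASSESSED"
        records.append(
            ConcordanceRecord(
                sample_id=call.sample_id,
                locus_id=call.locus_id,
                ngs_af_percent=call.allelic_fraction_percent,
                ddpcr_af_by_polymerase=afs,
                verdict=verdict,
            )
        )
    return ConcordanceResult(records=tuple(records), artifact_prone=artifact_prone)


@dataclass(frozen=True)
class FidelityReport:
    """Machine-readable fidelity summary with a plain-text rendering."""

    ngs_locus_prevalence: Mapping[str, Mapping[str, object]]
    error_estimates: tuple[ErrorRateEstimate, ...]
    fold_comparisons: tuple[FoldComparison, ...]
    concordance: ConcordanceResult | None

    def to_dict(self) -> dict:
        return {
            "ngs_locus_prevalence": {k: dict(v) for k, v in self.ngs_locus_prevalence.items()},
            "error_estimates": [
                {
                    "locus_id": e.locus_id,
                    "polymerase": e.polymerase,
                    "cycles": e.cycles,
                    "f_obs": e.f_obs,
                    "e_hat": e.e_hat,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                for e in self.error_estimates
            ],
            "fold_comparisons": [
                {
                    "polymerase": f.polymerase,
                    "e_hat": f.e_hat,
                    "kind": f.kind,
                    "fold": f.fold,
                    "consistent_with_reported": f.consistent_with_reported,
                }
                for f in self.fold_comparisons
            ],
            "verdicts": [
                {
                    "sample_id": r.sample_id,
                    "locus_id": r.locus_id,
                    "ngs_af_percent": r.ngs_af_percent,
                    "verdict": r.verdict,
                }
                for r in (self.concordance.records if self.concordance else ())
            ],
        }

    def to_text(self) -> str:
        lines = ["Detection-fidelity report", "=" * 25, ""]
        lines.append("Deep-sequencing prevalence by locus:")
        for locus, info in self.ngs_locus_prevalence.items():
            lines.append(
                f"  {locus}: called in {info['n_patients_called']}/{info['n_patients']} patients"
                + (f" + {info['n_controls_called']} control(s)" if info["n_controls_called"] else "")
            )
        if self.error_estimates:
            lines.append("")
            lines.append("Amplification error-rate estimates (from preamplified WT control DNA):")
            for e in self.error_estimates:
                lines.append(
                    f"  {e.locus_id} / {e.polymerase} ({e.cycles} cycles): "
                    f"e_hat = {e.e_hat:.3g} [{e.ci_low:.3g}, {e.ci_high:.3g}]"
                )
        if self.fold_comparisons:
            lines.append("")
            lines.append("Fold over vendor-reported fidelity:")
            for f in self.fold_comparisons:
                if f.kind == "point":
                    lines.append(f"  {f.polymerase}: {f.fold:.1f}x reported")
                elif f.consistent_with_reported:
                    lines.append(f"  {f.polymerase}: consistent with reported bound")
                else:
                    lines.append(f"  {f.polymerase}: >= {f.fold:.1f}x reported bound")
        if self.concordance is not None:
            lines.append("")
            lines.append("Cross-platform verdicts:")
            for r in self.concordance.records:
                af = "" if r.ngs_af_percent is None else f" (NGS AF {r.ngs_af_percent:.2f}%)"
                lines.append(f"  {r.sample_id} {r.locus_id}{af}: {r.verdict}")
        return "\n".join(lines) + "\n"


def fidelity_report(
    ngs_calls: Sequence[VariantCall],
    ddpcr_data: Sequence[DropletData],
    polymerases: Mapping[str, PolymeraseProfile],
    patient_samples: Sequence[str],
    control_samples: Sequence[str] = (),
    control_equivalents: Mapping[str, str] | None = None,
) -> FidelityReport:
    """Assemble the cohort-level fidelity report.

    Error rates are estimated from preamplified wild-type control rows
    (artifacts in known mutation-free DNA are the purest error signal);
    fold comparisons use each polymerase's vendor profile.  An empty cohort
    yields an empty report.
    """
    prevalence: dict[str, dict[str, object]] = {}
    called = [c for c in ngs_calls if c.called]
    for locus in sorted({c.locus_id for c in ngs_calls}):
        carriers = {c.sample_id for c in called if c.locus_id == locus}
        prevalence[locus] = {
            "n_patients": len(patient_samples),
            "n_patients_called": len(carriers & set(patient_samples)),
            "n_controls_called": len(carriers & set(control_samples)),
            "samples": sorted(carriers),
        }

    estimates = []
    folds = []
    for d in ddpcr_data:
        if d.sample_type == "wt_control" and d.preamplified and d.wt_channel > 0:
            est = estimate_error_rate(
                d.mut_channel,
                d.wt_channel,
                d.preamp_cycles,
                locus_id=d.locus_id,
                polymerase=d.polymerase,
            )
            estimates.append(est)
            if d.polymerase in polymerases:
                folds.append(fold_over_reported(est.e_hat, polymerases[d.polymerase]))

    concordance = None
    if ngs_calls and ddpcr_data:
        concordance = classify_concordance(
            ngs_calls, ddpcr_data, control_equivalents=control_equivalents
        )
    return FidelityReport(
        ngs_locus_prevalence=prevalence,
        error_estimates=tuple(estimates),
        fold_comparisons=tuple(folds),
        concordance=concordance,
    )
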