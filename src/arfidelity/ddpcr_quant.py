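"""Droplet digital PCR quantification and AR copy-number calling.

Inputs are classified droplet counts per sample and assay (an assay is a
locus + preamplification polymerase + cycle number).  Two allelic-fraction
statistics are provided:

* the raw mutant/wild-type droplet ratio, ``100 * mut / wt`` — the
  convention of the packaged study tables, which do not report total droplet
  counts;
* Poisson-corrected concentrations ``lambda = -ln(1 - n_pos / n_total)``
  (mean target molecules per droplet) and the fractional abundance
  ``100 * lambda_mut / (lambda_mut + lambda_wt)``, available only when the
  total droplet count is known (e.g. simulated assays).

Replicate wells are merged by elementwise summation before quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import beta

__all__ = [
    "DropletData",
    "QuantResult",
    "CopyNumberResult",
    "SaturationError",
    "MergeError",
    "merge_replicates",
    "raw_allelic_fraction",
    "poisson_lambda",
    "poisson_lambda_ci",
    "poisson_fractional_abundance",
    "quantify",
    "copy_number",
    "read_droplet_table",
    "default_droplet_table_path",
    "COPY_NUMBER_THRESHOLD",
]

#: Samples at or above this AR copy-number estimate are called increased.
COPY_NUMBER_THRESHOLD = 1.9


class SaturationError(ValueError):
    """All droplets positive: concentration not estimable."""


class MergeError(ValueError):
    """Replicates from different samples or assays cannot be merged."""


@dataclass(frozen=True)
class DropletData:
    """Classified droplet counts for one sample in one assay.

    ``n_mut_pos`` and ``n_wt_pos`` are single-channel-positive counts;
    droplets positive in both channels are ``n_double_pos``.  Study-table
    fixtures report channel totals with no double-positive breakdown, which
    is represented as ``n_double_pos = 0``.  ``n_total`` (all droplets,
    including negatives) is optional; without it only raw ratios are
    computable.
    """

    sample_id: str
    locus_id: str
    polymerase: str
    preamp_cycles: int
    n_mut_pos: int
    n_wt_pos: int
    n_double_pos: int = 0
    n_neg: int | None = None
    n_total: int | None = None
    sample_type: str = "patient"
    preamplified: bool = True

    def __post_init__(self) -> None:
        for name in ("n_mut_pos", "n_wt_pos", "n_double_pos"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_total is not None:
            occupied = self.n_mut_pos + self.n_wt_pos + self.n_double_pos
            if self.n_neg is not None and occupied + self.n_neg != self.n_total:
                raise ValueError("droplet partition does not sum to n_total")
            if occupied > self.n_total:
                raise ValueError("more positive droplets than total droplets")

    @property
    def mut_channel(self) -> int:
        """Mutant-channel positives (singles + doubles)."""
        return self.n_mut_pos + self.n_double_pos

    @property
    def wt_channel(self) -> int:
        """Wild-type-channel positives (singles + doubles)."""
        return self.n_wt_pos + self.n_double_pos

    @property
    def assay(self) -> tuple[str, str, int]:
        return (self.locus_id, self.polymerase, self.preamp_cycles)


@dataclass(frozen=True)
class QuantResult:
    raw_af_percent: float
    lambda_mut: float | None
    lambda_wt: float | None
    poisson_af_percent: float | None
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    cn_estimate: float
    increased: bool

    def __post_init__(self) -> None:
        assert self.increased == (self.cn_estimate >= COPY_NUMBER_THRESHOLD)


def merge_replicates(replicates: Sequence[DropletData]) -> DropletData:
    """Sum droplet counts over replicate wells of the same sample and assay.

    A single replicate is returned unchanged.  ``n_total``/``n_neg`` are
    summed only when present in every replicate.
    """
    if not replicates:
        raise MergeError("no replicates to merge")
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.sample_id != first.sample_id or rep.assay != first.assay:
            raise MergeError(
                f"cannot merge {rep.sample_id}/{rep.assay} into {first.sample_id}/{first.assay}"
            )
    totals = [r.n_total for r in replicates]
    negs = [r.n_neg for r in replicates]
    return replace(
        first,
        n_mut_pos=sum(r.n_mut_pos for r in replicates),
        n_wt_pos=sum(r.n_wt_pos for r in replicates),
        n_double_pos=sum(r.n_double_pos for r in replicates),
        n_total=sum(totals) if all(t is not None for t in totals) else None,
        n_neg=sum(negs) if all(n is not None for n in negs) else None,
    )


def raw_allelic_fraction(d: DropletData, include_double_in_mutant: bool = True) -> float:
    """Raw mutant/wild-type droplet ratio in percent (``100 * mut / wt``).

    This is the statistic printed in the study tables.  A mutant-positive
    assay with zero wild-type droplets is saturated and reported as 100 (the
    tables' convention for pure mutant control DNA); use :func:`quantify`
    to obtain the SATURATED flag alongside.  Zero droplets in both channels
    quantifies as 0.0 only because no mutant signal is present.
    """
    mut = d.mut_channel if include_double_in_mutant else d.n_mut_pos
    wt = d.wt_channel
    if wt == 0:
        return 100.0 if mut > 0 else 0.0
    return 100.0 * mut / wt


def poisson_lambda(n_pos: int, n_total: int) -> float:
    """Mean target molecules per droplet from Poisson partitioning,
    ``-ln(1 - n_pos/n_total)``.

    Raises :class:`SaturationError` when every droplet is positive.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must be in [0, n_total]")
    if n_pos == n_total:
        raise SaturationError("all droplets positive; concentration unbounded")
    return -math.log1p(-n_pos / n_total)


def poisson_lambda_ci(n_pos: int, n_total: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) confidence interval for the per-droplet mean
    occupancy, obtained by transforming the binomial interval on the
    positive-droplet fraction through ``-ln(1 - p)``."""
    if not 0 <= n_pos <= n_total:
        raise ValueError("n_pos must be in [0, n_total]")
    alpha = 1.0 - conf
    lo_p = 0.0 if n_pos == 0 else float(beta.ppf(alpha / 2, n_pos, n_total - n_pos + 1))
    hi_p = 1.0 if n_pos == n_total else float(beta.ppf(1 - alpha / 2, n_pos + 1, n_total - n_pos))
    hi = math.inf if hi_p >= 1.0 else -math.log1p(-hi_p)
    return (-math.log1p(-lo_p), hi)


def poisson_fractional_abundance(d: DropletData) -> float:
    """Poisson-corrected mutant fractional abundance in percent,
    ``100 * lambda_mut / (lambda_mut + lambda_wt)``.

    Channel positives include double-positive droplets.  Requires
    ``n_total``; raises ``ValueError`` without it and
    :class:`SaturationError` if either channel is fully positive.
    """
    if d.n_total is None:
        raise ValueError(f"{d.sample_id}: n_total unknown; only raw ratios computable")
    lam_mut = poisson_lambda(d.mut_channel, d.n_total)
    lam_wt = poisson_lambda(d.wt_channel, d.n_total)
    if lam_mut + lam_wt == 0:
        return 0.0
    return 100.0 * lam_mut / (lam_mut + lam_wt)


def quantify(d: DropletData, include_double_in_mutant: bool = True) -> QuantResult:
    """Compute raw and (when possible) Poisson statistics with flags."""
    flags = set()
    if d.wt_channel == 0 and d.mut_channel > 0:
        flags.add("SATURATED")
    raw = raw_allelic_fraction(d, include_double_in_mutant)
    lam_mut = lam_wt = pois = None
    if d.n_total is None:
        flags.add("NO_TOTAL")
    else:
        try:
            lam_mut = poisson_lambda(d.mut_channel, d.n_total)
            lam_wt = poisson_lambda(d.wt_channel, d.n_total)
            pois = poisson_fractional_abundance(d)
        except SaturationError:
            flags.add("SATURATED")
    return QuantResult(
        raw_af_percent=raw,
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        poisson_af_percent=pois,
        flags=frozenset(flags),
    )


def _as_lambda(x: DropletData | float) -> float:
    if isinstance(x, DropletData):
        if x.n_total is None:
            raise ValueError("copy number from droplet data requires n_total")
        return poisson_lambda(x.mut_channel + x.n_wt_pos, x.n_total)
    return float(x)


def copy_number(
    target: DropletData | float,
    reference: DropletData | float,
    reference_copies_in_sample: int,
    sample_id: str = "",
) -> CopyNumberResult:
    """AR copy number from target and reference concentrations.

    ``cn = (lambda_target / lambda_reference) * reference_copies_in_sample``
    where ``reference_copies_in_sample`` is the expected copy count of the
    reference gene in the assayed genome: 1 for an X-linked reference (ZXDB)
    in a male sample, 2 for a female sample or an autosomal reference
    (NSUN3) scaled to the male X baseline.  A sample is called increased at
    ``cn >= 1.9`` (inclusive).
    """
    lam_t = _as_lambda(target)
    lam_r = _as_lambda(reference)
    if lam_r <= 0:
        raise ValueError("reference concentration must be positive")
    cn = lam_t / lam_r * reference_copies_in_sample
    if isinstance(target, DropletData) and not sample_id:
        sample_id = target.sample_id
    return CopyNumberResult(sample_id=sample_id, cn_estimate=cn, increased=cn >= COPY_NUMBER_THRESHOLD)


_DDPCR_COLUMNS = [
    "sample_id",
    "sample_type",
    "locus_id",
    "polymerase",
    "cycles",
    "preamplified",
    "mut_droplets",
    "wt_droplets",
]


def read_droplet_table(path: str | Path | pd.DataFrame) -> list[DropletData]:
    """Read a delimited droplet-count table (path or pre-loaded DataFrame).

    Expected columns: ``sample_id, sample_type, locus_id, polymerase,
    cycles, preamplified, mut_droplets, wt_droplets`` with optional
    ``double_droplets, neg_droplets, total_droplets`` and extra columns
    (e.g. a table label) ignored.
    """
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep="\t")
    missing = [c for c in _DDPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        get = lambda name: getattr(row, name, None)
        n_total = get("total_droplets")
        n_neg = get("neg_droplets")
        out.append(
            DropletData(
                sample_id=str(row.sample_id),
                locus_id=str(row.locus_id),
                polymerase=str(row.polymerase),
                preamp_cycles=int(row.cycles),
                n_mut_pos=int(row.mut_droplets),
                n_wt_pos=int(row.wt_droplets),
                n_double_pos=int(get("double_droplets") or 0),
                n_neg=int(n_neg) if n_neg is not None and not pd.isna(n_neg) else None,
                n_total=int(n_total) if n_total is not None and not pd.isna(n_total) else None,
                sample_type=str(row.sample_type),
                preamplified=bool(int(row.preamplified)),
            )
        )
    return out


def default_droplet_table_path() -> Path:
    """Path of the packaged ddPCR droplet-count fixture."""
    from importlib import resources

    return Path(str(resources.files("arfidelity").joinpath("data/ddpcr_droplet_counts.tsv")))
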