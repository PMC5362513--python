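"""Stochastic model of PCR preamplification error and downstream sampling.

This is the package's synthetic-data generator.  It emulates the structure
of the study data: plasma cfDNA template pools carrying true hotspot
mutations at low allelic fraction (0.2–0.5 %), polymerase-introduced
artifacts accumulating over 12–22 preamplification cycles, deep-sequencing
count sampling at ~10,000x, and Poisson droplet partitioning for ddPCR.

The amplification model is a molecule-level branching process: each cycle,
every molecule independently produces one copy with probability equal to
the per-cycle efficiency; each new copy acquires a substitution at a
tracked hotspot with probability ``e = base_error_rate * locus_multiplier``
(errors per base per duplication).  Parents persist unchanged and mutant
molecules propagate in later cycles; back-mutation (an ``e**2`` effect) is
ignored.  Under this model the expected mutant fraction after ``c`` cycles
at efficiency 1 is ``c * e / 2``: each cycle, half of all strands are newly
synthesised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ddpcr_quant import DropletData
from .locus_model import LocusSpec, load_loci
from .ngs_caller import AlleleCountRecord

__all__ = [
    "PolymeraseProfile",
    "AmplificationConfig",
    "NgsSimConfig",
    "LocusPool",
    "MoleculePool",
    "CohortDataset",
    "load_polymerases",
    "make_template_pool",
    "simulate_preamplification",
    "expected_error_fraction",
    "simulate_ngs_counts",
    "simulate_ddpcr",
    "simulate_cohort",
    "GENOME_EQUIVALENTS_PER_NG",
]

#: Haploid genome equivalents per nanogram of human DNA (~3.3 pg per genome).
GENOME_EQUIVALENTS_PER_NG = 303


@dataclass(frozen=True)
class PolymeraseProfile:
    """Per-base-per-duplication error model for one polymerase.

    ``base_error_rate`` drives the simulator; ``locus_multipliers`` scale it
    at specific hotspots (0 disables error there entirely, mimicking a
    polymerase with no detectable artifact at that locus).
    ``reported_error_rate`` is the vendor's genome-averaged figure, or None
    when the vendor states only a bound (then ``reported_rate_bound`` is
    that upper bound).
    """

    name: str
    base_error_rate: float
    locus_multipliers: Mapping[str, float] = field(default_factory=dict)
    reported_error_rate: float | None = None
    reported_rate_bound: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.base_error_rate <= 1e-2:
            raise ValueError(f"{self.name}: base_error_rate outside [0, 1e-2]")
        for locus, m in self.locus_multipliers.items():
            if not (math.isfinite(m) and m >= 0):
                raise ValueError(f"{self.name}: bad multiplier for {locus}")

    def effective_rate(self, locus_id: str) -> float:
        return self.base_error_rate * self.locus_multipliers.get(locus_id, 1.0)


@dataclass(frozen=True)
class AmplificationConfig:
    """Preamplification reaction parameters.

    ``input_genome_equivalents`` counts haploid templates per tracked
    amplicon; ``efficiency`` is the per-cycle duplication probability;
    ``max_total_molecules`` caps the exact simulation (beyond it the ref
    population grows deterministically and the run is flagged approximate).
    """

    input_genome_equivalents: int = 3 * GENOME_EQUIVALENTS_PER_NG
    cycles: int = 22
    efficiency: float = 0.95
    max_total_molecules: float = 1e15

    def __post_init__(self) -> None:
        if self.input_genome_equivalents < 1:
            raise ValueError("input_genome_equivalents must be >= 1")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must be in (0, 1]")


@dataclass(frozen=True)
class NgsSimConfig:
    """Deep-sequencing count-sampling parameters."""

    depth: int = 10_000
    seq_error_rate: float = 1e-4
    strand_balance: float = 0.5
    quality_mean: float = 33.0
    mapq_mean: float = 60.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if not 0 < self.strand_balance < 1:
            raise ValueError("strand_balance must be in (0, 1)")


@dataclass
class LocusPool:
    """Molecule counts per allele at one tracked locus."""

    ref_base: str
    alt_bases: tuple[str, ...]
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def mutant_count(self) -> int:
        return self.total - self.counts.get(self.ref_base, 0)

    @property
    def mutant_fraction(self) -> float:
        total = self.total
        return self.mutant_count / total if total else 0.0

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative molecule count")


@dataclass
class MoleculePool:
    """Simulated template population across all tracked loci."""

    loci: dict[str, LocusPool]
    approximated: bool = False

    def validate(self) -> None:
        for pool in self.loci.values():
            pool.validate()


def load_polymerases(path: str | Path | None = None) -> dict[str, PolymeraseProfile]:
    """Load polymerase profiles from YAML (packaged defaults if no path)."""
    if path is None:
        path = Path(str(resources.files("arfidelity").joinpath("data/polymerases.yaml")))
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for entry in doc["polymerases"]:
        out[entry["name"]] = PolymeraseProfile(
            name=entry["name"],
            base_error_rate=float(entry["base_error_rate"]),
            locus_multipliers={k: float(v) for k, v in (entry.get("locus_multipliers") or {}).items()},
            reported_error_rate=(
                float(entry["reported_error_rate"])
                if entry.get("reported_error_rate") is not None
                else None
            ),
            reported_rate_bound=(
                float(entry["reported_rate_bound"])
                if entry.get("reported_rate_bound") is not None
                else None
            ),
        )
    return out


def make_template_pool(
    loci: Iterable[LocusSpec],
    genome_equivalents: int,
    sex: str = "male",
    true_mutations: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> MoleculePool:
    """Build a pre-amplification template pool.

    AR is X-linked: male samples contribute 1 template copy per genome
    equivalent, female samples 2.  ``true_mutations`` maps locus_id to the
    true mutant allelic fraction (of templates); mutant template counts are
    binomially sampled when an ``rng`` is given, otherwise rounded
    deterministically.  Multi-alt loci split the mutant templates over the
    first declared alternate (true mutations in this study are single-base).
    """
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    copies = genome_equivalents * (1 if sex == "male" else 2)
    true_mutations = dict(true_mutations or {})
    pools: dict[str, LocusPool] = {}
    for locus in loci:
        af = true_mutations.pop(locus.locus_id, 0.0)
        if not 0 <= af <= 0.5:
            raise ValueError(f"{locus.locus_id}: true AF {af} outside [0, 0.5]")
        if rng is not None:
            n_mut = int(rng.binomial(copies, af))
        else:
            n_mut = round(copies * af)
        counts = {locus.ref_base: copies - n_mut}
        for i, alt in enumerate(locus.alt_bases):
            counts[alt] = n_mut if i == 0 else 0
        pools[locus.locus_id] = LocusPool(locus.ref_base, locus.alt_bases, counts)
    if true_mutations:
        raise KeyError(f"true mutations at undeclared loci: {sorted(true_mutations)}")
    return MoleculePool(loci=pools)


def simulate_preamplification(
    pool: MoleculePool,
    polymerase: PolymeraseProfile,
    config: AmplificationConfig,
    rng: np.random.Generator | int,
) -> MoleculePool:
    """Run the branching-process preamplification and return the final pool.

    Exact per-cycle sampling: every molecule of every allele class
    duplicates with probability ``efficiency``; new reference copies mutate
    with probability ``e`` (substitution drawn uniformly over the locus's
    declared alternates).  If the expected final population exceeds
    ``config.max_total_molecules`` the reference majority grows
    deterministically instead (mutant lineages stay stochastic) and the
    result is flagged ``approximated``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    pool.validate()
    p = config.efficiency
    out: dict[str, LocusPool] = {}
    approximated = False
    for locus_id, lp in pool.loci.items():
        e = polymerase.effective_rate(locus_id)
        if not 0 <= e < 0.01:
            raise ValueError(
                f"{polymerase.name}@{locus_id}: effective error rate {e} outside [0, 0.01)"
            )
        expected_final = lp.total * (1 + p) ** config.cycles
        approx = expected_final > config.max_total_molecules
        approximated = approximated or approx
        counts = dict(lp.counts)
        alts = lp.alt_bases
        for _ in range(config.cycles):
            n_ref = counts.get(lp.ref_base, 0)
            alt_parents = {alt: counts.get(alt, 0) for alt in alts}
            if approx:
                new_ref = int(round(n_ref * p))
            else:
                new_ref = int(rng.binomial(n_ref, p))
            n_err = int(rng.binomial(new_ref, e)) if e > 0 and new_ref > 0 else 0
            counts[lp.ref_base] = n_ref + new_ref - n_err
            # mutant lineages duplicate too (no back-mutation); copies made
            # this cycle do not duplicate again until the next cycle
            for alt, n_alt in alt_parents.items():
                if n_alt:
                    counts[alt] = n_alt + int(rng.binomial(n_alt, p))
            if n_err:
                split = rng.multinomial(n_err, [1 / len(alts)] * len(alts))
                for alt, k in zip(alts, split):
                    counts[alt] = counts.get(alt, 0) + int(k)
        out[locus_id] = LocusPool(lp.ref_base, alts, counts)
    return MoleculePool(loci=out, approximated=approximated)


def expected_error_fraction(e: float, cycles: int, efficiency: float = 1.0) -> float:
    """Expected mutant allele fraction from amplification error alone.

    Computed iteratively as the ratio of expected mutant molecules to
    expected total molecules under the branching model; reduces to
    ``cycles * e / 2`` at efficiency 1 (each cycle, half of all strands are
    newly synthesised).  Valid for ``e * cycles << 1``.
    """
    if e < 0:
        raise ValueError("e must be non-negative")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    total = 1.0
    mutant = 0.0
    for _ in range(cycles):
        new_total = efficiency * total
        new_mut = mutant * efficiency + (total - mutant) * efficiency * e
        mutant += new_mut
        total += new_total
    return mutant / total


def simulate_ngs_counts(
    pool: MoleculePool,
    config: NgsSimConfig,
    rng: np.random.Generator | int,
    sample_id: str = "sim",
) -> list[AlleleCountRecord]:
    """Sample deep-sequencing allele counts from a molecule pool.

    ``depth`` reads per locus are drawn multinomially from the pool's
    allele fractions; each read's called base is then miscalled to one of
    the other three nucleotides (uniformly) with probability
    ``seq_error_rate``; strand is assigned by ``strand_balance``.  Returns
    one stranded record per allele with at least one read (the reference
    record is always emitted).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    bases = "ACGT"
    records: list[AlleleCountRecord] = []
    for locus_id, lp in sorted(pool.loci.items()):
        total = lp.total
        if total == 0:
            raise ValueError(f"{locus_id}: empty pool")
        fractions = np.array([lp.counts.get(b, 0) / total for b in bases])
        reads = rng.multinomial(config.depth, fractions)
        called = reads.astype(np.int64).copy()
        if config.seq_error_rate > 0:
            for i, b in enumerate(bases):
                n_err = rng.binomial(reads[i], config.seq_error_rate)
                if n_err:
                    called[i] -= n_err
                    others = [j for j in range(4) if j != i]
                    dest = rng.multinomial(n_err, [1 / 3] * 3)
                    for j, k in zip(others, dest):
                        called[j] += k
        for i, b in enumerate(bases):
            n = int(called[i])
            if n == 0 and b != lp.ref_base:
                continue
            fwd = int(rng.binomial(n, config.strand_balance)) if n else 0
            bq = float(np.clip(rng.normal(config.quality_mean, 2.0), 2.0, 45.0))
            mq = float(np.clip(rng.normal(config.mapq_mean, 2.0), 0.0, 60.0))
            records.append(
                AlleleCountRecord(
                    sample_id=sample_id,
                    locus_id=locus_id,
                    allele=b,
                    fwd_count=fwd,
                    rev_count=n - fwd,
                    mean_base_quality=round(bq, 1),
                    mean_mapq=round(mq, 1),
                )
            )
    return records


def simulate_ddpcr(
    pool: MoleculePool,
    locus_id: str,
    n_droplets: int,
    sampled_genome_equivalents: int,
    rng: np.random.Generator | int,
    sample_id: str = "sim",
    polymerase: str = "sim",
    preamp_cycles: int = 22,
    sample_type: str = "patient",
    preamplified: bool = True,
) -> DropletData:
    """Partition sampled molecules into droplets and classify them.

    ``sampled_genome_equivalents`` molecules of the locus amplicon are drawn
    from the pool's allele fractions and loaded uniformly at random into
    ``n_droplets`` droplets (Poisson loading): a droplet is mutant-positive
    if it received at least one mutant molecule, wild-type-positive with at
    least one reference molecule, double-positive with both.  The rare
    mutant molecules are placed individually; reference occupancy uses the
    Poisson occupancy probability ``1 - exp(-lambda_wt)`` per droplet.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    lp = pool.loci[locus_id]
    if sampled_genome_equivalents == 0 or lp.total == 0:
        return DropletData(
            sample_id=sample_id,
            locus_id=locus_id,
            polymerase=polymerase,
            preamp_cycles=preamp_cycles,
            n_mut_pos=0,
            n_wt_pos=0,
            n_double_pos=0,
            n_neg=n_droplets,
            n_total=n_droplets,
            sample_type=sample_type,
            preamplified=preamplified,
        )
    n_mut_mol = int(rng.binomial(sampled_genome_equivalents, lp.mutant_fraction))
    n_wt_mol = sampled_genome_equivalents - n_mut_mol
    lam_wt = n_wt_mol / n_droplets
    occ_wt = -math.expm1(-lam_wt)
    wt_channel = int(rng.binomial(n_droplets, occ_wt))
    mut_droplet_ids = np.unique(rng.integers(0, n_droplets, size=n_mut_mol))
    mut_channel = len(mut_droplet_ids)
    n_double = int(rng.binomial(mut_channel, wt_channel / n_droplets)) if mut_channel else 0
    n_mut_single = mut_channel - n_double
    n_wt_single = wt_channel - n_double
    n_neg = n_droplets - n_mut_single - n_wt_single - n_double
    return DropletData(
        sample_id=sample_id,
        locus_id=locus_id,
        polymerase=polymerase,
        preamp_cycles=preamp_cycles,
        n_mut_pos=n_mut_single,
        n_wt_pos=n_wt_single,
        n_double_pos=n_double,
        n_neg=n_neg,
        n_total=n_droplets,
        sample_type=sample_type,
        preamplified=preamplified,
    )


@dataclass
class CohortDataset:
    """Synthetic cohort emulating the study's data structure."""

    ngs_records: list[AlleleCountRecord]
    ddpcr_records: list[DropletData]

    def ngs_frame(self) -> pd.DataFrame:
        from .ngs_caller import COUNT_COLUMNS

        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "locus_id": r.locus_id,
                    "allele": r.allele,
                    "fwd_count": r.fwd_count,
                    "rev_count": r.rev_count,
                    "mean_base_quality": r.mean_base_quality,
                    "mean_mapq": r.mean_mapq,
                }
                for r in self.ngs_records
            ],
            columns=COUNT_COLUMNS,
        )

    def ddpcr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": d.sample_id,
                    "sample_type": d.sample_type,
                    "locus_id": d.locus_id,
                    "polymerase": d.polymerase,
                    "cycles": d.preamp_cycles,
                    "preamplified": int(d.preamplified),
                    "mut_droplets": d.n_mut_pos,
                    "wt_droplets": d.n_wt_pos,
                    "double_droplets": d.n_double_pos,
                    "neg_droplets": d.n_neg,
                    "total_droplets": d.n_total,
                }
                for d in self.ddpcr_records
            ]
        )


def simulate_cohort(
    n_patients: int,
    true_mutations: Mapping[str, Mapping[str, float]],
    ngs_polymerase: PolymeraseProfile,
    ddpcr_polymerases: Sequence[PolymeraseProfile],
    rng_seed: int,
    loci: Sequence[LocusSpec] | None = None,
    amp_config: AmplificationConfig | None = None,
    ngs_config: NgsSimConfig | None = None,
    n_droplets: int = 80_000,
    droplet_genome_equivalents: int = 30_000,
) -> CohortDataset:
    """Generate a full synthetic cohort (deep-sequencing table + per-
    polymerase ddPCR tables).

    ``true_mutations`` maps sample id (``"Pt 1"`` ... ``"Pt n"``) to
    {locus_id: true template AF}; true mutations are injected into the
    template pools before amplification, so every artifact arises only
    through polymerase error.  A healthy male and female control are
    appended to the NGS arm; the ddPCR arm includes preamplified wild-type
    genomic DNA and a preamplified plus a non-amplified no-template control
    per polymerase.  Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    loci = list(loci) if loci is not None else load_loci()
    amp_config = amp_config or AmplificationConfig()
    ngs_config = ngs_config or NgsSimConfig()

    samples: list[tuple[str, str, str, Mapping[str, float]]] = []
    for i in range(1, n_patients + 1):
        sid = f"Pt {i}"
        samples.append((sid, "patient", "male", true_mutations.get(sid, {})))
    samples.append(("Male Control", "healthy_control", "male", {}))
    samples.append(("Female Control", "healthy_control", "female", {}))

    ngs_records: list[AlleleCountRecord] = []
    ddpcr_records: list[DropletData] = []
    for sid, stype, sex, muts in samples:
        template = make_template_pool(
            loci, amp_config.input_genome_equivalents, sex=sex, true_mutations=muts, rng=rng
        )
        ngs_pool = simulate_preamplification(template, ngs_polymerase, amp_config, rng)
        ngs_records.extend(simulate_ngs_counts(ngs_pool, ngs_config, rng, sample_id=sid))
        if stype == "patient":
            for poly in ddpcr_polymerases:
                dd_template = make_template_pool(
                    loci, amp_config.input_genome_equivalents, sex=sex, true_mutations=muts, rng=rng
                )
                dd_pool = simulate_preamplification(dd_template, poly, amp_config, rng)
                for locus in loci:
                    ddpcr_records.append(
                        simulate_ddpcr(
                            dd_pool,
                            locus.locus_id,
                            n_droplets,
                            droplet_genome_equivalents,
                            rng,
                            sample_id=sid,
                            polymerase=poly.name,
                            preamp_cycles=amp_config.cycles,
                            sample_type="patient",
                        )
                    )

    # wild-type genomic DNA and no-template controls per ddPCR polymerase
    for poly in ddpcr_polymerases:
        wt_template = make_template_pool(
            loci, amp_config.input_genome_equivalents, sex="female", rng=rng
        )
        wt_pool = simulate_preamplification(wt_template, poly, amp_config, rng)
        empty = MoleculePool(
            loci={
                l.locus_id: LocusPool(l.ref_base, l.alt_bases, {l.ref_base: 0})
                for l in loci
            }
        )
        for locus in loci:
            ddpcr_records.append(
                simulate_ddpcr(
                    wt_pool,
                    locus.locus_id,
                    n_droplets,
                    droplet_genome_equivalents,
                    rng,
                    sample_id="Wild-type Genomic DNA",
                    polymerase=poly.name,
                    preamp_cycles=amp_config.cycles,
                    sample_type="wt_control",
                )
            )
            for preamp in (True, False):
                ddpcr_records.append(
                    simulate_ddpcr(
                        empty,
                        locus.locus_id,
                        n_droplets,
                        0,
                        rng,
                        sample_id="No Template Control",
                        polymerase=poly.name,
                        preamp_cycles=amp_config.cycles if preamp else 0,
                        sample_type="ntc",
                        preamplified=preamp,
                    )
                )
    return CohortDataset(ngs_records=ngs_records, ddpcr_records=ddpcr_records)
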