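"""Androgen-receptor hotspot locus definitions and sequence-context features.

The ligand-binding-domain hotspots interrogated throughout this package are
the five recurrently mutated AR codons linked to anti-androgen resistance:
L702H, W742C, H875Y, F877L and T878A.  Each locus is declared in a structured
YAML configuration (gene, chromosome, 1-based position of the mutated base,
reference base, alternate bases and the codon-change notation in which the
mutated base is lowercase, e.g. ``tTC>cTC`` for F877L).

Coordinates are 1-based inclusive in user-facing tables and configuration,
0-based internally; every function that crosses that boundary says which
convention it uses.  All loci are recorded on the genomic plus strand; the
codon notation is stored in transcript orientation with an explicit
``orientation`` flag (AR is plus-strand, so the two coincide here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml
from pyfaidx import Fasta

__all__ = [
    "LocusSpec",
    "ContextWindow",
    "CodonChange",
    "RepeatFeatures",
    "CodonNotationError",
    "UndefinedContentError",
    "parse_codon_notation",
    "format_codon_notation",
    "gc_content",
    "repeat_features",
    "load_loci",
    "load_context_windows",
    "default_loci_path",
    "default_context_fasta_path",
]

_VALID_BASES = set("ACGT")


class CodonNotationError(ValueError):
    """Raised when a codon-change notation string cannot be parsed."""


class UndefinedContentError(ValueError):
    """Raised when a sequence composition statistic is undefined (all-N)."""


class CodonChange(NamedTuple):
    """Parsed codon-change notation.

    ``ref_base``/``alt_bases`` are the uppercase substituted bases;
    ``codon_offset`` is the 0-based position of the change within the codon;
    ``wt_codon`` is the uppercase wild-type codon.
    """

    ref_base: str
    alt_bases: str
    codon_offset: int
    wt_codon: str


class RepeatFeatures(NamedTuple):
    max_homopolymer_len: int
    max_dinucleotide_repeat_units: int


@dataclass(frozen=True)
class LocusSpec:
    """A single AR hotspot locus.

    ``position`` is the 1-based genomic coordinate of the mutated base.
    """

    gene: str
    locus_id: str
    chrom: str
    position: int
    ref_base: str
    alt_bases: tuple[str, ...]
    codon_notation: str
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.locus_id}: position must be >= 1")
        if self.ref_base not in _VALID_BASES:
            raise ValueError(f"{self.locus_id}: invalid ref base {self.ref_base!r}")
        for alt in self.alt_bases:
            if alt not in _VALID_BASES:
                raise ValueError(f"{self.locus_id}: invalid alt base {alt!r}")
            if alt == self.ref_base:
                raise ValueError(f"{self.locus_id}: alt base equals ref base {alt!r}")
        change = parse_codon_notation(self.codon_notation)
        if change.ref_base != self.ref_base or set(change.alt_bases) != set(self.alt_bases):
            raise ValueError(
                f"{self.locus_id}: codon notation {self.codon_notation!r} is "
                f"inconsistent with ref={self.ref_base} alts={self.alt_bases}"
            )


@dataclass(frozen=True)
class ContextWindow:
    """A nucleotide window centred (usually) on a hotspot site.

    ``offset_of_site`` is the 0-based index of the mutated base within
    ``sequence``.  Windows truncated at contig ends may be shorter than
    ``2 * window_half_width + 1`` but must still index the site.
    """

    locus_id: str
    sequence: str
    offset_of_site: int
    window_half_width: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.locus_id}: empty context window")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{self.locus_id}: window contains non-ACGTN characters")
        if not 0 <= self.offset_of_site < len(seq):
            raise ValueError(f"{self.locus_id}: offset_of_site outside sequence")
        if len(seq) > 2 * self.window_half_width + 1:
            raise ValueError(f"{self.locus_id}: window longer than 2*half_width+1")


_SIDE_RE = re.compile(r"^[ACGTacgt]{3}(?:/[acgt])*$")


def _parse_side(side: str, notation: str) -> tuple[str, int, str]:
    """Return (uppercase codon, lowercase index, extra alt letters)."""
    if not _SIDE_RE.match(side):
        raise CodonNotationError(
            f"malformed codon notation {notation!r}: side {side!r} is not a "
            "3-base codon with optional /x alternates"
        )
    codon, _, extra = side.partition("/")
    lower_positions = [i for i, c in enumerate(codon) if c.islower()]
    if len(lower_positions) != 1:
        raise CodonNotationError(
            f"malformed codon notation {notation!r}: side {side!r} must mark "
            "exactly one base lowercase"
        )
    extras = [c for c in extra.split("/") if c] if extra else []
    return codon.upper(), lower_positions[0], "".join(e.upper() for e in extras)


def parse_codon_notation(notation: str) -> CodonChange:
    """Parse a codon-change string such as ``"tTC>cTC"`` or ``"TGg>TGt/c"``.

    The lowercase letter on each side marks the mutated base; a trailing
    ``/x`` on the right side declares an additional alternate at the same
    position (``TGg>TGt/c`` means G>T and G>C at codon offset 2).

    Returns a :class:`CodonChange`; raises :class:`CodonNotationError` for a
    missing ``>``, sides that are not 3-base codons, zero or multiple
    lowercase positions, sides differing away from the marked base, or an
    identity change.
    """
    if notation.count(">") != 1:
        raise CodonNotationError(f"malformed codon notation {notation!r}: expected one '>'")
    left, right = notation.split(">")
    wt_codon, wt_off, wt_extra = _parse_side(left, notation)
    if wt_extra:
        raise CodonNotationError(
            f"malformed codon notation {notation!r}: alternates only allowed on the right side"
        )
    mut_codon, mut_off, extras = _parse_side(right, notation)
    if wt_off != mut_off:
        raise CodonNotationError(
            f"malformed codon notation {notation!r}: lowercase positions differ between sides"
        )
    for i in range(3):
        if i != wt_off and wt_codon[i] != mut_codon[i]:
            raise CodonNotationError(
                f"malformed codon notation {notation!r}: sides differ away from the marked base"
            )
    ref = wt_codon[wt_off]
    alts = mut_codon[wt_off] + extras
    if ref in alts:
        raise CodonNotationError(
            f"malformed codon notation {notation!r}: no change at the marked base"
        )
    if len(set(alts)) != len(alts):
        raise CodonNotationError(f"malformed codon notation {notation!r}: duplicate alternates")
    return CodonChange(ref_base=ref, alt_bases=alts, codon_offset=wt_off, wt_codon=wt_codon)


def format_codon_notation(change: CodonChange) -> str:
    """Reconstruct the notation string from a parse (inverse of
    :func:`parse_codon_notation`)."""
    off = change.codon_offset
    left = "".join(
        c.lower() if i == off else c for i, c in enumerate(change.wt_codon)
    )
    first, *rest = change.alt_bases
    right_codon = "".join(
        (first.lower() if i == off else c) for i, c in enumerate(change.wt_codon)
    )
    right = right_codon + "".join(f"/{a.lower()}" for a in rest)
    return f"{left}>{right}"


def gc_content(window: ContextWindow) -> float:
    """G+C fraction of the window in [0, 1].

    N bases are excluded from both numerator and denominator (windows may
    cross masked sequence).  Raises :class:`UndefinedContentError` for an
    all-N window.
    """
    seq = window.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise UndefinedContentError(f"{window.locus_id}: GC content undefined for all-N window")
    return (seq.count("G") + seq.count("C")) / acgt


def repeat_features(window: ContextWindow) -> RepeatFeatures:
    """Longest homopolymer run and longest tandem dinucleotide repeat.

    The dinucleotide count is in whole units; a homopolymer of length 2k is
    also a degenerate dinucleotide repeat of k units (``TTTT`` -> (4, 2)).
    """
    seq = window.sequence
    max_homo = 1
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        max_homo = max(max_homo, run)
    max_di = 1 if len(seq) >= 2 else 0
    for i in range(len(seq) - 1):
        unit = seq[i : i + 2]
        k = 1
        while seq[i + 2 * k : i + 2 * k + 2] == unit:
            k += 1
        max_di = max(max_di, k)
    return RepeatFeatures(max_homo, max_di)


def default_loci_path() -> Path:
    return Path(str(resources.files("arfidelity").joinpath("data/loci.yaml")))


def default_context_fasta_path() -> Path:
    return Path(str(resources.files("arfidelity").joinpath("data/synthetic_context_windows.fasta")))


def load_loci(path: str | Path | None = None) -> list[LocusSpec]:
    """Load hotspot locus declarations from YAML (packaged defaults if no
    path given)."""
    path = Path(path) if path is not None else default_loci_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    loci = []
    for entry in doc["loci"]:
        loci.append(
            LocusSpec(
                gene=entry["gene"],
                locus_id=entry["locus_id"],
                chrom=entry["chrom"],
                position=int(entry["position"]),
                ref_base=entry["ref_base"].upper(),
                alt_bases=tuple(a.upper() for a in entry["alt_bases"]),
                codon_notation=entry["codon_notation"],
                orientation=entry.get("orientation", "+"),
            )
        )
    return loci


def load_context_windows(
    loci: Iterable[LocusSpec],
    fasta_path: str | Path | None = None,
    half_width: int = 20,
) -> dict[str, ContextWindow]:
    """Extract a context window around each locus from a FASTA file.

    Windows are clipped at contig ends; the site offset is adjusted so it
    still indexes the mutated base.  The packaged default FASTA holds
    synthetic illustrative windows (the true genomic windows are not part of
    this package's fixtures).
    """
    fasta_path = Path(fasta_path) if fasta_path is not None else default_context_fasta_path()
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    windows: dict[str, ContextWindow] = {}
    for locus in loci:
        if locus.chrom not in fasta:
            raise KeyError(f"{locus.locus_id}: contig {locus.chrom!r} not in {fasta_path}")
        contig = fasta[locus.chrom]
        site0 = locus.position - 1  # 1-based -> 0-based
        start = max(0, site0 - half_width)
        end = min(len(contig), site0 + half_width + 1)
        seq = str(contig[start:end])
        windows[locus.locus_id] = ContextWindow(
            locus_id=locus.locus_id,
            sequence=seq,
            offset_of_site=site0 - start,
            window_half_width=half_width,
        )
    return windows
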