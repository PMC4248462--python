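"""Text formats: samtools-style mpileup, BEAGLE genotype probabilities,
SAF tables and region strings.

No statistics live here. All coordinates are 1-based inclusive; base
qualities are phred+33 encoded on disk and plain integer phred in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np

VALID_BASES = frozenset("ACGT")

WHOLE_CHROM = 2**63 - 1  # sentinel end for "whole chromosome" regions


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class PileupSite:
    """One genomic site with per-individual observed bases and qualities.

    ``reads[i]`` is the list of ``(base, phred_quality)`` pairs for
    individual ``i``; an individual with no coverage has an empty list and
    is never omitted, so ``len(reads)`` is always the sample size.
    """

    chrom: str
    pos: int
    ref_base: str
    reads: list[list[tuple[str, int]]]
    anc_base: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class BeagleSiteGP:
    """Per-individual genotype-probability triples for one marker.

    Triples are ordered (major homozygote, heterozygote, minor homozygote)
    and each sums to one.
    """

    marker: str
    allele1: str
    allele2: str
    gp: list[tuple[float, float, float]]


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def parse_region(text: str) -> Region:
    """Parse ``chrom[:start-end]``; a bare chromosome means the whole of it."""
    if ":" not in text:
        if not text:
            raise FormatError("empty region string")
        return Region(text, 1, WHOLE_CHROM)
    chrom, _, span = text.partition(":")
    try:
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed region {text!r}") from exc
    if start > end:
        raise FormatError(f"region start > end in {text!r}")
    return Region(chrom, start, end)


# mpileup base-column symbols that consume one character of the quality string
_QUAL_CONSUMING = frozenset(".,ACGTNacgtn*<>")


def _parse_base_column(bases: str, quals: str, ref: str, min_baseQ: int,
                       line_no: int) -> list[tuple[str, int]]:
    """Expand one individual's mpileup base string against its quality string.

    Handles the full grammar: '.'/',' are the reference base, '^X' starts a
    read segment (X is a mapping quality, consumed), '$' ends one, '+n'/'-n'
    introduce an n-base indel sequence that is skipped, '*' is a deletion
    placeholder and 'N' an ambiguous call — both consume a quality and are
    dropped. Remaining symbols are uppercased; quality filtering applied.
    """
    out: list[tuple[str, int]] = []
    i = 0  # index into bases
    q = 0  # index into quals
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus the encoded mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormatError(f"line {line_no}: dangling '{c}' in base column")
            indel_len = int(bases[i + 1:j])
            i = j + indel_len
            continue
        if c not in _QUAL_CONSUMING:
            raise FormatError(f"line {line_no}: unexpected symbol {c!r} in base column")
        if q >= len(quals):
            raise FormatError(f"line {line_no}: more bases than quality characters")
        qual = ord(quals[q]) - 33
        q += 1
        i += 1
        if c in ".,":
            base = ref
        else:
            base = c.upper()
        if base in ("N", "*", "<", ">"):
            continue
        if qual >= min_baseQ and base in VALID_BASES:
            out.append((base, qual))
    if q != len(quals):
        raise FormatError(f"line {line_no}: {len(quals) - q} unused quality characters")
    return out


def read_mpileup(stream: Iterable[str], n_individuals: int, min_baseQ: int = 0,
                 min_mapQ: Optional[int] = None) -> Iterator[PileupSite]:
    """Iterate sites of a samtools mpileup text stream.

    ``min_mapQ`` is accepted for interface symmetry but inert: the 6-column
    text dialect carries no per-read mapping qualities (mapping-quality
    filtering belongs to the upstream pileup generator).
    """
    del min_mapQ  # text mpileup has no per-read mapQ column
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        expected = 3 + 3 * n_individuals
        if len(cols) != expected:
            raise FormatError(
                f"line {line_no}: expected {expected} columns for "
                f"{n_individuals} individuals, found {len(cols)}")
        chrom, pos_s, ref = cols[0], cols[1], cols[2].upper()
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise FormatError(f"line {line_no}: bad position {pos_s!r}") from exc
        reads: list[list[tuple[str, int]]] = []
        for ind in range(n_individuals):
            depth_s, bases, quals = cols[3 + 3 * ind: 6 + 3 * ind]
            if depth_s == "0" or bases == "*":
                reads.append([])
                continue
            try:
                depth = int(depth_s)
            except ValueError as exc:
                raise FormatError(f"line {line_no}: bad depth {depth_s!r}") from exc
            if depth != len(quals):
                raise FormatError(
                    f"line {line_no}: individual {ind}: depth {depth} does not "
                    f"match {len(quals)} quality characters")
            reads.append(_parse_base_column(bases, quals, ref, min_baseQ, line_no))
        yield PileupSite(chrom=chrom, pos=pos, ref_base=ref, reads=reads)


def write_mpileup(sites: Iterable[PileupSite], stream: TextIO) -> None:
    """Write sites in the 6-column-per-individual mpileup text dialect."""
    for site in sites:
        cols = [site.chrom, str(site.pos), site.ref_base]
        for ind_reads in site.reads:
            if not ind_reads:
                cols += ["0", "*", "*"]
                continue
            bases = "".join(
                "." if b == site.ref_base else b for b, _ in ind_reads)
            quals = "".join(chr(min(q, 93) + 33) for _, q in ind_reads)
            cols += [str(len(ind_reads)), bases, quals]
        stream.write("\t".join(cols) + "\n")


def read_beagle(stream: Iterable[str]) -> Iterator[BeagleSiteGP]:
    """Iterate records of a BEAGLE genotype-probability text file."""
    it = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        return
    n_cols = len(header.split())
    if n_cols < 6 or (n_cols - 3) % 3 != 0:
        raise FormatError(f"beagle header has {n_cols} columns; expected 3 + 3k")
    n_individuals = (n_cols - 3) // 3
    for line_no, line in enumerate(it, start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != n_cols:
            raise FormatError(
                f"line {line_no}: expected {n_individuals} probability triples, "
                f"found {(len(fields) - 3) / 3:g}")
        marker, a1, a2 = fields[:3]
        try:
            probs = [float(x) for x in fields[3:]]
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-numeric probability") from exc
        gp = [tuple(probs[3 * i: 3 * i + 3]) for i in range(n_individuals)]
        for i, triple in enumerate(gp):
            if not math.isclose(sum(triple), 1.0, abs_tol=1e-6):
                raise FormatError(
                    f"line {line_no}: triple for individual {i} sums to "
                    f"{sum(triple):.8f}, not 1")
        yield BeagleSiteGP(marker=marker, allele1=a1, allele2=a2, gp=gp)


def write_beagle(records: Iterable[BeagleSiteGP], stream: TextIO) -> None:
    records = list(records)
    if not records:
        stream.write("marker\tallele1\tallele2\n")
        return
    n = len(records[0].gp)
    header = ["marker", "allele1", "allele2"]
    for i in range(n):
        header += [f"Ind{i}"] * 3
    stream.write("\t".join(header) + "\n")
    for rec in records:
        cols = [rec.marker, rec.allele1, rec.allele2]
        for triple in rec.gp:
            cols += [f"{p:.6g}" for p in triple]
        stream.write("\t".join(cols) + "\n")


def write_saf(records: Iterable[tuple[str, int, Sequence[float]]],
              stream: TextIO) -> None:
    """Write per-site SAF log-likelihood vectors as TSV.

    Each record is ``(chrom, pos, logp)`` with ``len(logp) = 2n + 1``;
    values are written to 12 significant digits so a read/write round trip
    is value-identical at that precision.
    """
    records = iter(records)
    first = next(records, None)
    if first is None:
        stream.write("chrom\tpos\n")
        return
    k = len(first[2])
    stream.write("chrom\tpos\t" + "\t".join(f"logp{j}" for j in range(k)) + "\n")
    for chrom, pos, logp in [first, *records]:
        if len(logp) != k:
            raise FormatError(
                f"SAF row for {chrom}:{pos} has {len(logp)} values, expected {k}")
        stream.write(f"{chrom}\t{pos}\t"
                     + "\t".join(f"{v:.12g}" for v in logp) + "\n")


def read_saf(stream: Iterable[str]) -> Iterator[tuple[str, int, np.ndarray]]:
    it = iter(stream)
    try:
        header = next(it)
    except StopIteration:
        raise FormatError("empty SAF file (missing header)")
    n_cols = len(header.split())
    for line_no, line in enumerate(it, start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != n_cols:
            raise FormatError(
                f"line {line_no}: SAF row has {len(fields)} columns, "
                f"header declares {n_cols}")
        try:
            logp = np.array([float(x) for x in fields[2:]])
        except ValueError as exc:
            raise FormatError(f"line {line_no}: non-numeric SAF value") from exc
        yield fields[0], int(fields[1]), logp
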