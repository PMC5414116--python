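"""Genomic domain types, interval arithmetic and FASTA/BED/VCF I/O.

All internal coordinates are 0-based half-open; conversion to the 1-based
VCF convention happens only at the I/O boundary.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomicInterval",
    "IntervalSet",
    "ReferenceGenome",
    "Variant",
    "VariantKind",
    "merge",
    "intersect",
    "subtract",
    "find_cpg_sites",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_vcf",
    "write_vcf",
]

_VALID_BASES = frozenset("ACGTN")
_ALLELE_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Inputs are well-formed but mutually inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region [start, end) on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A collection of genomic intervals, stored sorted per chromosome.

    Records may overlap as stored (as read from a BED file); :meth:`merge`
    returns the minimal non-overlapping cover.  Membership queries operate
    on the merged representation.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._ivals: Dict[str, np.ndarray] = {}
        for chrom in sorted(per_chrom):
            arr = np.array(sorted(per_chrom[chrom]), dtype=np.int64)
            self._ivals[chrom] = arr.reshape(-1, 2)
        self._merged: Optional[Dict[str, np.ndarray]] = None

    @classmethod
    def _from_arrays(cls, arrays: Dict[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._ivals = {c: a for c, a in sorted(arrays.items()) if len(a)}
        obj._merged = None
        return obj

    @property
    def chroms(self) -> List[str]:
        return list(self._ivals)

    def arrays(self) -> Dict[str, np.ndarray]:
        return self._ivals

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom, arr in self._ivals.items():
            for s, e in arr:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivals.values())

    def __bool__(self) -> bool:
        return len(self) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(
            np.array_equal(self._ivals[c], other._ivals[c]) for c in self._ivals
        )

    @property
    def total_bp(self) -> int:
        """Sum of stored interval lengths (footprint once merged)."""
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values())
        )

    def _merged_arrays(self) -> Dict[str, np.ndarray]:
        if self._merged is None:
            self._merged = {c: _merge_array(a) for c, a in self._ivals.items()}
        return self._merged

    def merge(self) -> "IntervalSet":
        """Minimal sorted non-overlapping cover of this set."""
        return IntervalSet._from_arrays(dict(self._merged_arrays()))

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 0-based position ``pos`` lies inside the footprint."""
        arr = self._merged_arrays().get(chrom)
        if arr is None or not len(arr):
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos < arr[i, 1]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`contains` for an array of 0-based positions."""
        arr = self._merged_arrays().get(chrom)
        out = np.zeros(len(positions), dtype=bool)
        if arr is None or not len(arr):
            return out
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        out[ok] = positions[ok] < arr[idx[ok], 1]
        return out


def _merge_array(arr: np.ndarray) -> np.ndarray:
    if len(arr) <= 1:
        return arr.copy()
    out: List[Tuple[int, int]] = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        s, e = int(s), int(e)
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def merge(s: IntervalSet) -> IntervalSet:
    return s.merge()


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-exact intersection of the footprints of ``a`` and ``b``."""
    out: Dict[str, np.ndarray] = {}
    am, bm = a._merged_arrays(), b._merged_arrays()
    for chrom in am:
        if chrom not in bm:
            continue
        x, y = am[chrom], bm[chrom]
        res: List[Tuple[int, int]] = []
        i = j = 0
        while i < len(x) and j < len(y):
            s = max(x[i, 0], y[j, 0])
            e = min(x[i, 1], y[j, 1])
            if s < e:
                res.append((int(s), int(e)))
            if x[i, 1] <= y[j, 1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = np.array(res, dtype=np.int64)
    return IntervalSet._from_arrays(out)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Footprint of ``a`` with every base covered by ``b`` removed."""
    out: Dict[str, np.ndarray] = {}
    am, bm = a._merged_arrays(), b._merged_arrays()
    for chrom, x in am.items():
        y = bm.get(chrom)
        if y is None or not len(y):
            if len(x):
                out[chrom] = x.copy()
            continue
        res: List[Tuple[int, int]] = []
        j = 0
        for s, e in x:
            s, e = int(s), int(e)
            cur = s
            while j < len(y) and y[j, 1] <= cur:
                j += 1
            k = j
            while k < len(y) and y[k, 0] < e:
                if cur < y[k, 0]:
                    res.append((cur, int(y[k, 0])))
                cur = max(cur, int(y[k, 1]))
                k += 1
            if cur < e:
                res.append((cur, e))
        if res:
            out[chrom] = np.array(res, dtype=np.int64)
    return IntervalSet._from_arrays(out)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Uppercase sequences over {A,C,G,T,N} with cached CpG positions."""

    def __init__(self, sequences: Dict[str, str]) -> None:
        self.sequences: Dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"sequence {chrom!r} contains invalid characters: {sorted(bad)}"
                )
            self.sequences[chrom] = seq
        self._cpg: Optional[Dict[str, np.ndarray]] = None

    @property
    def chroms(self) -> List[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    @property
    def cpg_positions(self) -> Dict[str, np.ndarray]:
        """Per-chromosome sorted 0-based offsets of the C of each CpG."""
        if self._cpg is None:
            self._cpg = find_cpg_sites(self)
        return self._cpg


def find_cpg_sites(genome: ReferenceGenome) -> Dict[str, np.ndarray]:
    """Locate every CG dinucleotide; positions with N never qualify."""
    out: Dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        is_c = arr[:-1] == ord("C")
        is_g = arr[1:] == ord("G")
        out[chrom] = np.flatnonzero(is_c & is_g).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    OTHER = "other"


@dataclass(frozen=True)
class Variant:
    """A somatic SNV or indel; ``pos`` is 1-based per the VCF convention."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - _ALLELE_BASES:
                raise ValueError(f"invalid allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantKind.SNV
        if len(self.alt) > len(self.ref) and self.alt.startswith(self.ref):
            return VariantKind.INSERTION
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return VariantKind.DELETION
        return VariantKind.OTHER

    @property
    def indel_size(self) -> int:
        """Signed length change (+1 for a 1-bp insertion, −1 for a deletion)."""
        return len(self.alt) - len(self.ref)

    @property
    def assigned_base(self) -> int:
        """0-based base used for interval assignment.

        SNVs map to their own base; indels to the first changed base
        (the base after the anchor).
        """
        if self.kind is VariantKind.SNV:
            return self.pos - 1
        if self.kind in (VariantKind.INSERTION, VariantKind.DELETION):
            return self.pos  # anchor (pos-1, 0-based) + 1
        return self.pos - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a multi-record FASTA into a :class:`ReferenceGenome`.

    Raises :class:`FormatError` naming the offending line for malformed
    headers or characters outside {A,C,G,T,N} (either case).
    """
    path = Path(path)
    sequences: Dict[str, List[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in sequences:
                    raise FormatError(f"{path}:{lineno}: duplicate record {name!r}")
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                bad = set(line.upper()) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}"
                    )
                sequences[current].append(line.upper())
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome({k: "".join(v) for k, v in sequences.items()})


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            seq = genome.sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, merge_records: bool = False) -> IntervalSet:
    """Read a BED3+ file (0-based half-open); extra columns are ignored."""
    path = Path(path)
    ivals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            ivals.append(GenomicInterval(chrom, start, end))
    s = IntervalSet(ivals)
    return s.merge() if merge_records else s


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED3, chromosomes lexicographic then start ascending."""
    with open(path, "w") as fh:
        for iv in intervals.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# VCF (site-only, via pysam)
# ---------------------------------------------------------------------------


def read_vcf(
    path: str | Path, genome: Optional[ReferenceGenome] = None
) -> List[Variant]:
    """Read a site-only VCF; multi-allelic records are split per ALT.

    With ``genome`` supplied, every REF allele is checked against the
    reference sequence; mismatches raise :class:`ValidationError` listing
    the offending records.
    """
    variants: List[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            for alt in rec.alts:
                variants.append(Variant(rec.chrom, rec.pos, rec.ref, str(alt)))
    if genome is not None:
        bad = []
        for v in variants:
            seq = genome.sequences.get(v.chrom)
            expected = (
                seq[v.pos - 1 : v.pos - 1 + len(v.ref)] if seq is not None else None
            )
            if expected != v.ref:
                bad.append(f"{v.chrom}:{v.pos} REF={v.ref} genome={expected}")
        if bad:
            raise ValidationError(
                "REF does not match reference genome: " + "; ".join(bad)
            )
    return variants


def write_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    genome: Optional[ReferenceGenome] = None,
) -> None:
    """Write a minimal site-only VCF with deterministic record order."""
    header = pysam.VariantHeader()
    if genome is not None:
        lengths = {c: len(s) for c, s in genome.sequences.items()}
    else:
        lengths = {}
        for v in variants:
            need = v.pos + len(v.ref)
            lengths[v.chrom] = max(lengths.get(v.chrom, 0), need)
    for chrom in sorted(lengths):
        header.contigs.add(chrom, length=lengths[chrom])
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            out.write(rec)
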