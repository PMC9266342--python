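"""Shared primitives: genomic regions, DNA encoding, exact k-mer indexing.

All internal coordinates are 0-based half-open.  User-facing reports and
parsed ``chrom:start-end`` strings are 1-based inclusive; conversion happens
only at the I/O boundary (`Region.from_1based` / `Region.to_1based`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Tuple

import numpy as np

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# A=0 C=1 G=2 T=3 for 2-bit packing
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T (case-insensitive) to uint8 codes 0..3.

    Any other character encodes to 255, which never matches a genome base.
    """
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class GenomeSequence:
    """An ordered collection of named chromosome sequences (A/C/G/T only)."""

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        self.chromosomes: Dict[str, str] = dict(chromosomes)
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequence) and self.chromosomes == other.chromosomes

    def names(self) -> List[str]:
        return list(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, region: "Region") -> str:
        return self.chromosomes[region.chrom][region.start : region.end]


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Region") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, pos: int) -> int:
        """0 if pos lies inside; otherwise the gap to the nearest edge."""
        if self.start <= pos < self.end:
            return 0
        return self.start - pos if pos < self.start else pos - (self.end - 1)

    def validate_in(self, genome: GenomeSequence) -> None:
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"region {self} exceeds chromosome length {genome.length(self.chrom)}"
            )

    @classmethod
    def from_1based(cls, spec: str) -> "Region":
        """Parse ``chrom:start-end`` with 1-based inclusive coordinates."""
        chrom, _, rng = spec.rpartition(":")
        if not chrom:
            raise ValueError(f"malformed region spec {spec!r}")
        lo, _, hi = rng.partition("-")
        return cls(chrom, int(lo.replace(",", "")) - 1, int(hi.replace(",", "")))

    def to_1based(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class KmerIndex:
    """Exact-match k-mer index over a genome, queried by binary search.

    Chromosomes are concatenated into one code array; k-mers spanning a
    chromosome boundary are excluded.  k is limited to 31 so a k-mer packs
    into a uint64.
    """

    def __init__(self, genome: GenomeSequence, k: int = 31):
        if not 1 <= k <= 31:
            raise ValueError("k must be in 1..31")
        self.k = k
        self.genome = genome
        self.names = genome.names()
        lengths = [genome.length(n) for n in self.names]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.codes = np.concatenate(
            [encode_seq(genome[n]) for n in self.names]
        ).astype(np.uint8)
        n = self.codes.size
        if n < k:
            self._sorted = np.empty(0, dtype=np.uint64)
            self._positions = np.empty(0, dtype=np.int64)
            return
        kmers = _rolling_codes(self.codes, k)
        valid = np.ones(n - k + 1, dtype=bool)
        for off in self.offsets[1:-1]:
            valid[max(0, off - k + 1) : off] = False
        positions = np.nonzero(valid)[0]
        kmers = kmers[positions]
        order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[order]
        self._positions = positions[order]

    def to_global(self, chrom: str, pos: int) -> int:
        return int(self.offsets[self.names.index(chrom)] + pos)

    def to_local(self, gpos: int) -> Tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.names[i], int(gpos - self.offsets[i])

    def chrom_bounds(self, gpos: int) -> Tuple[int, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return int(self.offsets[i]), int(self.offsets[i + 1])

    def lookup(self, kmer_code: int) -> np.ndarray:
        """Global positions at which this k-mer occurs."""
        lo = int(np.searchsorted(self._sorted, np.uint64(kmer_code), side="left"))
        hi = int(np.searchsorted(self._sorted, np.uint64(kmer_code), side="right"))
        return self._positions[lo:hi]


def _rolling_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a 2-bit code array into uint64."""
    n = codes.size
    out = np.zeros(n - k + 1, dtype=np.uint64)
    acc = np.zeros(n, dtype=np.uint64)
    acc[:] = codes
    mask = np.uint64((1 << (2 * k)) - 1)
    rolled = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        rolled = (rolled << np.uint64(2)) | acc
        if j < k - 1:
            rolled = rolled[:-1]
            acc = acc[1:]
    return (rolled & mask).astype(np.uint64)


def kmer_codes_of(seq_codes: np.ndarray, k: int) -> np.ndarray:
    """k-mer codes of an encoded read; positions containing non-ACGT are invalid
    (the 255 sentinel makes the packed code unmatchable only probabilistically,
    so callers should pre-screen reads for Ns if they matter)."""
    if seq_codes.size < k:
        return np.empty(0, dtype=np.uint64)
    return _rolling_codes(seq_codes.astype(np.uint64), k)
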