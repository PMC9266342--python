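"""Alignment records, SAM flag semantics, read QC, and a minimal built-in
read mapper.

The mapper does exact k-mer seeding with ungapped extension.  It is
deliberately ungapped: a read spanning an insertion junction either
soft-clips or goes unmapped, which is precisely the discordant signal the
mate-locating stage exploits.  Its SAM output is interchangeable with an
external aligner's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .core import GenomeSequence, KmerIndex, encode_seq, kmer_codes_of, revcomp
from .sim import ReadPair, ReadPairSet

UNMAPPED_SENTINEL = "*"

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

_FLAG_NAMES = [
    ("paired", FLAG_PAIRED), ("proper_pair", FLAG_PROPER),
    ("unmapped", FLAG_UNMAPPED), ("mate_unmapped", FLAG_MATE_UNMAPPED),
    ("reverse", FLAG_REVERSE), ("mate_reverse", FLAG_MATE_REVERSE),
    ("first_in_pair", FLAG_FIRST), ("second_in_pair", FLAG_SECOND),
    ("secondary", FLAG_SECONDARY), ("qc_fail", FLAG_QCFAIL),
    ("duplicate", FLAG_DUP), ("supplementary", FLAG_SUPPLEMENTARY),
]


def decode_flag(flag: int) -> Dict[str, bool]:
    """Decode a 12-bit SAM flag into named booleans."""
    return {name: bool(flag & bit) for name, bit in _FLAG_NAMES}


def encode_flag(bits: Dict[str, bool]) -> int:
    """Inverse of :func:`decode_flag`."""
    return sum(bit for name, bit in _FLAG_NAMES if bits.get(name, False))


@dataclass
class AlignmentRecord:
    """One SAM line's worth of alignment information.

    ``pos``/``mate_pos`` are 1-based as in SAM (0 when unmapped).  Unknown
    optional tags are preserved verbatim in ``tags``.
    """

    query_name: str
    flag: int
    ref_name: str = UNMAPPED_SENTINEL
    pos: int = 0
    mapq: int = 0
    cigar: str = "*"
    seq: str = "*"
    qual: str = "*"
    mate_ref: str = UNMAPPED_SENTINEL
    mate_pos: int = 0
    tlen: int = 0
    tags: List[Tuple[str, str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.flag < 4096:
            raise ValueError(f"malformed flag {self.flag}")
        if bool(self.flag & FLAG_UNMAPPED) != (self.ref_name == UNMAPPED_SENTINEL):
            # SAM permits placed-unmapped records (ref of the mate); we allow
            # an unmapped record to carry its mate's ref, but a mapped record
            # must have a real reference.
            if not (self.flag & FLAG_UNMAPPED):
                raise ValueError("mapped record lacks a reference name")

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    def aligned_blocks(self) -> List[Tuple[int, int]]:
        """0-based half-open reference spans consumed by M/=/X/D/N operations
        that cover the reference; soft-clips consume nothing."""
        if self.is_unmapped or self.cigar in ("*", ""):
            return []
        blocks: List[Tuple[int, int]] = []
        ref = self.pos - 1
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "M=X":
                blocks.append((ref, ref + n))
                ref += n
            elif ch in "DN":
                ref += n
            # I, S, H, P consume no reference
        return blocks


@dataclass
class QCReport:
    reads_in: int = 0
    reads_dropped_lowq: int = 0
    bases_trimmed: int = 0
    reads_out: int = 0


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def quality_filter_reads(
    pairs: ReadPairSet,
    min_frac_q20: float = 0.70,
    trim_q: int = 30,
    min_len: int = 50,
) -> Tuple[ReadPairSet, QCReport]:
    """Apply the read QC rules: drop a read when more than 30% of its bases
    fall below Q20, then trim the 3' end while the terminal base is below
    Q30.  A pair is dropped when either mate is dropped or trims below
    ``min_len``.
    """
    report = QCReport()
    kept: List[ReadPair] = []
    for p in pairs:
        report.reads_in += 2
        out_mates = []
        trimmed_here = 0
        for seq, qual in ((p.seq1, p.qual1), (p.seq2, p.qual2)):
            if len(seq) != len(qual):
                raise ValueError(f"pair {p.pair_id}: quality length mismatch")
            q = _phred(qual)
            if (q < 20).sum() > (1.0 - min_frac_q20) * q.size:
                break
            end = q.size
            while end > 0 and q[end - 1] < trim_q:
                end -= 1
            if end < min_len:
                break
            trimmed_here += q.size - end
            out_mates.append((seq[:end], qual[:end]))
        if len(out_mates) != 2:
            # the whole pair goes; the surviving mate counts as dropped too
            report.reads_dropped_lowq += 2
            continue
        report.bases_trimmed += trimmed_here
        (s1, q1), (s2, q2) = out_mates
        kept.append(ReadPair(p.pair_id, s1, q1, s2, q2, p.origin1, p.origin2))
    report.reads_out = 2 * len(kept)
    return ReadPairSet(kept), report


# ---------------------------------------------------------------------------
# built-in mapper


class _Candidate:
    __slots__ = ("gstart", "reverse", "mismatches", "aligned", "clip_left", "clip_right")

    def __init__(self, gstart, reverse, mismatches, aligned, clip_left, clip_right):
        self.gstart = gstart
        self.reverse = reverse
        self.mismatches = mismatches
        self.aligned = aligned
        self.clip_left = clip_left
        self.clip_right = clip_right

    @property
    def score(self) -> int:
        return (self.aligned - self.mismatches) - self.mismatches


def build_index(target: GenomeSequence, k: int = 31) -> KmerIndex:
    return KmerIndex(target, k)


_weight_cache: Dict[int, np.ndarray] = {}


def _seed_weights(k: int) -> np.ndarray:
    if k not in _weight_cache:
        _weight_cache[k] = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(
            np.uint64
        )
    return _weight_cache[k]


def _map_single(
    index: KmerIndex, seq: str, max_mismatch_frac: float
) -> Tuple[Optional[_Candidate], int]:
    """Best ungapped placement of one read; returns (best, n_competitive)."""
    k = index.k
    L = len(seq)
    if L < k:
        return None, 0
    fwd = encode_seq(seq)
    rev = encode_seq(revcomp(seq))
    offsets = sorted({0, (L - k) // 2, L - k})
    weights = _seed_weights(k)
    candidates: Dict[Tuple[int, bool], _Candidate] = {}
    for reverse, codes in ((False, fwd), (True, rev)):
        u64 = codes.astype(np.uint64)
        for off in offsets:
            code = int((u64[off : off + k] * weights).sum(dtype=np.uint64))
            for gpos in index.lookup(code).tolist():
                gstart = gpos - off
                key = (gstart, reverse)
                if key in candidates:
                    continue
                lo, hi = index.chrom_bounds(gpos)
                a = max(gstart, lo)
                b = min(gstart + L, hi)
                if b - a < k:
                    continue
                ref = index.codes[a:b]
                qry = codes[a - gstart : b - gstart]
                mism = int((ref != qry).sum())
                candidates[key] = _Candidate(
                    gstart, reverse, mism, b - a, a - gstart, gstart + L - b
                )
    viable = [
        c
        for c in candidates.values()
        if c.mismatches <= max_mismatch_frac * c.aligned
    ]
    if not viable:
        return None, 0
    # deterministic: best score, then lowest genomic position, forward first
    viable.sort(key=lambda c: (-c.score, c.gstart, c.reverse))
    best = viable[0]
    competitive = sum(
        1
        for c in viable
        if (c.gstart, c.reverse) != (best.gstart, best.reverse)
        and c.mismatches <= best.mismatches + 1
    )
    return best, competitive


def _record_from_candidate(
    index: KmerIndex, name: str, seq: str, qual: str, c: Optional[_Candidate], comp: int
) -> AlignmentRecord:
    if c is None:
        return AlignmentRecord(name, FLAG_UNMAPPED, seq=seq, qual=qual)
    chrom, pos = index.to_local(c.gstart + c.clip_left)
    flag = FLAG_REVERSE if c.reverse else 0
    cig = ""
    lc = c.clip_left if not c.reverse else c.clip_right
    rc = c.clip_right if not c.reverse else c.clip_left
    # CIGAR is in read orientation as stored in SAM (already reverse-complemented)
    if lc:
        cig += f"{lc}S"
    cig += f"{c.aligned}M"
    if rc:
        cig += f"{rc}S"
    out_seq = revcomp(seq) if c.reverse else seq
    out_qual = qual[::-1] if c.reverse else qual
    mapq = 60 if comp == 0 else 0
    return AlignmentRecord(
        name, flag, chrom, pos + 1, mapq, cig, out_seq, out_qual
    )


def map_reads(
    pairs: ReadPairSet,
    target: GenomeSequence,
    k: int = 31,
    max_mismatch_frac: float = 0.15,
    index: Optional[KmerIndex] = None,
    proper_max_insert: int = 2000,
) -> List[AlignmentRecord]:
    """Map read pairs to a target genome with exact k-mer seeding and
    ungapped extension.

    Unique best hits get MAPQ 60; placements with a competitor within one
    mismatch get MAPQ 0.  Unmapped mates are emitted as flag-correct records
    carrying the mapped mate's reference and position (SAM convention).
    """
    if target.total_length() == 0:
        raise ValueError("empty target")
    if index is None:
        index = KmerIndex(target, k)
    records: List[AlignmentRecord] = []
    for p in pairs:
        if k > min(len(p.seq1), len(p.seq2)):
            raise ValueError("k exceeds read length")
        c1, n1 = _map_single(index, p.seq1, max_mismatch_frac)
        c2, n2 = _map_single(index, p.seq2, max_mismatch_frac)
        r1 = _record_from_candidate(index, p.pair_id, p.seq1, p.qual1, c1, n1)
        r2 = _record_from_candidate(index, p.pair_id, p.seq2, p.qual2, c2, n2)
        r1.flag |= FLAG_PAIRED | FLAG_FIRST
        r2.flag |= FLAG_PAIRED | FLAG_SECOND
        _set_mate_fields(r1, r2, proper_max_insert)
        _set_mate_fields(r2, r1, proper_max_insert)
        records.extend((r1, r2))
    return records


def _set_mate_fields(rec: AlignmentRecord, mate: AlignmentRecord, max_insert: int) -> None:
    if mate.is_unmapped:
        rec.flag |= FLAG_MATE_UNMAPPED
        rec.mate_ref = rec.ref_name if not rec.is_unmapped else UNMAPPED_SENTINEL
        rec.mate_pos = rec.pos if not rec.is_unmapped else 0
    else:
        if mate.flag & FLAG_REVERSE:
            rec.flag |= FLAG_MATE_REVERSE
        rec.mate_ref = mate.ref_name
        rec.mate_pos = mate.pos
        if rec.is_unmapped:
            # placed-unmapped convention: carry the mate's coordinates
            rec.ref_name = mate.ref_name
            rec.pos = mate.pos
    if (
        not rec.is_unmapped
        and not mate.is_unmapped
        and rec.ref_name == mate.ref_name
        and bool(rec.flag & FLAG_REVERSE) != bool(mate.flag & FLAG_REVERSE)
        and abs(rec.pos - mate.pos) <= max_insert
    ):
        rec.flag |= FLAG_PROPER
        rec.tlen = mate.pos - rec.pos  # sign only; magnitude unused downstream


# ---------------------------------------------------------------------------
# SAM I/O (thin adapters over pysam text SAM)


def write_sam(
    records: Sequence[AlignmentRecord], genome: GenomeSequence, path: str
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in genome.names()],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.query_name
            a.flag = rec.flag
            a.reference_id = (
                fh.header.get_tid(rec.ref_name)
                if rec.ref_name != UNMAPPED_SENTINEL
                else -1
            )
            a.reference_start = rec.pos - 1 if rec.pos > 0 else -1
            a.mapping_quality = rec.mapq
            if rec.cigar != "*":
                a.cigarstring = rec.cigar
            if rec.seq != "*":
                a.query_sequence = rec.seq
                if rec.qual != "*":
                    a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            a.next_reference_id = (
                fh.header.get_tid(rec.mate_ref)
                if rec.mate_ref != UNMAPPED_SENTINEL
                else -1
            )
            a.next_reference_start = rec.mate_pos - 1 if rec.mate_pos > 0 else -1
            a.template_length = rec.tlen
            for tag, vtype, val in rec.tags:
                a.set_tag(tag, val, vtype)
            fh.write(a)


def read_sam(path: str) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """Read a text SAM file; returns (records, {chrom: length} from @SQ)."""
    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=True) as fh:
        lengths = {sq["SN"]: sq["LN"] for sq in fh.header.to_dict().get("SQ", [])}
        if not lengths:
            raise ValueError(f"{path}: SAM header lacks @SQ lines")
        for a in fh:
            ref = a.reference_name if a.reference_id >= 0 else UNMAPPED_SENTINEL
            if ref != UNMAPPED_SENTINEL and ref not in lengths:
                raise ValueError(f"{path}: record references unknown chromosome {ref}")
            qual = (
                pysam.qualities_to_qualitystring(a.query_qualities)
                if a.query_qualities is not None
                else "*"
            )
            records.append(
                AlignmentRecord(
                    query_name=a.query_name,
                    flag=a.flag,
                    ref_name=ref,
                    pos=a.reference_start + 1 if a.reference_start >= 0 else 0,
                    mapq=a.mapping_quality,
                    cigar=a.cigarstring or "*",
                    seq=a.query_sequence or "*",
                    qual=qual,
                    mate_ref=(
                        a.next_reference_name
                        if a.next_reference_id >= 0
                        else UNMAPPED_SENTINEL
                    ),
                    mate_pos=a.next_reference_start + 1
                    if a.next_reference_start >= 0
                    else 0,
                    tlen=a.template_length,
                    tags=[(t, _tag_type(v), v) for t, v in a.get_tags()],
                )
            )
    return records, lengths


def _tag_type(val: object) -> str:
    if isinstance(val, int):
        return "i"
    if isinstance(val, float):
        return "f"
    return "Z"
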