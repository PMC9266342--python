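"""Localization of translocated-cluster recipient loci.

Two independent evidence tracks are combined:

* discordant mates — reads that fail to map against the donor-cluster
  sequence while their mate maps to it are realigned to the whole genome;
  after MAPQ filtering their depth, normalized by each chromosome's average
  total-coverage depth, piles up in the flanks of every insertion site;
* junction contigs — assembled sequences matching partly the donor cluster
  and partly a distant genomic locus pinpoint the insertion coordinate at
  base resolution.

reconcile() labels each locus by its evidence tier (confirmed / depth-only /
junction-only) rather than deciding among depth-only candidates: depth
evidence without a junction contig is suggestive, not positional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GenomeSequence, KmerIndex, Region, encode_seq, revcomp
from .seqio_align import (
    FLAG_FIRST,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_UNMAPPED,
    AlignmentRecord,
)
from .sim import ReadPair, ReadPairSet

# samtools-style masks: keep -f 5, drop -F 77 and -F 141
KEEP_MASK = FLAG_PAIRED | FLAG_UNMAPPED  # 5
DROP_MASK_1 = 77  # paired + both-unmapped + first in pair
DROP_MASK_2 = 141  # paired + both-unmapped + second in pair


@dataclass
class CandidateRegion:
    region: Region
    supporting_reads: int
    mean_norm_depth: float
    passes_length_filter: bool


@dataclass
class JunctionCall:
    contig_id: str
    contig_breakpoint: int  # 0-based offset in contig where the junction lies
    cluster_side: Region  # matched span within the donor
    genome_side: Region  # matched span outside the donor
    orientation: str  # "same" | "opposite"
    insertion_site: int  # inferred 0-based insertion coordinate on genome_side.chrom


def keep_discordant(flag: int) -> bool:
    """The samtools predicate ``-f 5 -F 77 -F 141``: paired and itself
    unmapped, but not with an unmapped mate."""
    return (
        (flag & KEEP_MASK) == KEEP_MASK
        and (flag & DROP_MASK_1) != DROP_MASK_1
        and (flag & DROP_MASK_2) != DROP_MASK_2
    )


def select_discordant_mates(records: Sequence[AlignmentRecord]) -> ReadPairSet:
    """From donor-only alignments, pull the unmapped reads whose mates
    mapped, as single-end reads ready for whole-genome realignment."""
    singles: List[ReadPair] = []
    for rec in records:
        if not keep_discordant(rec.flag):
            continue
        mate_tag = "1" if rec.flag & FLAG_FIRST else "2"
        # packaged as a degenerate pair (mate 2 unused) to reuse ReadPairSet
        singles.append(
            ReadPair(
                f"{rec.query_name}/{mate_tag}",
                rec.seq,
                rec.qual if rec.qual != "*" else "I" * len(rec.seq),
                rec.seq,
                rec.qual if rec.qual != "*" else "I" * len(rec.seq),
                ("", -1, "+"),
                ("", -1, "-"),
            )
        )
    return ReadPairSet(singles)


def realign_single_ended(
    mates: ReadPairSet,
    genome: GenomeSequence,
    k: int = 31,
    index: Optional[KmerIndex] = None,
) -> List[AlignmentRecord]:
    """Map each selected mate as a single-end read against the whole genome."""
    from .seqio_align import _map_single, _record_from_candidate

    if index is None:
        index = KmerIndex(genome, k)
    out: List[AlignmentRecord] = []
    for p in mates:
        c, comp = _map_single(index, p.seq1, 0.15)
        out.append(_record_from_candidate(index, p.pair_id, p.seq1, p.qual1, c, comp))
    return out


def locate_recipients(
    mate_alignments: Sequence[AlignmentRecord],
    genome: GenomeSequence,
    donor: Region,
    chrom_mean_depth: Mapping[str, float],
    min_mapq: int = 30,
    min_len: int = 100,
    min_norm_depth: float = 0.25,
    gap_tol: int = 500,
) -> List[CandidateRegion]:
    """Turn realigned discordant-mate depth into candidate insertion regions.

    Mate depth is normalized per chromosome by the average total-coverage
    depth (``chrom_mean_depth``); runs of positions at or above
    ``min_norm_depth`` separated by gaps of at most ``gap_tol`` (one insert
    length) are merged; regions within one insert of the donor are
    self-hits of the original copy and are suppressed.
    """
    donor.validate_in(genome)
    depth: Dict[str, np.ndarray] = {
        c: np.zeros(genome.length(c), dtype=np.int64) for c in genome.names()
    }
    spans: List[Tuple[str, int, int]] = []
    for rec in mate_alignments:
        if rec.is_unmapped or rec.mapq < min_mapq:
            continue
        for start, end in rec.aligned_blocks():
            depth[rec.ref_name][start:end] += 1
            spans.append((rec.ref_name, start, end))
    donor_pad = Region(
        donor.chrom,
        max(0, donor.start - gap_tol),
        min(genome.length(donor.chrom), donor.end + gap_tol),
    )
    candidates: List[CandidateRegion] = []
    for chrom in genome.names():
        avg = chrom_mean_depth.get(chrom, 0.0)
        if avg <= 0:
            continue
        norm = depth[chrom] / avg
        hot = norm >= min_norm_depth
        for start, end in _merge_runs(hot, gap_tol):
            region = Region(chrom, start, end)
            if region.overlaps(donor_pad):
                continue
            support = sum(
                1 for c, s, e in spans if c == chrom and s < end and e > start
            )
            candidates.append(
                CandidateRegion(
                    region,
                    support,
                    float(norm[start:end].mean()),
                    len(region) > min_len,
                )
            )
    candidates.sort(key=lambda c: (-c.supporting_reads, c.region.chrom, c.region.start))
    return candidates


def _merge_runs(mask: np.ndarray, gap_tol: int) -> List[Tuple[int, int]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    runs: List[Tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:].tolist():
        if i - prev > gap_tol:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


# ---------------------------------------------------------------------------
# junction contigs


def _longest_exact_match(
    contig_codes: np.ndarray, index: KmerIndex
) -> Optional[Tuple[int, int, int]]:
    """Longest exact match of the contig against the indexed genome.

    Returns (contig_start, genome_start, length) or None.  Seeds every k-th
    k-mer plus the final one and extends each hit maximally in both
    directions.
    """
    k = index.k
    n = contig_codes.size
    if n < k:
        return None
    from .seqio_align import _seed_weights

    weights = _seed_weights(k)
    u64 = contig_codes.astype(np.uint64)
    best: Optional[Tuple[int, int, int]] = None
    offsets = list(range(0, n - k + 1, k)) + [n - k]
    seen: set = set()
    for off in offsets:
        code = int((u64[off : off + k] * weights).sum(dtype=np.uint64))
        for gpos in index.lookup(code).tolist():
            lo, hi = index.chrom_bounds(gpos)
            # extend left
            ci, gi = off, gpos
            while ci > 0 and gi > lo and contig_codes[ci - 1] == index.codes[gi - 1]:
                ci -= 1
                gi -= 1
            # extend right
            cj, gj = off + k, gpos + k
            while cj < n and gj < hi and contig_codes[cj] == index.codes[gj]:
                cj += 1
                gj += 1
            key = (ci, gi)
            if key in seen:
                continue
            seen.add(key)
            length = cj - ci
            if best is None or length > best[2] or (
                length == best[2] and (ci, gi) < (best[0], best[1])
            ):
                best = (ci, gi, length)
    return best


def scan_junction_contigs(
    contigs: Mapping[str, str],
    donor_seq: str,
    genome: GenomeSequence,
    min_anchor: int = 100,
    max_gap: int = 10,
    k: int = 31,
    genome_index: Optional[KmerIndex] = None,
    donor_region: Optional[Region] = None,
) -> List[JunctionCall]:
    """Find contigs anchored partly in the donor cluster and partly at a
    distant genomic locus; the boundary between the two anchors is the
    insertion coordinate.

    Matching is exact (both strands).  ``donor_region`` (the donor's own
    location in the genome) is used to reject genome-side anchors that are
    simply the original donor copy.
    """
    donor_genome = GenomeSequence({"donor": donor_seq})
    donor_index = KmerIndex(donor_genome, k)
    if genome_index is None:
        genome_index = KmerIndex(genome, k)
    calls: List[JunctionCall] = []
    for cid, seq in contigs.items():
        if len(seq) < 2 * min_anchor:
            continue
        call = None
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = encode_seq(s)
            dmatch = _longest_exact_match(codes, donor_index)
            if dmatch is None or dmatch[2] < min_anchor:
                continue
            gmatch = _best_outside_donor_match(
                codes, genome_index, donor_region, min_anchor, dmatch
            )
            if gmatch is None:
                continue
            d_ci, d_gi, d_len = dmatch
            g_ci, g_gi, g_len = gmatch
            # the two anchors must abut in contig coordinates
            if d_ci < g_ci:
                gap = g_ci - (d_ci + d_len)
                breakpoint_ = d_ci + d_len
                donor_first = True
            else:
                gap = d_ci - (g_ci + g_len)
                breakpoint_ = g_ci + g_len
                donor_first = False
            if abs(gap) > max_gap:
                continue
            g_chrom, g_start = genome_index.to_local(g_gi)
            genome_side = Region(g_chrom, g_start, g_start + g_len)
            # donor tail followed by flank: site = flank start;
            # flank followed by donor head: site = flank end
            site = genome_side.start if donor_first else genome_side.end
            call = JunctionCall(
                contig_id=cid,
                contig_breakpoint=breakpoint_,
                cluster_side=Region("donor", d_gi, d_gi + d_len),
                genome_side=genome_side,
                orientation="same" if strand == "+" else "opposite",
                insertion_site=site,
            )
            break
        if call is not None:
            calls.append(call)
    return calls


def _best_outside_donor_match(
    codes: np.ndarray,
    genome_index: KmerIndex,
    donor_region: Optional[Region],
    min_anchor: int,
    dmatch: Tuple[int, int, int],
) -> Optional[Tuple[int, int, int]]:
    """Longest exact genome match that lies outside the donor's own locus and
    outside the contig span already claimed by the donor anchor."""
    k = genome_index.k
    n = codes.size
    d_ci, _, d_len = dmatch
    from .seqio_align import _seed_weights

    weights = _seed_weights(k)
    u64 = codes.astype(np.uint64)
    offsets = list(range(0, n - k + 1, k)) + [n - k]
    best: Optional[Tuple[int, int, int]] = None
    for off in offsets:
        # skip seeds buried inside the donor anchor
        if off >= d_ci and off + k <= d_ci + d_len:
            continue
        code = int((u64[off : off + k] * weights).sum(dtype=np.uint64))
        for gpos in genome_index.lookup(code).tolist():
            lo, hi = genome_index.chrom_bounds(gpos)
            ci, gi = off, gpos
            while ci > 0 and gi > lo and codes[ci - 1] == genome_index.codes[gi - 1]:
                ci -= 1
                gi -= 1
            cj, gj = off + k, gpos + k
            while cj < n and gj < hi and codes[cj] == genome_index.codes[gj]:
                cj += 1
                gj += 1
            length = cj - ci
            if length < min_anchor:
                continue
            if donor_region is not None:
                chrom, start = genome_index.to_local(gi)
                match_region = Region(chrom, start, start + length)
                if match_region.overlaps(donor_region):
                    continue
            if best is None or length > best[2] or (
                length == best[2] and (ci, gi) < (best[0], best[1])
            ):
                best = (ci, gi, length)
    return best


# ---------------------------------------------------------------------------
# reconciliation


@dataclass
class InsertionReportEntry:
    chrom: str
    position_1based: Optional[int]  # junction coordinate when available
    tier: str  # confirmed | depth-only | junction-only
    candidate: Optional[CandidateRegion]
    junction: Optional[JunctionCall]


def reconcile(
    candidates: Sequence[CandidateRegion],
    junctions: Sequence[JunctionCall],
    tol: int = 500,
) -> List[InsertionReportEntry]:
    """Cross the depth-candidate and junction evidence tracks.

    A junction within ``tol`` bp of a passing candidate confirms it; the
    remaining passing candidates are depth-only; unmatched junctions are
    junction-only.  Evidence tiers are reported, not filtered.
    """
    passing = [c for c in candidates if c.passes_length_filter]
    matched_c: set = set()
    matched_j: set = set()
    entries: List[InsertionReportEntry] = []
    for jx, j in enumerate(junctions):
        for cx, c in enumerate(passing):
            if (
                c.region.chrom == j.genome_side.chrom
                and c.region.distance_to(j.insertion_site) <= tol
            ):
                entries.append(
                    InsertionReportEntry(
                        j.genome_side.chrom, j.insertion_site + 1, "confirmed", c, j
                    )
                )
                matched_c.add(cx)
                matched_j.add(jx)
                break
    for cx, c in enumerate(passing):
        if cx not in matched_c:
            entries.append(
                InsertionReportEntry(c.region.chrom, None, "depth-only", c, None)
            )
    for jx, j in enumerate(junctions):
        if jx not in matched_j:
            entries.append(
                InsertionReportEntry(
                    j.genome_side.chrom, j.insertion_site + 1, "junction-only", None, j
                )
            )
    return entries


def report_to_json(entries: Sequence[InsertionReportEntry], path: str) -> None:
    payload = []
    for e in entries:
        payload.append(
            {
                "chrom": e.chrom,
                "position": e.position_1based,
                "tier": e.tier,
                "candidate_region": e.candidate.region.to_1based() if e.candidate else None,
                "supporting_reads": e.candidate.supporting_reads if e.candidate else None,
                "mean_norm_depth": e.candidate.mean_norm_depth if e.candidate else None,
                "contig": e.junction.contig_id if e.junction else None,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def report_to_tsv(entries: Sequence[InsertionReportEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\ttier\tcandidate_region\tsupporting_reads\tcontig\n")
        for e in entries:
            fh.write(
                "\t".join(
                    [
                        e.chrom,
                        str(e.position_1based or ""),
                        e.tier,
                        e.candidate.region.to_1based() if e.candidate else "",
                        str(e.candidate.supporting_reads if e.candidate else ""),
                        e.junction.contig_id if e.junction else "",
                    ]
                )
                + "\n"
            )
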