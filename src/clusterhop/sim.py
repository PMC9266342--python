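"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (depth segmentation, discordant-mate
localization, CGH differential representation, expression correlation) is
exercised against data produced here, so each generator records what it
planted in a :class:`SimTruth` and is bit-reproducible for a fixed seed.

The default read-simulation parameters mirror a short-insert Illumina
paired-end library: 2 x 151 bp reads, tightly size-selected inserts of
500 +/- 25 bp (truncated normal, sd 12.5, hard-truncated at +/-2 sd).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GenomeSequence, Region, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_READ_LEN = 151
DEFAULT_INSERT_MEAN = 500
DEFAULT_INSERT_SD = 12.5


@dataclass
class SimTruth:
    """Planted ground truth for one simulated sample.

    ``insertion_sites`` are in *reference* coordinates (0-based); applying
    them right-to-left per chromosome keeps them valid during insertion.
    ``copy_count`` counts the donor plus every planted extra copy.
    """

    donor: Region
    insertion_sites: List[Tuple[str, int]] = field(default_factory=list)
    copy_count: int = 1
    planted_cnv_genes: List[Tuple[str, float]] = field(default_factory=list)
    planted_degs: List[Tuple[str, str, float]] = field(default_factory=list)
    planted_correlations: List[Tuple[Tuple[str, str], int]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        d = asdict(self)
        d["donor"] = {"chrom": self.donor.chrom, "start": self.donor.start, "end": self.donor.end}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


@dataclass
class ReadPair:
    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    origin1: Tuple[str, int, str]  # (chrom, 0-based pos, strand) in the source genome
    origin2: Tuple[str, int, str]


class ReadPairSet:
    """A list of simulated read pairs with their true origins."""

    def __init__(self, pairs: Sequence[ReadPair]):
        self.pairs: List[ReadPair] = list(pairs)
        for p in self.pairs:
            if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
                raise ValueError(f"pair {p.pair_id}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def make_reference(
    n_chroms: int, lengths: Sequence[int], gc: float, seed: int
) -> GenomeSequence:
    """Generate a random multi-chromosome genome with the given GC content.

    Bases are drawn i.i.d.; chromosomes are named chrI, chrII, ... in order.
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if len(lengths) != n_chroms:
        raise ValueError(f"expected {n_chroms} lengths, got {len(lengths)}")
    if any(l < 1000 for l in lengths):
        raise ValueError("chromosome lengths must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: Dict[str, str] = {}
    for i, length in enumerate(lengths):
        codes = rng.choice(4, size=length, p=p)
        chroms[_roman_name(i + 1)] = _BASES[codes].tobytes().decode("ascii")
    return GenomeSequence(chroms)


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def _roman_name(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "chr" + "".join(out)


def plant_cluster_duplication(
    ref: GenomeSequence,
    donor: Region,
    sites: Sequence[Tuple[str, int]],
    seed: int = 0,
) -> Tuple[GenomeSequence, SimTruth]:
    """Insert the donor subsequence verbatim at each site, producing a sample
    genome carrying extra cluster copies.

    Sites are reference coordinates; multiple insertions on one chromosome
    are applied right-to-left so earlier sites stay valid.  Sites inside the
    donor region are rejected (a copy nested in its own source would make
    the truth coordinates ambiguous).
    """
    donor.validate_in(ref)
    donor_seq = ref.fetch(donor)
    per_chrom: Dict[str, List[int]] = {}
    for chrom, pos in sites:
        if chrom not in ref:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos <= ref.length(chrom):
            raise ValueError(f"site {chrom}:{pos} outside chromosome")
        if chrom == donor.chrom and donor.start <= pos < donor.end:
            raise ValueError(f"insertion site {chrom}:{pos} falls inside the donor region")
        per_chrom.setdefault(chrom, []).append(pos)
    chroms = dict(ref.chromosomes)
    for chrom, positions in per_chrom.items():
        seq = chroms[chrom]
        for pos in sorted(positions, reverse=True):
            seq = seq[:pos] + donor_seq + seq[pos:]
        chroms[chrom] = seq
    truth = SimTruth(
        donor=donor,
        insertion_sites=[(c, p) for c, p in sites],
        copy_count=1 + len(sites),
    )
    return GenomeSequence(chroms), truth


def simulate_paired_reads(
    genome: GenomeSequence,
    mean_coverage: float,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = 0.0,
    seed: int = 0,
    base_quality: int = 37,
) -> ReadPairSet:
    """Simulate paired-end reads with truncated-normal insert sizes.

    Fragments fall uniformly within each chromosome; the pair count is
    Poisson with mean ``coverage * genome_size / (2 * read_len)``.  Mate 1 is
    the forward end of the fragment, mate 2 the reverse complement of the
    other end.  Substitution errors only; qualities are constant.
    """
    if not insert_mean > 2 * read_len:
        raise ValueError("insert_mean must exceed 2 * read_len")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    qual = chr(base_quality + 33)
    pairs: List[ReadPair] = []
    counter = 0
    for chrom in genome.names():
        seq = genome[chrom]
        length = len(seq)
        max_insert = int(insert_mean + 2 * insert_sd)
        if length < max_insert:
            continue
        n_pairs = rng.poisson(mean_coverage * length / (2 * read_len))
        inserts = _truncated_normal(rng, insert_mean, insert_sd, n_pairs)
        starts = rng.integers(0, length - inserts + 1)
        for start, insert in zip(starts.tolist(), inserts.tolist()):
            frag = seq[start : start + insert]
            s1 = frag[:read_len]
            s2 = revcomp(frag[insert - read_len :])
            if error_rate > 0:
                s1 = _mutate(rng, s1, error_rate)
                s2 = _mutate(rng, s2, error_rate)
            counter += 1
            pairs.append(
                ReadPair(
                    pair_id=f"sim:{counter}",
                    seq1=s1,
                    qual1=qual * read_len,
                    seq2=s2,
                    qual2=qual * read_len,
                    origin1=(chrom, start, "+"),
                    origin2=(chrom, start + insert - read_len, "-"),
                )
            )
    return ReadPairSet(pairs)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) hard-truncated at +/- 2 sd, rounded to int."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(16, n - filled))
        keep = draw[np.abs(draw - mean) <= 2 * sd]
        take = keep[: n - filled]
        out[filled : filled + take.size] = np.rint(take).astype(np.int64)
        filled += take.size
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # substitute with one of the three other bases
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        for i in hit.tolist():
            cur = idx[arr[i]]
            arr[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_cgh(
    genes: Sequence[str],
    strains: Sequence[str],
    effects: Mapping[Tuple[str, str], float],
    replicates: int = 12,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate CGH log2(test/reference) ratios with per-(gene, strain)
    planted effects and Gaussian replicate noise.

    Returns a long-format table with columns gene, strain, replicate,
    log2_ratio; unplanted (gene, strain) combinations have effect 0.

    The default of 12 values per (gene, strain) models probe-level
    measurement (several probes per gene times two technical replicates).
    An exact signed-rank test on n values has a two-sided p floor of
    2^(1-n), so BH-corrected calls at FDR 0.05 need roughly n >= 12 at
    realistic planted-to-null ratios; fewer values leave the test with no
    power after correction no matter how small the noise.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    for g, s in effects:
        if g not in set(genes) or s not in set(strains):
            raise ValueError(f"planted effect references unknown gene/strain ({g}, {s})")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        for strain in strains:
            mu = effects.get((gene, strain), 0.0)
            vals = mu + rng.normal(0.0, noise_sd, size=replicates)
            for r, v in enumerate(vals, start=1):
                rows.append((gene, strain, r, v))
    return pd.DataFrame(rows, columns=["gene", "strain", "replicate", "log2_ratio"])


def group_effects(
    genes_with_lfc: Mapping[str, float], strains: Iterable[str]
) -> Dict[Tuple[str, str], float]:
    """Expand per-gene effects over a strain group into the (gene, strain)
    mapping simulate_cgh expects."""
    strains = list(strains)
    return {(g, s): lfc for g, lfc in genes_with_lfc.items() for s in strains}


def simulate_expression(
    genes: Sequence[str],
    strains: Sequence[str],
    groups: Mapping[str, str],
    planted_degs: Sequence[Tuple[str, str, float]] = (),
    coexpr_blocks: Sequence[Tuple[Sequence[str], int]] = (),
    noise_sd: float = 0.3,
    factor_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-strain expression log2 fold changes versus a reference.

    ``planted_degs`` entries (gene, group_label, log2fc) add the offset to
    every strain of that group.  Each coexpression block shares a latent
    per-strain factor: in a positive block every gene loads +factor_sd, in a
    negative block the first gene loads + and the rest load -, which is the
    only sign pattern giving mutual anti-correlation for pairs.

    Returns a genes x strains DataFrame of log2FC values.
    """
    seen: set = set()
    for block, _sign in coexpr_blocks:
        for g in block:
            if g in seen:
                raise ValueError(f"gene {g!r} appears in more than one coexpression block")
            seen.add(g)
    for s in strains:
        if s not in groups:
            raise ValueError(f"strain {s!r} has no group label")
    rng = np.random.default_rng(seed)
    mat = rng.normal(0.0, noise_sd, size=(len(genes), len(strains)))
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(strains)}
    for gene, label, lfc in planted_degs:
        for s in strains:
            if groups[s] == label:
                mat[gi[gene], si[s]] += lfc
    for block, sign in coexpr_blocks:
        factor = rng.normal(0.0, 1.0, size=len(strains))
        for j, g in enumerate(block):
            load = factor_sd if (sign > 0 or j == 0) else -factor_sd
            mat[gi[g]] += load * factor
    return pd.DataFrame(mat, index=list(genes), columns=list(strains))


def extract_junction_contigs(
    sample: GenomeSequence,
    ref: GenomeSequence,
    truth: SimTruth,
    flank: int = 300,
) -> Dict[str, str]:
    """Cut junction-spanning windows out of the sample genome, emulating the
    near-error-free contigs a de novo assembler would produce across each
    insertion breakpoint.

    For every planted site two contigs are produced: one across the left
    junction (recipient flank + donor head) and one across the right
    junction (donor tail + recipient flank).
    """
    donor_len = len(truth.donor)
    contigs: Dict[str, str] = {}
    # shift reference sites into sample coordinates: insertions on the same
    # chromosome located left of a site each push it right by donor_len
    per_chrom: Dict[str, List[int]] = {}
    for chrom, pos in truth.insertion_sites:
        per_chrom.setdefault(chrom, []).append(pos)
    k = 0
    for chrom, positions in per_chrom.items():
        for pos in sorted(positions):
            shift = sum(donor_len for p in positions if p < pos)
            spos = pos + shift  # insertion start in sample coordinates
            seq = sample[chrom]
            left = seq[max(0, spos - flank) : spos + flank]
            right = seq[max(0, spos + donor_len - flank) : spos + donor_len + flank]
            k += 1
            contigs[f"junction_{k}_left"] = left
            contigs[f"junction_{k}_right"] = right
    return contigs


# ---------------------------------------------------------------------------
# plain-text writers


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq_pair(pairs: ReadPairSet, path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pair(path1: str, path2: str) -> ReadPairSet:
    from Bio import SeqIO

    pairs = []
    for r1, r2 in zip(SeqIO.parse(path1, "fastq"), SeqIO.parse(path2, "fastq")):
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        name = r1.id[:-2] if r1.id.endswith("/1") else r1.id
        pairs.append(
            ReadPair(name, str(r1.seq), q1, str(r2.seq), q2, ("", -1, "+"), ("", -1, "-"))
        )
    return ReadPairSet(pairs)


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
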