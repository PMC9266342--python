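"""End-to-end orchestration: QC -> map -> depth/CBS -> discordant-mate
localization -> junction reconciliation, plus the optional CGH, expression
and variant-merge arms when their tables are supplied.

Every stage logs record counts in and out (the filters are count-reducing,
and the counts are the audit trail), and every output embeds the config
hash and the seed, so re-running an identical config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .core import GenomeSequence, KmerIndex, Region
from .sim import ReadPairSet, read_fasta, read_fastq_pair
from .seqio_align import map_reads, quality_filter_reads
from .coverage_cnv import (
    call_duplication,
    cbs_segment,
    normalize_geometric,
    per_base_depth,
    window_log2,
)
from .mate_locator import (
    locate_recipients,
    realign_single_ended,
    reconcile,
    scan_junction_contigs,
    select_discordant_mates,
)
from .cgh_diffrep import cgh_calls, consistency_filter
from .expression_corr import call_degs, correlation_matrix, degs_to_frame

logger = logging.getLogger("clusterhop")


@dataclass
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    presence: Dict[str, bool]

    def __post_init__(self) -> None:
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid alleles {self.ref!r}/{self.alt!r}")


def resistant_specific_variants(
    sites: Sequence[VariantSite],
    resistant: Set[str],
    sensitive: Set[str],
    require_all_resistant: bool = True,
) -> List[VariantSite]:
    """Variants present only in resistant strains: in every resistant strain
    (or any, with ``require_all_resistant=False``) and in no sensitive one."""
    if not resistant or not sensitive:
        raise ValueError("both strain sets must be non-empty")
    out = []
    for site in sites:
        for strain in resistant | sensitive:
            if strain not in site.presence:
                raise ValueError(f"presence missing for strain {strain!r}")
        in_res = [site.presence[s] for s in sorted(resistant)]
        res_ok = all(in_res) if require_all_resistant else any(in_res)
        if res_ok and not any(site.presence[s] for s in sorted(sensitive)):
            out.append(site)
    return out


def read_minimal_vcf(path: str) -> List[VariantSite]:
    """Minimal VCF ingestion via pysam: CHROM/POS/REF/first ALT plus
    per-sample GT presence (any non-reference allele counts as present)."""
    import pysam

    sites: List[VariantSite] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if not rec.alts:
                continue
            presence = {}
            for s in samples:
                gt = rec.samples[s].get("GT")
                presence[s] = bool(gt) and any(a not in (0, None) for a in gt)
            sites.append(
                VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], presence)
            )
    return sites


@dataclass
class PipelineConfig:
    reference_fasta: str
    reads_fastq_1: str
    reads_fastq_2: str
    donor: str  # 1-based inclusive chrom:start-end
    contigs_fasta: Optional[str] = None
    cgh_tsv: Optional[str] = None
    expr_tsv: Dict[str, str] = field(default_factory=dict)  # condition -> path
    vcf: Optional[str] = None
    phenotypes: Dict[str, str] = field(default_factory=dict)  # strain -> label
    # stage parameters
    window: int = 1000
    alpha: float = 0.01
    nperm: int = 1000
    dup_log2: float = 0.3
    min_mapq: int = 30
    min_len: int = 100
    min_norm_depth: float = 0.25
    gap_tol: int = 500
    fdr: float = 0.05
    max_sensitive_cgh: int = 2
    max_sensitive_deg: int = 1
    qc_min_len: int = 50
    mapper_k: int = 31
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str) -> Dict:
    """Execute the full chain from files on disk; returns (and writes) the
    unified report."""
    os.makedirs(out_dir, exist_ok=True)
    genome = GenomeSequence(read_fasta(config.reference_fasta))
    donor = Region.from_1based(config.donor)
    donor.validate_in(genome)
    pairs = read_fastq_pair(config.reads_fastq_1, config.reads_fastq_2)
    contigs = read_fasta(config.contigs_fasta) if config.contigs_fasta else {}
    resistant = {s for s, l in config.phenotypes.items() if l == "resistant"}
    sensitive = {s for s, l in config.phenotypes.items() if l == "sensitive"}
    report = analyze(
        genome=genome,
        pairs=pairs,
        donor=donor,
        contigs=contigs,
        config=config,
        resistant=resistant,
        sensitive=sensitive,
        cgh=pd.read_csv(config.cgh_tsv, sep="\t") if config.cgh_tsv else None,
        expr={
            cond: pd.read_csv(p, sep="\t", index_col=0)
            for cond, p in config.expr_tsv.items()
        },
        variants=read_minimal_vcf(config.vcf) if config.vcf else None,
    )
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    _report_tsv(report, os.path.join(out_dir, "report.tsv"))
    return report


def analyze(
    genome: GenomeSequence,
    pairs: ReadPairSet,
    donor: Region,
    config: PipelineConfig,
    contigs: Optional[Dict[str, str]] = None,
    resistant: Optional[Set[str]] = None,
    sensitive: Optional[Set[str]] = None,
    cgh: Optional[pd.DataFrame] = None,
    expr: Optional[Dict[str, pd.DataFrame]] = None,
    variants: Optional[Sequence[VariantSite]] = None,
) -> Dict:
    """The in-memory pipeline: all sequence stages, plus the table-driven arms
    when inputs are given."""
    report: Dict = {
        "provenance": {
            "version": __version__,
            "config_hash": config.digest(),
            "seed": config.seed,
        },
        "stages": {},
    }

    # 1. read QC
    clean, qc = quality_filter_reads(pairs, min_len=config.qc_min_len)
    report["stages"]["qc"] = {
        "reads_in": qc.reads_in,
        "reads_dropped_lowq": qc.reads_dropped_lowq,
        "bases_trimmed": qc.bases_trimmed,
        "reads_out": qc.reads_out,
    }
    logger.info("qc: %d -> %d reads", qc.reads_in, qc.reads_out)

    # 2. map to the reference genome
    genome_index = KmerIndex(genome, config.mapper_k)
    records = map_reads(clean, genome, index=genome_index)
    mapped = sum(1 for r in records if not r.is_unmapped)
    report["stages"]["map"] = {"records": len(records), "mapped": mapped}
    logger.info("map: %d/%d mapped", mapped, len(records))

    # 3. depth -> normalize -> windows -> CBS -> duplication calls
    raw = per_base_depth(records, genome)
    norm = normalize_geometric(raw)
    wt = window_log2(norm, config.window)
    segments = cbs_segment(wt, config.alpha, config.nperm, seed=config.seed)
    dup_regions = call_duplication(segments, wt, dup_log2=config.dup_log2)
    report["duplicated_regions"] = [r.to_1based() for r in dup_regions]
    report["segments"] = [
        {
            "chrom": s.chrom,
            "start_window": s.start_window,
            "end_window": s.end_window,
            "mean_log2": round(s.mean, 4),
            "call": s.call,
        }
        for s in segments
    ]
    logger.info("cnv: %d segments, %d duplicated regions", len(segments), len(dup_regions))

    # 4. discordant mates against the donor-only target
    donor_genome = GenomeSequence({donor.chrom: genome.fetch(donor)})
    donor_records = map_reads(clean, donor_genome, index=KmerIndex(donor_genome, config.mapper_k))
    discordant = select_discordant_mates(donor_records)
    realigned = realign_single_ended(discordant, genome, index=genome_index)
    chrom_means = raw.chrom_means()
    candidates = locate_recipients(
        realigned,
        genome,
        donor,
        chrom_means,
        min_mapq=config.min_mapq,
        min_len=config.min_len,
        min_norm_depth=config.min_norm_depth,
        gap_tol=config.gap_tol,
    )
    report["stages"]["locate"] = {
        "discordant_mates": len(discordant),
        "candidates": len(candidates),
        "passing_candidates": sum(1 for c in candidates if c.passes_length_filter),
    }

    # 5. junction contigs + reconciliation
    junctions = (
        scan_junction_contigs(
            contigs,
            genome.fetch(donor),
            genome,
            genome_index=genome_index,
            donor_region=donor,
        )
        if contigs
        else []
    )
    entries = reconcile(candidates, junctions, tol=config.gap_tol)
    report["insertion_sites"] = [
        {
            "chrom": e.chrom,
            "position": e.position_1based,
            "tier": e.tier,
            "candidate_region": e.candidate.region.to_1based() if e.candidate else None,
            "supporting_reads": e.candidate.supporting_reads if e.candidate else None,
        }
        for e in entries
    ]
    logger.info(
        "locate: %d discordant mates, %d candidates, %d junctions",
        len(discordant),
        len(candidates),
        len(junctions),
    )

    # 6. optional table-driven arms
    if cgh is not None and resistant and sensitive:
        calls = cgh_calls(cgh, fdr=config.fdr)
        diffrep = consistency_filter(
            calls, resistant, sensitive, max_sensitive=config.max_sensitive_cgh
        )
        report["diffrep_genes"] = [
            {"gene": g.gene, "direction": g.direction, "n_sensitive": g.n_sensitive_concordant}
            for g in diffrep
        ]
    if expr and resistant and sensitive:
        report["degs"] = {}
        for cond, mat in expr.items():
            degs = call_degs(
                mat, resistant, sensitive, cond, max_sensitive=config.max_sensitive_deg
            )
            report["degs"][cond] = [
                {"gene": d.gene, "direction": d.direction}
                for d in degs
                if d.group_consistent
            ]
    if variants is not None and resistant and sensitive:
        spec = resistant_specific_variants(list(variants), resistant, sensitive)
        report["resistant_specific_variants"] = [
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt} for v in spec
        ]
    return report


def _report_tsv(report: Dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#config_hash\t%s\n" % report["provenance"]["config_hash"])
        fh.write("section\tchrom\tposition_or_region\ttier_or_call\n")
        for r in report.get("duplicated_regions", []):
            fh.write(f"duplicated_region\t{r.split(':')[0]}\t{r.split(':')[1]}\tduplicated\n")
        for e in report.get("insertion_sites", []):
            fh.write(
                f"insertion_site\t{e['chrom']}\t{e['position'] or e['candidate_region'] or ''}\t{e['tier']}\n"
            )
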