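"""The standard synthetic study scenario used by the examples, the
end-to-end tests and the acceptance script.

It emulates the configuration the method targets: a multi-chromosome genome
(5 x 600 kb) carrying a 4 kb gene cluster at the right end of the last
chromosome (the donor), with extra cluster copies inserted at interior loci
of two other chromosomes, sequenced at 30x with 2 x 151 bp pairs of insert
500 +/- 25 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .core import GenomeSequence, Region
from .sim import (
    ReadPairSet,
    SimTruth,
    extract_junction_contigs,
    make_reference,
    plant_cluster_duplication,
    simulate_paired_reads,
)

N_CHROMS = 5
CHROM_LEN = 600_000
DONOR_LEN = 4_000
GC = 0.38
COVERAGE = 30.0
READ_LEN = 151
INSERT_MEAN = 500.0
INSERT_SD = 12.5
ERROR_RATE = 0.005
INSERTION_SITES: List[Tuple[str, int]] = [("chrII", 250_000), ("chrIV", 400_000)]


@dataclass
class Scenario:
    reference: GenomeSequence
    sample: GenomeSequence
    donor: Region
    truth: SimTruth
    reads: ReadPairSet
    contigs: Dict[str, str]


def build_scenario(
    seed: int,
    n_sites: int = 2,
    coverage: float = COVERAGE,
    error_rate: float = ERROR_RATE,
) -> Scenario:
    """Build the full study scenario; ``n_sites=0`` gives the single-copy
    (sensitive-strain) null scenario."""
    ref = make_reference(N_CHROMS, [CHROM_LEN] * N_CHROMS, GC, seed=seed)
    donor_chrom = ref.names()[-1]
    donor = Region(donor_chrom, CHROM_LEN - DONOR_LEN, CHROM_LEN)
    sites = INSERTION_SITES[:n_sites]
    sample, truth = plant_cluster_duplication(ref, donor, sites, seed=seed)
    reads = simulate_paired_reads(
        sample,
        mean_coverage=coverage,
        read_len=READ_LEN,
        insert_mean=INSERT_MEAN,
        insert_sd=INSERT_SD,
        error_rate=error_rate,
        seed=seed + 1,
    )
    contigs = extract_junction_contigs(sample, ref, truth) if sites else {}
    return Scenario(ref, sample, donor, truth, reads, contigs)
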