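"""CGH differential representation: per-(gene, strain) Wilcoxon signed-rank
tests on replicate log2(test/reference) ratios, BH FDR across all tests, and
the resistant/sensitive consistency rule.

The signed-rank test is one-sample against 0 with the standard conventions:
zero differences dropped before ranking, ties sharing mid-ranks.  The exact
null (all 2^n sign assignments, with the actual mid-ranks) is computed by
dynamic programming for n <= 25; above that a normal approximation with
continuity correction and tie-corrected variance is used.  The null
distribution is symmetric about its center for any rank multiset, so the
two-sided p equals the symmetric tail mass P(|W - total/2| >= |w - total/2|).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 25


@lru_cache(maxsize=4096)
def _signed_rank_counts(scaled_ranks: Tuple[int, ...]) -> Tuple[np.ndarray, int]:
    """Null counts of W+ (sum of doubled mid-ranks of positive values) over
    all 2^n sign assignments, plus the grand total."""
    total = sum(scaled_ranks)
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts, total


def wilcoxon_gene_test(values: Sequence[float]) -> Tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test of replicate log-ratios
    against 0.  Returns (p, log2FC) with log2FC the plain mean of the
    replicates.  All-zero input is degenerate: p = 1, log2FC = 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate values")
    log2fc = float(x.mean())
    nz = x[x != 0]
    n = nz.size
    if n == 0:
        return 1.0, 0.0
    ranks = stats.rankdata(np.abs(nz))  # mid-ranks; multiples of 0.5
    scaled = np.rint(2 * ranks).astype(int)
    w = int(scaled[nz > 0].sum())
    total = int(scaled.sum())
    if n <= EXACT_MAX_N:
        counts, _ = _signed_rank_counts(tuple(sorted(scaled.tolist())))
        center = total / 2.0
        d = abs(w - center)
        idx = np.arange(counts.size)
        p = counts[np.abs(idx - center) >= d - 1e-9].sum() / (2.0**n)
        return float(min(1.0, p)), log2fc
    mean = total / 2.0
    var = float((scaled.astype(float) ** 2).sum()) / 4.0
    # w lives on the doubled-rank scale, so the standard continuity
    # correction of 0.5 rank units is 1.0 here
    d = abs(w - mean)
    z = max(0.0, d - 1.0) / np.sqrt(var)
    return float(min(1.0, 2 * stats.norm.sf(z))), log2fc


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CGHCall:
    gene: str
    strain: str
    log2fc: float
    p: float
    q: float
    status: str  # over | under | ns


def cgh_calls(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Per-(gene, strain) Wilcoxon calls from a long-format CGH table with
    columns gene, strain, replicate, log2_ratio; q-values are BH-adjusted
    across all (gene, strain) tests."""
    required = {"gene", "strain", "log2_ratio"}
    if not required <= set(table.columns):
        raise ValueError(f"CGH table must have columns {sorted(required)}")
    rows = []
    for (gene, strain), grp in table.groupby(["gene", "strain"], sort=True):
        p, lfc = wilcoxon_gene_test(grp["log2_ratio"].to_numpy())
        rows.append((gene, strain, lfc, p))
    calls = pd.DataFrame(rows, columns=["gene", "strain", "log2fc", "p"])
    calls["q"] = bh_fdr(calls["p"].to_numpy())
    sig = calls["q"] < fdr
    calls["status"] = np.where(
        sig & (calls["log2fc"] > 0),
        "over",
        np.where(sig & (calls["log2fc"] < 0), "under", "ns"),
    )
    return calls


@dataclass
class DiffRepGene:
    gene: str
    direction: str  # over | under
    n_resistant_called: int
    n_sensitive_concordant: int


def consistency_filter(
    calls: pd.DataFrame,
    resistant: Set[str],
    sensitive: Set[str],
    max_sensitive: int = 2,
    mode: str = "absolute",
    min_frac_discordant: float = 0.75,
) -> List[DiffRepGene]:
    """Retain genes called in the same direction in *every* resistant strain
    and concordant in at most ``max_sensitive`` sensitive strains.

    ``mode='fraction'`` instead requires strictly more than
    ``min_frac_discordant`` of the sensitive strains to be non-concordant.
    """
    if not resistant:
        raise ValueError("resistant strain set must be non-empty")
    strains = set(calls["strain"])
    missing = (set(resistant) | set(sensitive)) - strains
    if missing:
        raise ValueError(f"strains missing from calls: {sorted(missing)}")
    out: List[DiffRepGene] = []
    for gene, grp in calls.groupby("gene", sort=True):
        status = dict(zip(grp["strain"], grp["status"]))
        for direction in ("over", "under"):
            if not all(status.get(s) == direction for s in resistant):
                continue
            n_sens = sum(1 for s in sensitive if status.get(s) == direction)
            if mode == "absolute":
                ok = n_sens <= max_sensitive
            elif mode == "fraction":
                ok = bool(sensitive) and (
                    (len(sensitive) - n_sens) > min_frac_discordant * len(sensitive)
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if ok:
                out.append(DiffRepGene(str(gene), direction, len(resistant), n_sens))
    return out


def read_cgh_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotypes(path: str) -> Tuple[Set[str], Set[str]]:
    """Two-column TSV (strain, resistant|sensitive) -> (resistant, sensitive)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["strain", "phenotype"])
    groups: dict = {"resistant": set(), "sensitive": set()}
    for _, row in df.iterrows():
        ph = str(row["phenotype"]).strip().lower()
        if ph not in groups:
            raise ValueError(f"unknown phenotype {row['phenotype']!r}")
        groups[ph].add(str(row["strain"]))
    return groups["resistant"], groups["sensitive"]
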