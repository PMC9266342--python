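"""Expression analysis: per-strain DEG calls against a reference, Spearman
correlation structure among gene sets, and copy-number-versus-expression
correlation.

DEG calling is strain-wise: a gene is over (under) in a strain when its
log2FC versus the reference is >= +1 (<= -1), and group-consistent when
every resistant strain shares the direction while at most ``max_sensitive``
sensitive strains do.

Spearman rho is the Pearson correlation of mid-ranks.  For n <= 8 paired
observations the p-value is exact, by enumerating all n! rank permutations;
above that the usual t approximation is used.  Missing values (NaN) are
handled pairwise-complete; a pair with fewer than 4 complete observations,
or zero variance in either vector, is undefined and excluded from the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cgh_diffrep import bh_fdr

MIN_PAIRED_OBS = 4
EXACT_MAX_N = 8


@dataclass
class DEGCall:
    gene: str
    condition: str
    log2fc: Dict[str, float]  # per strain
    status: Dict[str, str]  # per strain: over | under | ns
    group_consistent: bool
    direction: Optional[str] = None  # over | under when group_consistent


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    rho: float
    p: float
    q: float = np.nan
    significant: bool = False


def _status(lfc: float) -> str:
    if lfc >= 1.0:
        return "over"
    if lfc <= -1.0:
        return "under"
    return "ns"


def call_degs(
    expr: pd.DataFrame,
    resistant: Set[str],
    sensitive: Set[str],
    condition: str,
    max_sensitive: int = 1,
) -> List[DEGCall]:
    """Per-strain DEG statuses from a genes x strains log2FC matrix, plus the
    every-resistant / max-``max_sensitive``-sensitive group-consistency rule."""
    missing = (set(resistant) | set(sensitive)) - set(expr.columns)
    if missing:
        raise ValueError(f"strains missing from expression matrix: {sorted(missing)}")
    calls: List[DEGCall] = []
    for gene in expr.index:
        lfc = {s: float(expr.at[gene, s]) for s in expr.columns}
        status = {s: _status(v) for s, v in lfc.items()}
        direction = None
        for d in ("over", "under"):
            if all(status[s] == d for s in resistant):
                n_sens = sum(1 for s in sensitive if status[s] == d)
                if n_sens <= max_sensitive:
                    direction = d
                break
        calls.append(
            DEGCall(str(gene), condition, lfc, status, direction is not None, direction)
        )
    return calls


def spearman_pair(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rho (mid-rank Pearson) with exact permutation p for n <= 8."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < MIN_PAIRED_OBS:
        raise ValueError(f"need >= {MIN_PAIRED_OBS} paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before calling spearman_pair")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= EXACT_MAX_N:
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
        obs = abs(rho)
        count = 0
        for perm in permutations(ry):
            r = float(np.dot(rx_c, perm)) / denom
            if abs(r) >= obs - 1e-12:
                count += 1
        return rho, count / factorial(n)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), df=n - 2))


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def correlation_matrix(
    expr: pd.DataFrame, genes: Sequence[str], fdr: float = 0.05
) -> List[CorrelationResult]:
    """Spearman correlations for all unordered gene pairs, BH FDR across the
    pair list.  Undefined pairs (too few complete observations or zero
    variance) are excluded from the FDR and reported with NaN rho."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    missing = set(genes) - set(expr.index)
    if missing:
        raise ValueError(f"genes missing from expression matrix: {sorted(missing)}")
    results: List[CorrelationResult] = []
    defined: List[int] = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            x, y = _pairwise_complete(
                expr.loc[ga].to_numpy(dtype=float), expr.loc[gb].to_numpy(dtype=float)
            )
            try:
                if x.size < MIN_PAIRED_OBS:
                    raise ValueError("too few observations")
                rho, p = spearman_pair(x, y)
                defined.append(len(results))
                results.append(CorrelationResult(ga, gb, rho, p))
            except ValueError:
                results.append(CorrelationResult(ga, gb, np.nan, np.nan))
    if defined:
        qs = bh_fdr([results[i].p for i in defined])
        for i, q in zip(defined, qs):
            results[i].q = float(q)
            results[i].significant = bool(q <= fdr)
    return results


def copy_expression_correlation(
    copy_numbers: pd.DataFrame,
    expr: pd.DataFrame,
    genes: Sequence[str],
    fdr: float = 0.05,
) -> List[CorrelationResult]:
    """Per gene, Spearman correlation between its per-strain copy-number
    proxy (windowed normalized depth over the gene) and its per-strain
    expression, BH-adjusted across genes.  Zero-variance copy vectors are
    undefined and excluded from the FDR."""
    strains = [s for s in expr.columns if s in copy_numbers.columns]
    if len(strains) < MIN_PAIRED_OBS:
        raise ValueError("too few strains shared between copy-number and expression")
    results: List[CorrelationResult] = []
    defined: List[int] = []
    for gene in genes:
        if gene not in expr.index or gene not in copy_numbers.index:
            raise ValueError(f"gene {gene!r} missing from an input matrix")
        cn = copy_numbers.loc[gene, strains].to_numpy(dtype=float)
        ex = expr.loc[gene, strains].to_numpy(dtype=float)
        cn, ex = _pairwise_complete(cn, ex)
        try:
            if cn.size < MIN_PAIRED_OBS:
                raise ValueError("too few observations")
            rho, p = spearman_pair(cn, ex)
            defined.append(len(results))
            results.append(CorrelationResult(str(gene), "copy_number", rho, p))
        except ValueError:
            results.append(CorrelationResult(str(gene), "copy_number", np.nan, np.nan))
    if defined:
        qs = bh_fdr([results[i].p for i in defined])
        for i, q in zip(defined, qs):
            results[i].q = float(q)
            results[i].significant = bool(q <= fdr)
    return results


def degs_to_frame(calls: Sequence[DEGCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        for strain, lfc in c.log2fc.items():
            rows.append(
                (c.gene, c.condition, strain, lfc, c.status[strain], c.group_consistent, c.direction or "")
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "condition", "strain", "log2fc", "status", "group_consistent", "direction"],
    )


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_a, r.gene_b, r.rho, r.p, r.q, r.significant) for r in results],
        columns=["gene_a", "gene_b", "rho", "p", "q", "significant"],
    )
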