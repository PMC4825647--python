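"""Hypergeometric over-representation analysis of gene lists.

For a list of n genes drawn from a universe of N genes, K of which carry a
functional term, the raw p-value for observing k annotated genes in the list
is the upper tail P(X >= k) of Hypergeometric(N, K, n).  Only
over-representation is tested.  The Bonferroni-corrected p-value multiplies
the raw p by the number of terms tested — by default the terms with at least
one gene in the list (switchable to all terms in the annotation table) — and
caps at 1.

List genes absent from the universe are dropped (with a logged count) before
testing, and n is the list size after that exclusion.  Reported alongside the
p-values are the two percentages used for plotting:
``percent_in_list = 100*k/n`` and ``percent_in_genome = 100*K/N``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import AnnotationTable

log = logging.getLogger(__name__)

RESULT_COLUMNS = (
    "term_id",
    "term_name",
    "k",
    "n",
    "K",
    "N",
    "percent_in_list",
    "percent_in_genome",
    "p_raw",
    "p_bonferroni",
)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k annotated genes observed in a size-n list, from a size-N universe
    containing K annotated genes.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"invalid universe: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def percent(k: int, n: int) -> float:
    """100*k/n at full precision."""
    if n <= 0:
        raise ValueError(f"denominator must be positive, got {n}")
    return 100.0 * k / n


def format_percent(x: float) -> str:
    """Display form: round half-even to 2 dp, then strip at most one trailing zero.

    Mirrors the mixed display conventions of percentage tables where 10.00
    prints as "10.0" while 7.45 keeps both decimals.  Full precision is what
    computations and tests use; this is presentation only.
    """
    s = f"{round(float(x), 2):.2f}"
    if s.endswith("0") and not s.endswith(".00"):
        s = s[:-1]
    elif s.endswith(".00"):
        s = s[:-1]
    return s


def enrich(
    gene_list,
    annotations: AnnotationTable,
    universe=None,
    family: str = "observed",
) -> pd.DataFrame:
    """Over-representation test of ``gene_list`` against an annotation table.

    ``universe`` defaults to the annotation table's universe (the set of
    annotated genes if none was declared); pass the set of genes on the
    array to use the array-as-universe convention.  ``family`` selects the
    Bonferroni multiplier: "observed" counts terms with k >= 1 in this list,
    "all" counts every term in the table.

    Returns one row per term with k >= 1, sorted by raw p ascending (ties by
    term id).
    """
    if family not in ("observed", "all"):
        raise ValueError(f"family must be 'observed' or 'all', got {family!r}")
    universe = frozenset(universe) if universe is not None else annotations.genes
    if not universe:
        raise ValueError("empty gene universe")
    genes = list(dict.fromkeys(gene_list))  # dedupe, keep order
    kept = [g for g in genes if g in universe]
    dropped = len(genes) - len(kept)
    if dropped:
        log.info("enrich: dropped %d list gene(s) outside the universe", dropped)
    n = len(kept)
    N = len(universe)
    kept_set = set(kept)

    term_names = annotations.term_names()
    rows = []
    n_terms_with_hit = 0
    for term, term_set in annotations.term_genes().items():
        in_universe = term_set & universe
        K = len(in_universe)
        k = len(in_universe & kept_set)
        if k == 0:
            continue
        n_terms_with_hit += 1
        rows.append(
            {
                "term_id": term,
                "term_name": term_names[term],
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "percent_in_list": percent(k, n),
                "percent_in_genome": percent(K, N),
                "p_raw": hypergeom_pvalue(k, K, n, N),
            }
        )
    multiplier = n_terms_with_hit if family == "observed" else len(annotations.terms)
    result = pd.DataFrame(rows, columns=list(RESULT_COLUMNS[:-1]))
    result["p_bonferroni"] = np.minimum(1.0, result["p_raw"] * max(multiplier, 1))
    result = result.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)
    return result[list(RESULT_COLUMNS)]


def report_percentages(results: pd.DataFrame) -> pd.DataFrame:
    """Two-column percent comparison per term, rounded for display.

    Numeric columns are rounded half-even to 2 decimal places; the ``*_display``
    columns apply :func:`format_percent`.  Full precision stays in ``results``.
    """
    report = results[["term_id", "term_name", "k", "n", "K", "N"]].copy()
    report["percent_in_list"] = results["percent_in_list"].map(lambda x: round(x, 2))
    report["percent_in_genome"] = results["percent_in_genome"].map(lambda x: round(x, 2))
    report["percent_in_list_display"] = results["percent_in_list"].map(format_percent)
    report["percent_in_genome_display"] = results["percent_in_genome"].map(format_percent)
    return report
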