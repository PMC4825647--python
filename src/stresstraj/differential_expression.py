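"""Per-timepoint expression ratios and the baseline differential-expression call.

Ratios: per gene and timepoint, the replicate-averaged linear mutant:wild-type
ratio ``2 ** mean_over_replicates(mutant_log2 - wildtype_log2)``, with the
channel → genotype mapping resolved per array through its dye-swap flag.

Baseline calls: an unpaired two-sample t-test (pooled variance by default,
Welch by flag) between the per-replicate normalized log2 values of the two
genotypes at the pre-stress timepoint, combined with a two-sided linear
fold-change rule: a gene is called "over" when fold >= fold_threshold and
p < alpha, "under" when fold <= 1/fold_threshold and p < alpha, "none"
otherwise.  p-values are raw (no multiple-testing correction).

Degenerate genes are handled by documented convention: zero variance in both
genotypes with equal means gives p = 1 (call "none"); zero variance with
unequal means gives p = 0 (the noiseless limit, where the call is decided by
the fold rule alone).  Genes floored in every array of both genotypes carry
no signal and are forced to "none" and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RatioTable

#: relative guard at the fold-threshold boundary
_FOLD_EPS = 1e-12


@dataclass
class DEThresholds:
    """Significance and fold-change cutoffs for the baseline call."""

    alpha: float = 0.05
    fold_threshold: float = 1.5

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fold_threshold < 1:
            raise ValueError(f"fold_threshold must be >= 1, got {self.fold_threshold}")


def _genotype_matrix(arrays, genotype: str) -> pd.DataFrame:
    """Genes x replicates matrix of normalized log2 values for one genotype."""
    first = arrays[0].genes
    for a in arrays[1:]:
        if not first.equals(a.genes):
            raise ValueError(
                f"arrays disagree on the gene set ({a.array_id} vs {arrays[0].array_id})"
            )
    return pd.DataFrame(
        {a.array_id: a.log2_for(genotype) for a in arrays}
    )


def compute_ratio_table(normalized_arrays, provenance: str = "") -> RatioTable:
    """Replicate-averaged linear mutant:wild-type ratio per gene per timepoint.

    Timepoint order follows first appearance in ``normalized_arrays``.
    """
    if not normalized_arrays:
        raise ValueError("no arrays given")
    timepoints = []
    for a in normalized_arrays:
        if a.timepoint not in timepoints:
            timepoints.append(a.timepoint)
    cols = {}
    for tp in timepoints:
        reps = [a for a in normalized_arrays if a.timepoint == tp]
        if not reps:
            raise ValueError(f"timepoint {tp!r} has no arrays")
        diffs = _genotype_matrix(reps, "mutant") - _genotype_matrix(reps, "wildtype")
        cols[tp] = np.exp2(diffs.mean(axis=1))
    ratios = pd.DataFrame(cols)[timepoints]
    ratios.index.name = "gene_id"
    return RatioTable(ratios=ratios, provenance=provenance)


def baseline_de_test(
    normalized_arrays,
    thresholds: DEThresholds | None = None,
    baseline_timepoint: str | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Baseline differential-expression table.

    Returns one row per gene: ``mean_log2_ratio``, linear ``fold_change``,
    ``t_stat``, two-sided raw ``p_value``, ``call`` in {"under", "over",
    "none"}, and ``all_floored`` (no signal in either genotype anywhere).
    """
    thresholds = thresholds or DEThresholds()
    if baseline_timepoint is None:
        baseline_timepoint = normalized_arrays[0].timepoint
    reps = [a for a in normalized_arrays if a.timepoint == baseline_timepoint]
    if len(reps) < 2:
        raise ValueError(
            f"need at least 2 replicate arrays at baseline {baseline_timepoint!r}, got {len(reps)}"
        )
    mut = _genotype_matrix(reps, "mutant").to_numpy(dtype=float)
    wt = _genotype_matrix(reps, "wildtype").to_numpy(dtype=float)
    genes = _genotype_matrix(reps, "mutant").index

    # near-identical rows (noiseless limit) trip scipy's precision warning;
    # those rows are overwritten by the documented zero-variance convention below
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_value = stats.ttest_ind(mut, wt, axis=1, equal_var=not welch)
    mean_diff = mut.mean(axis=1) - wt.mean(axis=1)

    # zero variance in both groups: p = 1 when means are equal, p = 0 otherwise
    degenerate = (mut.var(axis=1) == 0) & (wt.var(axis=1) == 0)
    equal_means = degenerate & (mean_diff == 0)
    unequal_means = degenerate & (mean_diff != 0)
    t_stat = np.where(equal_means, 0.0, t_stat)
    p_value = np.where(equal_means, 1.0, p_value)
    t_stat = np.where(unequal_means, np.where(mean_diff > 0, np.inf, -np.inf), t_stat)
    p_value = np.where(unequal_means, 0.0, p_value)

    fold = np.exp2(mean_diff)
    mut_floored = np.column_stack([a.floored_for("mutant") for a in reps])
    wt_floored = np.column_stack([a.floored_for("wildtype") for a in reps])
    all_floored = mut_floored.all(axis=1) & wt_floored.all(axis=1)

    ft = thresholds.fold_threshold
    significant = p_value < thresholds.alpha
    over = significant & (fold >= ft * (1 - _FOLD_EPS))
    under = significant & (fold <= (1.0 / ft) * (1 + _FOLD_EPS))
    call = np.full(len(genes), "none", dtype=object)
    call[over] = "over"
    call[under] = "under"
    call[all_floored] = "none"

    return pd.DataFrame(
        {
            "mean_log2_ratio": mean_diff,
            "fold_change": fold,
            "t_stat": t_stat,
            "p_value": p_value,
            "call": call,
            "all_floored": all_floored,
        },
        index=genes,
    )


def de_gene_lists(de_table: pd.DataFrame) -> dict:
    """Sorted under/over gene lists from a baseline DE table."""
    return {
        "under": sorted(de_table.index[de_table["call"] == "under"]),
        "over": sorted(de_table.index[de_table["call"] == "over"]),
    }
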