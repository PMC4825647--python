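"""Rule-based trajectory filtering and Up/Nc/Dn pattern classification.

A gene's expression trajectory is its linear mutant:wild-type ratio at each
timepoint, baseline first.  Two deterministic rules structure the analysis:

* the change filter retains a gene iff, at any post-baseline timepoint t,
  ``|r_t - r_0| / r_0 >= filter_threshold`` (default 0.40, against baseline
  only, not consecutive timepoints);
* each consecutive timepoint pair is labelled Up when the signed relative
  change ``(r_next - r_prev)/r_prev`` is at least ``transition_threshold``
  (default 0.20), Dn when at most its negative, Nc otherwise.

Concatenating the labels gives one of 3^(T-1) pattern codes (27 for four
timepoints, e.g. "UpNcDn").  "At least" means ``>=`` at the boundary, with a
tiny absolute guard (1e-12) on the relative change so that decimal inputs
such as 1.0 → 1.2 land on the intended side of the threshold despite binary
floating point.

The signed relative change is measured against the EARLIER value, so Up and
Dn are asymmetric in ratio space: 1.0 → 1.2 is Up at the 20% threshold, but
1.2 → 1.0 is a 16.7% drop and hence Nc.  A log-symmetric alternative
(|log2(r_next/r_prev)| >= log2(1 + threshold)) is available via
``log_scale=True``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import RatioTable

LABELS = ("Up", "Nc", "Dn")

#: absolute guard on the relative change at a threshold boundary
BOUNDARY_EPS = 1e-12


def enumerate_patterns(n_timepoints: int = 4) -> list:
    """All 3^(n-1) pattern codes, lexicographic over (Up, Nc, Dn) per position."""
    if n_timepoints < 2:
        raise ValueError(f"need at least 2 timepoints, got {n_timepoints}")
    return ["".join(p) for p in itertools.product(LABELS, repeat=n_timepoints - 1)]


def null_pattern(n_timepoints: int = 4) -> str:
    """The all-Nc code (no change across any transition)."""
    return "Nc" * (n_timepoints - 1)


def _transition_labels(r_prev, r_next, threshold: float, log_scale: bool) -> np.ndarray:
    r_prev = np.asarray(r_prev, dtype=float)
    r_next = np.asarray(r_next, dtype=float)
    if np.any(r_prev <= 0) or np.any(r_next <= 0):
        raise ValueError("ratios must be strictly positive")
    if threshold < 0:
        raise ValueError(f"transition threshold must be non-negative, got {threshold}")
    if log_scale:
        rel = np.log2(r_next / r_prev)
        thr = np.log2(1.0 + threshold)
    else:
        rel = (r_next - r_prev) / r_prev
        thr = threshold
    if thr == 0:
        up = rel > 0
        dn = rel < 0
    else:
        up = rel >= thr - BOUNDARY_EPS
        dn = rel <= -thr + BOUNDARY_EPS
    out = np.full(rel.shape, "Nc", dtype=object)
    out[up] = "Up"
    out[dn] = "Dn"
    return out


def classify_transition(
    r_prev: float,
    r_next: float,
    transition_threshold: float = 0.20,
    log_scale: bool = False,
) -> str:
    """Label one timepoint transition as "Up", "Dn" or "Nc"."""
    return str(
        _transition_labels(
            np.array([r_prev]), np.array([r_next]), transition_threshold, log_scale
        )[0]
    )


def relative_change_from_baseline(ratios: RatioTable) -> pd.Series:
    """Max over post-baseline timepoints of |r_t - r0| / r0, per gene."""
    vals = ratios.ratios.to_numpy(dtype=float)
    r0 = vals[:, [0]]
    rel = np.abs(vals[:, 1:] - r0) / r0
    return pd.Series(rel.max(axis=1), index=ratios.ratios.index, name="max_rel_change")


def filter_by_change(ratios: RatioTable, filter_threshold: float = 0.40) -> pd.DataFrame:
    """Apply the against-baseline change filter.

    Returns a per-gene frame with the maximal relative change and a
    ``passed`` flag (``>=`` at the boundary).
    """
    if filter_threshold < 0:
        raise ValueError(f"filter threshold must be non-negative, got {filter_threshold}")
    max_rel = relative_change_from_baseline(ratios)
    passed = max_rel >= filter_threshold - BOUNDARY_EPS
    return pd.DataFrame({"max_rel_change": max_rel, "passed": passed})


@dataclass
class ClusterResult:
    """Pattern assignment of the filtered genes.

    ``patterns`` maps each filtered gene to its code; ``filter_table`` keeps
    the filter outcome for every gene in the input.
    """

    patterns: pd.Series
    filter_table: pd.DataFrame
    filter_threshold: float
    transition_threshold: float
    n_timepoints: int

    @property
    def occupancy(self) -> pd.Series:
        """Gene count per pattern code over all 3^(T-1) codes (0 for empty)."""
        codes = enumerate_patterns(self.n_timepoints)
        counts = self.patterns.value_counts()
        return counts.reindex(codes, fill_value=0).astype(int)

    def members(self, code: str) -> list:
        return list(self.patterns.index[self.patterns == code])

    @property
    def n_filtered(self) -> int:
        return len(self.patterns)


def classify_trajectories(
    ratios: RatioTable,
    genes=None,
    transition_threshold: float = 0.20,
    log_scale: bool = False,
) -> pd.Series:
    """Pattern code per gene (no filtering applied)."""
    df = ratios.ratios if genes is None else ratios.ratios.loc[list(genes)]
    vals = df.to_numpy(dtype=float)
    parts = [
        _transition_labels(vals[:, t], vals[:, t + 1], transition_threshold, log_scale)
        for t in range(vals.shape[1] - 1)
    ]
    codes = np.array(["".join(row) for row in zip(*[p.tolist() for p in parts])])
    return pd.Series(codes, index=df.index, name="pattern")


def assign_patterns(
    ratios: RatioTable,
    filter_threshold: float = 0.40,
    transition_threshold: float = 0.20,
    log_scale: bool = False,
    genes=None,
) -> ClusterResult:
    """Filter genes by the baseline-change rule, then assign pattern codes.

    When ``genes`` is given the filter step is skipped and exactly those
    genes are classified (used by the sensitivity scan to hold the filtered
    set fixed while the transition threshold varies).
    """
    filter_table = filter_by_change(ratios, filter_threshold)
    if genes is None:
        genes = filter_table.index[filter_table["passed"]]
    patterns = classify_trajectories(ratios, genes, transition_threshold, log_scale)
    return ClusterResult(
        patterns=patterns,
        filter_table=filter_table,
        filter_threshold=filter_threshold,
        transition_threshold=transition_threshold,
        n_timepoints=len(ratios.timepoints),
    )


@dataclass
class SensitivityScan:
    """Cluster occupancy at each scanned transition threshold."""

    occupancy: pd.DataFrame  # index: pattern codes; columns: thresholds
    patterns: dict = field(repr=False)  # threshold -> per-gene pattern Series
    nc_monotone: bool = True


def sensitivity_scan(
    ratios: RatioTable,
    transition_thresholds,
    filter_threshold: float = 0.40,
    log_scale: bool = False,
) -> SensitivityScan:
    """Recompute cluster occupancy at several transition thresholds.

    The filtered gene set is held fixed.  The report checks the structural
    monotonicity property: per gene, the number of Nc labels is
    non-decreasing in the threshold.
    """
    thresholds = list(transition_thresholds)
    if not thresholds:
        raise ValueError("need at least one transition threshold")
    for thr in thresholds:
        if thr < 0:
            raise ValueError(f"transition threshold must be non-negative, got {thr}")
    filter_table = filter_by_change(ratios, filter_threshold)
    genes = filter_table.index[filter_table["passed"]]
    codes = enumerate_patterns(len(ratios.timepoints))
    occupancy = {}
    patterns = {}
    for thr in thresholds:
        pats = classify_trajectories(ratios, genes, thr, log_scale)
        patterns[thr] = pats
        occupancy[thr] = pats.value_counts().reindex(codes, fill_value=0).astype(int)
    nc_counts = pd.DataFrame(
        {thr: patterns[thr].str.count("Nc") for thr in sorted(thresholds)}
    )
    monotone = bool((nc_counts.diff(axis=1).iloc[:, 1:] >= 0).all().all())
    return SensitivityScan(
        occupancy=pd.DataFrame(occupancy, index=codes),
        patterns=patterns,
        nc_monotone=monotone,
    )
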