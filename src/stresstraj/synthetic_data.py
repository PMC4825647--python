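"""Synthetic two-channel array data with known planted trajectories.

Emulates a 2-genotype co-hybridization design over four timepoints
(pre-stress, 10 min and 60 min of oxidative stress, 60 min post-stress) with
three replicate arrays per timepoint and dye reversal on the middle
replicate.  Each gene is planted with

* a baseline mutant:wild-type ratio r0 (a fold change >= the caller's DE
  threshold for the baseline-DE fraction of genes, a small log-normal wobble
  for the rest),
* a trajectory r0..r3 realizing one of the 3^(T-1) Up/Nc/Dn pattern codes,
  drawn from configurable pattern weights, and
* a wild-type mean abundance drawn log-uniformly over a wide intensity range.

Trajectories are constructed with a safety margin: Up/Dn transitions land at
``margin``-times the transition threshold from the previous value, the first
non-Nc transition is placed so the gene clears the against-baseline filter
at ``margin``-times the filter threshold, and Nc transitions jitter strictly
inside the threshold.  Every planted trajectory is re-checked at generation
time against the classifier of :mod:`stresstraj.trajectory_clustering`; an
inconsistent margin is rejected rather than silently planted.

Arrays then get per-probe multiplicative log-normal noise per channel and,
optionally, a smooth intensity-dependent dye bias added to the log-ratio
(amplitude * sin(pi * u), u the min-max-scaled mean log2 intensity), which
the loess stage is meant to remove.  Everything is deterministic given the
design seed; the pattern draw is the first consumption of
``numpy.random.default_rng(seed)`` (a documented contract used by the
regeneration oracle in the tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationTable,
    RatioTable,
    TwoChannelArray,
    _numeric_column,
    _parse_bool,
    _read_body,
    _split_meta,
    _write_tsv,
    write_array,
)
from .trajectory_clustering import (
    classify_trajectories,
    enumerate_patterns,
    filter_by_change,
    null_pattern,
)

log = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = ("pre", "oxid10", "oxid60", "post60")


def default_pattern_weights(timepoints=DEFAULT_TIMEPOINTS) -> dict:
    """Study-scale default pattern mixture for a 6253-gene genome.

    About 8% of genes respond (511/6253), dominated by a late divergence
    after stress removal (241 NcNcUp, 50 NcNcDn), the rest spread uniformly
    over the remaining codes; all other genes are non-responders (NcNcNc).
    """
    codes = enumerate_patterns(len(timepoints))
    total = 6253.0
    w = {c: 0.0 for c in codes}
    w["NcNcUp"] = 241 / total
    w["NcNcDn"] = 50 / total
    others = [c for c in codes if c not in ("NcNcNc", "NcNcUp", "NcNcDn")]
    for c in others:
        w[c] = (511 - 241 - 50) / len(others) / total
    w["NcNcNc"] = 1.0 - sum(w.values())
    return w


@dataclass
class SyntheticDesign:
    """All knobs of the simulated experiment."""

    n_genes: int = 6253
    probes_per_gene: int = 2
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 3
    dye_swapped_replicates: tuple = (2,)  # mutant on channel A for these replicates
    noise_sd_log2: float = 0.05
    dye_bias_amplitude: float = 0.0
    pattern_weights: dict | None = None  # None -> default_pattern_weights()
    de_fraction: float = 0.05
    de_fold_range: tuple = (2.0, 4.0)
    de_direction: str = "both"  # "both" | "over" | "under"
    baseline_log2_sd: float = 0.1
    abundance_range: tuple = (50.0, 50000.0)
    margin: float = 1.5
    transition_threshold: float = 0.20
    filter_threshold: float = 0.40
    nc_jitter: float | None = None  # half-width of Nc relative-change jitter
    seed: int = 0

    def validate(self) -> "SyntheticDesign":
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("n_genes and probes_per_gene must be positive")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        if self.replicates_per_timepoint < 1:
            raise ValueError("need at least 1 replicate per timepoint")
        if self.noise_sd_log2 < 0 or self.dye_bias_amplitude < 0:
            raise ValueError("noise and dye-bias amplitudes must be non-negative")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.de_direction not in ("both", "over", "under"):
            raise ValueError(f"unknown de_direction {self.de_direction!r}")
        if self.margin < 1.05:
            raise ValueError(
                f"planting margin {self.margin} is too small: transitions this close "
                "to the classification thresholds can be flipped by float rounding; "
                "use margin >= 1.05"
            )
        if self.filter_threshold * self.margin >= 0.95:
            raise ValueError(
                "filter_threshold * margin must stay below 0.95 so a planted 'Dn' "
                "excursion keeps ratios strictly positive"
            )
        w = self.weights_vector()
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("pattern weights must be non-negative with positive sum")
        return self

    def weights_vector(self) -> np.ndarray:
        codes = enumerate_patterns(len(self.timepoints))
        weights = self.pattern_weights
        if weights is None:
            weights = default_pattern_weights(self.timepoints)
        unknown = set(weights) - set(codes)
        if unknown:
            raise ValueError(f"unknown pattern code(s) in weights: {sorted(unknown)}")
        return np.array([weights.get(c, 0.0) for c in codes], dtype=float)

    def nc_jitter_halfwidth(self) -> float:
        """Half-width of the Nc jitter, strictly inside both thresholds.

        Bounded so that even a run of all-Nc transitions drifts less than
        the filter threshold (with margin) away from baseline.
        """
        if self.nc_jitter is not None:
            return float(self.nc_jitter)
        per_transition = self.transition_threshold / (2.0 * self.margin)
        n_trans = len(self.timepoints) - 1
        drift_cap = (1.0 + 0.9 * self.filter_threshold / self.margin) ** (1.0 / n_trans) - 1.0
        return min(per_transition, drift_cap)


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per gene.

    Columns: gene_id, pattern, de_flag, de_call ("over"/"under"/"none"),
    fold_change (linear, >= 1; 1.0 for non-DE genes), abundance, and one
    ``ratio_<timepoint>`` column per timepoint.
    """

    table: pd.DataFrame
    design: SyntheticDesign | None = None

    @property
    def timepoints(self) -> list:
        return [c[len("ratio_"):] for c in self.table.columns if c.startswith("ratio_")]

    def ratio_table(self) -> RatioTable:
        cols = [f"ratio_{tp}" for tp in self.timepoints]
        ratios = self.table.set_index("gene_id")[cols]
        ratios.columns = self.timepoints
        return RatioTable(ratios=ratios, provenance="planted")


def generate_truth(design: SyntheticDesign) -> SyntheticTruth:
    """Draw planted patterns, baseline ratios, trajectories and abundances.

    Deterministic given ``design.seed``.  Raises if the realized
    trajectories do not reproduce their planted pattern and filter status
    under the configured thresholds.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    codes = enumerate_patterns(len(design.timepoints))
    w = design.weights_vector()
    w = w / w.sum()
    n = design.n_genes
    n_trans = len(design.timepoints) - 1

    # documented contract: the pattern draw is the first rng consumption
    pattern_idx = rng.choice(len(codes), size=n, p=w)

    de_flag = rng.random(n) < design.de_fraction
    lo, hi = np.log(design.de_fold_range[0]), np.log(design.de_fold_range[1])
    folds = np.exp(rng.uniform(lo, hi, size=n))
    if design.de_direction == "both":
        over = rng.random(n) < 0.5
    else:
        over = np.full(n, design.de_direction == "over")
    wobble = np.clip(rng.normal(0.0, design.baseline_log2_sd, size=n), -0.4, 0.4)
    r0 = np.where(de_flag, np.where(over, folds, 1.0 / folds), np.exp2(wobble))

    ab_lo, ab_hi = np.log(design.abundance_range[0]), np.log(design.abundance_range[1])
    abundance = np.exp(rng.uniform(ab_lo, ab_hi, size=n))

    labels = np.array([[code[2 * t : 2 * t + 2] for t in range(n_trans)] for code in codes])
    gene_labels = labels[pattern_idx]  # (n, n_trans)
    jit = design.nc_jitter_halfwidth()
    jitter = rng.uniform(-jit, jit, size=(n, n_trans))

    first_non_nc = np.full(n, -1)
    for t in range(n_trans - 1, -1, -1):
        first_non_nc = np.where(gene_labels[:, t] != "Nc", t, first_non_nc)

    thr_t = design.transition_threshold * design.margin
    thr_f = design.filter_threshold * design.margin
    r = np.empty((n, n_trans + 1))
    r[:, 0] = r0
    for t in range(n_trans):
        lab = gene_labels[:, t]
        step = np.where(
            lab == "Nc",
            1.0 + jitter[:, t],
            np.where(lab == "Up", 1.0 + thr_t, 1.0 - thr_t),
        )
        r[:, t + 1] = r[:, t] * step
        # the first divergence is pinned relative to baseline so the gene
        # clears the against-baseline filter with the same margin
        is_first = first_non_nc == t
        r[is_first & (lab == "Up"), t + 1] = (r0 * (1.0 + thr_f))[is_first & (lab == "Up")]
        r[is_first & (lab == "Dn"), t + 1] = (r0 * (1.0 - thr_f))[is_first & (lab == "Dn")]

    table = pd.DataFrame(
        {
            "gene_id": _gene_ids(n),
            "pattern": np.array(codes, dtype=object)[pattern_idx],
            "de_flag": de_flag,
            "de_call": np.where(de_flag, np.where(over, "over", "under"), "none"),
            "fold_change": np.where(de_flag, folds, 1.0),
            "abundance": abundance,
        }
    )
    for t, tp in enumerate(design.timepoints):
        table[f"ratio_{tp}"] = r[:, t]

    truth = SyntheticTruth(table=table, design=design)
    _check_consistency(truth, design)
    return truth


def _gene_ids(n: int) -> list:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _check_consistency(truth: SyntheticTruth, design: SyntheticDesign) -> None:
    """Planted trajectories must reproduce their codes under the classifier."""
    ratios = truth.ratio_table()
    assigned = classify_trajectories(
        ratios, transition_threshold=design.transition_threshold
    )
    planted = truth.table.set_index("gene_id")["pattern"]
    mismatch = assigned != planted
    if mismatch.any():
        raise RuntimeError(
            f"{int(mismatch.sum())} planted trajectories do not realize their "
            f"pattern at margin {design.margin}; increase the margin"
        )
    passed = filter_by_change(ratios, design.filter_threshold)["passed"]
    want = planted != null_pattern(len(design.timepoints))
    bad = passed != want
    if bad.any():
        raise RuntimeError(
            f"{int(bad.sum())} planted trajectories have the wrong filter status "
            f"at margin {design.margin}; increase the margin"
        )


def simulate_arrays(truth: SyntheticTruth, design: SyntheticDesign | None = None) -> list:
    """One probe-level two-channel array per timepoint x replicate.

    Mutant channel expectation is abundance x planted ratio; both channels
    receive independent per-probe log-normal noise at ``noise_sd_log2``;
    the dye-swap scheme decides which physical channel carries the mutant;
    a smooth intensity-dependent dye bias is added to the log-ratio when
    ``dye_bias_amplitude`` > 0.  Noise is drawn from an rng seeded by
    ``[seed, 1]`` so truth generation and hybridization are independent
    streams of the same design seed.
    """
    design = design or truth.design
    if design is None:
        raise ValueError("no design available for simulation")
    design.validate()
    if list(truth.timepoints) != list(design.timepoints):
        raise ValueError("truth and design disagree on timepoints")
    if len(truth.table) != design.n_genes:
        raise ValueError("truth and design disagree on gene count")
    rng = np.random.default_rng([design.seed, 1])
    genes = truth.table["gene_id"].to_numpy()
    abundance = truth.table["abundance"].to_numpy(dtype=float)
    p = design.probes_per_gene
    probe_genes = np.repeat(genes, p)
    probe_ids = np.array(
        [f"{g}_p{i + 1}" for g in genes for i in range(p)], dtype=object
    )
    ab_lo = np.log2(design.abundance_range[0])
    ab_hi = np.log2(design.abundance_range[1])

    arrays = []
    for tp in design.timepoints:
        ratio = truth.table[f"ratio_{tp}"].to_numpy(dtype=float)
        for rep in range(1, design.replicates_per_timepoint + 1):
            wt = np.repeat(abundance, p) * np.exp2(
                rng.normal(0.0, design.noise_sd_log2, size=len(probe_ids))
            )
            mut = np.repeat(abundance * ratio, p) * np.exp2(
                rng.normal(0.0, design.noise_sd_log2, size=len(probe_ids))
            )
            swapped = rep in design.dye_swapped_replicates
            cha, chb = (mut, wt) if swapped else (wt, mut)
            if design.dye_bias_amplitude > 0:
                a = 0.5 * (np.log2(cha) + np.log2(chb))
                u = np.clip((a - ab_lo) / (ab_hi - ab_lo), 0.0, 1.0)
                half_bias = 0.5 * design.dye_bias_amplitude * np.sin(np.pi * u)
                cha = cha * np.exp2(-half_bias)
                chb = chb * np.exp2(half_bias)
            probes = pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "gene_id": probe_genes,
                    "channelA": cha,
                    "channelB": chb,
                }
            )
            arrays.append(
                TwoChannelArray(
                    array_id=f"{tp}_rep{rep}",
                    timepoint=tp,
                    replicate=rep,
                    dye_swapped=swapped,
                    probes=probes,
                ).validate()
            )
    return arrays


def generate_annotations(
    truth: SyntheticTruth,
    n_background_terms: int = 25,
    term_size_range: tuple = (5, 80),
    enriched_patterns: tuple = ("NcNcUp", "NcNcDn"),
    enriched_fraction: float = 0.5,
    seed: int | None = None,
) -> AnnotationTable:
    """Synthetic gene→term table for exercising the enrichment stage.

    A stand-in for a GO-style annotation resource: background terms are
    random gene sets, plus one deliberately enriched term per pattern in
    ``enriched_patterns`` covering ``enriched_fraction`` of that pattern's
    planted genes (with a little background).  The universe is every gene
    in the truth table.
    """
    design = truth.design
    base_seed = seed if seed is not None else (design.seed if design else 0)
    rng = np.random.default_rng([base_seed, 2])
    genes = truth.table["gene_id"].to_numpy()
    rows = []
    lo, hi = term_size_range
    for j in range(n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        term = f"SYN:{j:04d}"
        name = f"synthetic background set {j}"
        rows.extend((g, term, name) for g in sorted(members))
    for j, pattern in enumerate(enriched_patterns):
        in_pattern = truth.table.loc[truth.table["pattern"] == pattern, "gene_id"].to_numpy()
        n_take = max(1, int(round(enriched_fraction * len(in_pattern)))) if len(in_pattern) else 0
        members = list(rng.choice(in_pattern, size=n_take, replace=False)) if n_take else []
        members += list(rng.choice(genes, size=min(5, len(genes)), replace=False))
        term = f"SYN:E{j:03d}"
        name = f"synthetic set enriched in {pattern}"
        rows.extend((g, term, name) for g in sorted(set(members)))
    table = pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])
    table = table.drop_duplicates(subset=["gene_id", "term_id"]).reset_index(drop=True)
    return AnnotationTable(table=table, universe=frozenset(genes))


# ---------------------------------------------------------------------------
# on-disk forms
# ---------------------------------------------------------------------------


def write_truth(truth: SyntheticTruth, path) -> None:
    _write_tsv(truth.table, path, {"timepoints": ",".join(truth.timepoints)})


def read_truth(path) -> SyntheticTruth:
    meta, body, header_line = _split_meta(path)
    df = _read_body(path, body, header_line, ("gene_id", "pattern", "de_flag"))
    for col in df.columns:
        if col.startswith("ratio_") or col in ("fold_change", "abundance"):
            df[col] = _numeric_column(df, col, path, body)
    df["de_flag"] = df["de_flag"].map(lambda raw: _parse_bool(raw, path, "de_flag"))
    return SyntheticTruth(table=df, design=None)


def write_arrays(arrays, out_dir) -> list:
    """Write one TSV per array into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for array in arrays:
        path = out / f"{array.array_id}.tsv"
        write_array(array, path)
        paths.append(path)
    return paths
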