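"""End-to-end orchestration: simulate → normalize → ratios/DE → cluster → enrich.

A run is configured by a single :class:`PipelineConfig` (serializable to
YAML, hashed for provenance), executes deterministically given its seed, and
writes every intermediate artifact plus a ``summary.json`` into the run
directory.  Each stage logs one line with its parameters and row counts so
the filter attrition (genes considered → filtered → per-cluster) is
auditable from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .differential_expression import (
    DEThresholds,
    baseline_de_test,
    compute_ratio_table,
    de_gene_lists,
)
from .enrichment import enrich, report_percentages
from .io_formats import (
    read_ratio_table,
    write_gene_list,
    write_ratio_table,
    _write_tsv,
    _split_meta,
    _read_body,
)
from .normalization import normalize_array, write_normalized
from .synthetic_data import (
    SyntheticDesign,
    generate_annotations,
    generate_truth,
    read_truth,
    simulate_arrays,
    write_arrays,
    write_truth,
)
from .trajectory_clustering import (
    assign_patterns,
    enumerate_patterns,
    null_pattern,
    sensitivity_scan,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of a run, with the study's default parameterization."""

    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    loess: str = "auto"  # "auto" | "on" | "off"
    span: float = 0.4
    floor: float = 1.0
    percentile: float = 75.0
    pooled_percentile: bool = False
    alpha: float = 0.05
    fold_threshold: float = 1.5
    filter_threshold: float = 0.40
    transition_threshold: float = 0.20
    sensitivity_thresholds: tuple = (0.20, 0.30)
    log_scale_transitions: bool = False
    synthetic_annotations: bool = True
    welch: bool = False

    def validate(self) -> "PipelineConfig":
        self.design.validate()
        if self.loess not in ("auto", "on", "off"):
            raise ValueError(f"loess must be auto/on/off, got {self.loess!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.filter_threshold < 0 or self.transition_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        design = d.pop("design", {})
        if isinstance(design, dict):
            for key in ("timepoints", "dye_swapped_replicates", "de_fold_range", "abundance_range"):
                if key in design and isinstance(design[key], list):
                    design[key] = tuple(design[key])
            design = SyntheticDesign(**design)
        if "sensitivity_thresholds" in d and isinstance(d["sensitivity_thresholds"], list):
            d["sensitivity_thresholds"] = tuple(d["sensitivity_thresholds"])
        return cls(design=design, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        """sha256 of the canonical (key-sorted) JSON form; stable under reordering."""
        canon = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    arrays=None,
    annotations=None,
    write_array_files: bool = False,
) -> dict:
    """Execute the full analysis; returns (and writes) the summary.

    When ``arrays`` is None the synthetic design in the config is simulated
    and the planted truth is written alongside the outputs.  ``annotations``
    enables the enrichment stage; for simulated runs a synthetic annotation
    table is generated unless disabled in the config.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    truth = None

    if arrays is None:
        truth = generate_truth(design)
        arrays = simulate_arrays(truth, design)
        write_truth(truth, out / "truth.tsv")
        log.info("simulate: %d genes -> %d arrays (seed %d)", design.n_genes, len(arrays), design.seed)
        if annotations is None and config.synthetic_annotations:
            annotations = generate_annotations(truth)
        if write_array_files:
            write_arrays(arrays, out / "arrays")
        simulated = True
    else:
        simulated = False

    # loess "auto": simulated data are raw (apply iff bias was planted);
    # file data rely on their scanner-normalized metadata flag
    loess_mode = config.loess
    if loess_mode == "auto" and simulated:
        loess_mode = "on" if design.dye_bias_amplitude > 0 else "off"

    normalized = [
        normalize_array(
            a,
            loess=loess_mode,
            span=config.span,
            floor=config.floor,
            percentile=config.percentile,
            pooled_channels=config.pooled_percentile,
        )
        for a in arrays
    ]
    norm_dir = out / "normalized"
    for narr in normalized:
        write_normalized(narr, norm_dir / f"{narr.array_id}.tsv")
    log.info("normalize: %d arrays, loess=%s, floor=%g, percentile=%g",
             len(normalized), loess_mode, config.floor, config.percentile)

    ratios = compute_ratio_table(normalized, provenance=config.config_hash())
    write_ratio_table(ratios, out / "ratio_table.tsv")
    log.info("ratios: %d genes x %d timepoints", len(ratios.genes), len(ratios.timepoints))

    de_table = baseline_de_test(
        normalized,
        DEThresholds(alpha=config.alpha, fold_threshold=config.fold_threshold),
        baseline_timepoint=arrays[0].timepoint,
        welch=config.welch,
    )
    de_out = de_table.copy()
    de_out.index.name = "gene_id"
    _write_tsv(de_out, out / "de_table.tsv", index=True)
    lists = de_gene_lists(de_table)
    for name, genes in lists.items():
        write_gene_list(genes, out / f"genes_{name}.tsv")
    log.info("baseline DE: %d genes -> %d under, %d over (alpha=%g, fold=%g)",
             len(de_table), len(lists["under"]), len(lists["over"]),
             config.alpha, config.fold_threshold)

    clusters = assign_patterns(
        ratios,
        filter_threshold=config.filter_threshold,
        transition_threshold=config.transition_threshold,
        log_scale=config.log_scale_transitions,
    )
    patterns_df = pd.DataFrame(
        {
            "pattern": clusters.patterns,
            "max_rel_change": clusters.filter_table.loc[clusters.patterns.index, "max_rel_change"],
        }
    )
    patterns_df.index.name = "gene_id"
    _write_tsv(patterns_df, out / "patterns.tsv", index=True)
    filt = clusters.filter_table.copy()
    filt.index.name = "gene_id"
    _write_tsv(filt, out / "filtered_genes.tsv", index=True)
    occ = clusters.occupancy.rename("n_genes").to_frame()
    occ.index.name = "pattern"
    _write_tsv(occ, out / "occupancy.tsv", index=True)
    cluster_dir = out / "clusters"
    for code in clusters.occupancy.index[clusters.occupancy > 0]:
        write_gene_list(sorted(clusters.members(code)), cluster_dir / f"{code}.tsv")
    log.info("cluster: %d/%d genes pass the %g filter; %d/%d patterns occupied",
             clusters.n_filtered, len(ratios.genes), config.filter_threshold,
             int((clusters.occupancy > 0).sum()), len(clusters.occupancy))

    scan = sensitivity_scan(
        ratios,
        config.sensitivity_thresholds,
        filter_threshold=config.filter_threshold,
        log_scale=config.log_scale_transitions,
    )
    scan_df = scan.occupancy.copy()
    scan_df.columns = [f"threshold_{c:g}" for c in scan_df.columns]
    scan_df.index.name = "pattern"
    _write_tsv(scan_df, out / "sensitivity.tsv", index=True)
    if not scan.nc_monotone:
        raise AssertionError("sensitivity scan violated Nc-count monotonicity")

    top_terms: dict = {}
    if annotations is not None:
        # array-as-universe: restrict annotations to genes present on the array
        universe = set(ratios.genes)
        ann_table = annotations.table[annotations.table["gene_id"].isin(universe)]
        ann = type(annotations)(table=ann_table.reset_index(drop=True), universe=frozenset(universe))
        filtered_genes = sorted(clusters.patterns.index)
        for name, genes in {**lists, "filtered": filtered_genes}.items():
            if not genes:
                top_terms[name] = []
                continue
            result = enrich(genes, ann, universe=universe)
            _write_tsv(result, out / f"enrichment_{name}.tsv")
            _write_tsv(report_percentages(result), out / f"enrichment_{name}_percent.tsv")
            top = result.head(5)
            top_terms[name] = [
                {"term_id": r.term_id, "p_bonferroni": float(r.p_bonferroni)}
                for r in top.itertuples()
            ]
            log.info("enrich[%s]: %d genes, %d terms tested", name, len(genes), len(result))

    summary = {
        "config_hash": config.config_hash(),
        "n_genes": len(ratios.genes),
        "timepoints": list(ratios.timepoints),
        "n_under": len(lists["under"]),
        "n_over": len(lists["over"]),
        "n_filtered": clusters.n_filtered,
        "occupied_clusters": int((clusters.occupancy > 0).sum()),
        "cluster_sizes": {c: int(v) for c, v in clusters.occupancy.items() if v > 0},
        "sensitivity_nc_monotone": scan.nc_monotone,
        "top_terms": top_terms,
        "simulated": simulated,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    config.to_yaml(out / "config.yaml")
    return summary


# ---------------------------------------------------------------------------
# recovery against planted truth
# ---------------------------------------------------------------------------


def recovery_report(run_dir, truth_path=None, out_path=None) -> dict:
    """Compare a run's calls with the planted truth.

    Reads the ratio/pattern/DE outputs in ``run_dir`` and the truth TSV
    (default ``run_dir/truth.tsv``).  Genes the filter removed count as the
    all-Nc pattern.  Returns overall and per-pattern recovery, baseline-DE
    sensitivity/specificity, and the planted x assigned confusion matrix.
    """
    run = Path(run_dir)
    truth = read_truth(truth_path or run / "truth.tsv")
    ratios = read_ratio_table(run / "ratio_table.tsv")
    truth_genes = set(truth.table["gene_id"])
    if truth_genes != set(ratios.genes):
        raise ValueError("truth and run disagree on the gene set")
    n_timepoints = len(ratios.timepoints)

    meta, body, header_line = _split_meta(run / "patterns.tsv")
    pats = _read_body(run / "patterns.tsv", body, header_line, ("gene_id", "pattern"))
    assigned = pd.Series(null_pattern(n_timepoints), index=pd.Index(sorted(truth_genes)))
    assigned.loc[pats["gene_id"].to_numpy()] = pats["pattern"].to_numpy()
    planted = truth.table.set_index("gene_id")["pattern"].reindex(assigned.index)

    overall = float((assigned == planted).mean())
    per_pattern = {
        code: float((assigned[planted == code] == code).mean())
        for code in enumerate_patterns(n_timepoints)
        if (planted == code).any()
    }
    confusion = pd.crosstab(planted, assigned, rownames=["planted"], colnames=["assigned"])

    meta, body, header_line = _split_meta(run / "de_table.tsv")
    de = _read_body(run / "de_table.tsv", body, header_line, ("gene_id", "call"))
    de_call = de.set_index("gene_id")["call"].reindex(assigned.index)
    truth_call = truth.table.set_index("gene_id")["de_call"].reindex(assigned.index)
    is_de = truth_call != "none"
    sensitivity = float((de_call[is_de] == truth_call[is_de]).mean()) if is_de.any() else float("nan")
    specificity = float((de_call[~is_de] == "none").mean()) if (~is_de).any() else float("nan")

    report = {
        "pattern_recovery_overall": overall,
        "pattern_recovery_per_pattern": per_pattern,
        "de_sensitivity": sensitivity,
        "de_specificity": specificity,
    }
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
        confusion.to_csv(Path(out_path).with_suffix(".confusion.tsv"), sep="\t")
    report["confusion"] = confusion
    return report
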