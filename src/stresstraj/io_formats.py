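"""Tab-separated readers and writers for every artifact the pipeline touches.

All files are plain UTF-8 TSV: an optional block of ``#``-prefixed
``key=value`` metadata lines, a single header row, then data rows.  Writers
emit rows and columns in a deterministic order and floats at full repr
precision, so every artifact is diffable and round-trips bytewise.

The named columns are part of the public contract:

======================  ==================================================
artifact                columns
======================  ==================================================
array TSV               probe_id, gene_id, channelA, channelB
annotation TSV          gene_id, term_id, term_name
ratio TSV               gene_id, then one column per timepoint label
gene-list TSV           gene_id
======================  ==================================================

The raw Agilent feature-extraction format is deliberately not parsed; a
converter to this dialect is the documented extension point for real scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ARRAY_COLUMNS = ("probe_id", "gene_id", "channelA", "channelB")
ANNOTATION_COLUMNS = ("gene_id", "term_id", "term_name")


class FormatError(ValueError):
    """An input file violates the TSV dialect; names the offending line."""

    def __init__(self, path, message: str, line: int | None = None):
        where = str(path) if line is None else f"{path}, line {line}"
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.line = line


# ---------------------------------------------------------------------------
# core domain containers
# ---------------------------------------------------------------------------


@dataclass
class TwoChannelArray:
    """Probe-level intensities for one hybridization.

    Channels "A" and "B" are the two physical dye channels.  Which channel
    carries the mutant sample is resolved through ``dye_swapped``: in the
    default orientation the mutant is on channel B; a swapped replicate puts
    it on channel A.
    """

    array_id: str
    timepoint: str
    replicate: int
    dye_swapped: bool
    probes: pd.DataFrame  # columns: probe_id, gene_id, channelA, channelB
    loess_normalized: bool = False

    @property
    def mutant_channel(self) -> str:
        return "A" if self.dye_swapped else "B"

    @property
    def wildtype_channel(self) -> str:
        return "B" if self.dye_swapped else "A"

    def channel(self, name: str) -> np.ndarray:
        return self.probes[f"channel{name}"].to_numpy(dtype=float)

    def genotype_intensity(self, genotype: str) -> np.ndarray:
        """Intensities for ``genotype`` in {"mutant", "wildtype"}."""
        ch = self.mutant_channel if genotype == "mutant" else self.wildtype_channel
        return self.channel(ch)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def validate(self) -> "TwoChannelArray":
        missing = [c for c in ARRAY_COLUMNS if c not in self.probes.columns]
        if missing:
            raise FormatError(self.array_id, f"missing column(s) {missing}")
        vals = self.probes[["channelA", "channelB"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise FormatError(self.array_id, "non-finite intensity value")
        if not np.all(vals > 0):
            raise FormatError(self.array_id, "non-positive intensity value")
        per_probe = self.probes.groupby("probe_id", sort=False)["gene_id"].nunique()
        bad = per_probe[per_probe > 1]
        if len(bad):
            raise FormatError(
                self.array_id,
                f"probe(s) mapped to more than one gene: {list(bad.index[:5])}",
            )
        return self


@dataclass
class AnnotationTable:
    """Gene → functional-term annotations plus the gene universe.

    ``universe`` is the background gene set for enrichment; when not given
    explicitly it is inferred as the set of annotated genes.
    """

    table: pd.DataFrame  # columns: gene_id, term_id, term_name
    universe: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            missing = set(self.table["gene_id"]) - self.universe
            if missing:
                raise ValueError(
                    f"universe must contain every annotated gene; "
                    f"{len(missing)} missing (e.g. {sorted(missing)[:3]})"
                )

    @property
    def genes(self) -> frozenset:
        if self.universe is not None:
            return self.universe
        return frozenset(self.table["gene_id"])

    @property
    def terms(self) -> list:
        return sorted(self.table["term_id"].unique())

    def term_genes(self) -> dict:
        """Mapping term_id → frozenset of annotated genes."""
        return {
            term: frozenset(sub["gene_id"])
            for term, sub in self.table.groupby("term_id", sort=True)
        }

    def term_names(self) -> dict:
        return dict(zip(self.table["term_id"], self.table["term_name"]))


@dataclass
class RatioTable:
    """Per-gene linear mutant:wild-type expression ratio at each timepoint.

    The first column is the baseline (pre-stress) timepoint; all ratios are
    strictly positive.  ``provenance`` records the normalization settings
    hash of the run that produced the table.
    """

    ratios: pd.DataFrame  # index: gene_id; columns: timepoint labels
    provenance: str = ""

    def __post_init__(self):
        vals = self.ratios.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise ValueError("ratio table must be finite and strictly positive")
        if self.ratios.index.has_duplicates:
            raise ValueError("ratio table must have one row per gene")

    @property
    def timepoints(self) -> list:
        return list(self.ratios.columns)

    @property
    def genes(self) -> list:
        return list(self.ratios.index)


# ---------------------------------------------------------------------------
# low-level dialect helpers
# ---------------------------------------------------------------------------


def _format_meta(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _split_meta(path) -> tuple[dict, list, int]:
    """Return (metadata, non-comment lines, line number of the header row)."""
    text = Path(path).read_text(encoding="utf-8")
    meta: dict = {}
    body: list = []
    header_line = None
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            continue
        if header_line is None:
            header_line = i
        body.append((i, line))
    if header_line is None:
        raise FormatError(path, "no header row found")
    return meta, body, header_line


def _parse_bool(raw: str, path, key: str) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise FormatError(path, f"metadata {key}={raw!r} is not a boolean")


def _read_body(path, body, header_line, required_columns) -> pd.DataFrame:
    lines = [line for _, line in body if line.strip() != ""]
    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise FormatError(path, f"missing column(s) {missing}", line=header_line)
    return df


def _numeric_column(df: pd.DataFrame, col: str, path, body) -> np.ndarray:
    """Parse a column as float, naming the first offending line on failure."""
    def _to_float(raw):
        try:
            return float(raw)  # exact round-trip parse (pd.to_numeric can be 1 ulp off)
        except (TypeError, ValueError):
            return np.nan

    parsed = df[col].map(_to_float)
    bad = parsed.index[parsed.isna() & df[col].notna()]
    if len(bad):
        row = int(bad[0])
        line_no = [n for n, line in body if line.strip() != ""][row + 1]
        raise FormatError(
            path, f"non-numeric value {df[col].iloc[row]!r} in column {col}", line=line_no
        )
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0])
        line_no = [n for n, line in body if line.strip() != ""][row + 1]
        raise FormatError(path, f"empty value in column {col}", line=line_no)
    return parsed.to_numpy(dtype=float)


def _write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if meta:
            fh.write(_format_meta(meta))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


# ---------------------------------------------------------------------------
# arrays
# ---------------------------------------------------------------------------


def write_array(array: TwoChannelArray, path) -> None:
    array.validate()
    meta = {
        "array_id": array.array_id,
        "timepoint": array.timepoint,
        "replicate": array.replicate,
        "dye_swapped": str(array.dye_swapped).lower(),
        "loess_normalized": str(array.loess_normalized).lower(),
    }
    _write_tsv(array.probes[list(ARRAY_COLUMNS)], path, meta)


def read_array(path, timepoints=None) -> TwoChannelArray:
    """Read one hybridization; optionally restrict the timepoint label.

    Raises :class:`FormatError` (naming the line) for a missing column,
    non-numeric or non-positive intensity, or an unknown timepoint label.
    """
    meta, body, header_line = _split_meta(path)
    for key in ("array_id", "timepoint", "replicate", "dye_swapped"):
        if key not in meta:
            raise FormatError(path, f"missing metadata line '# {key}=...'")
    if timepoints is not None and meta["timepoint"] not in timepoints:
        raise FormatError(
            path, f"unknown timepoint label {meta['timepoint']!r}; expected one of {list(timepoints)}"
        )
    df = _read_body(path, body, header_line, ARRAY_COLUMNS)
    for col in ("channelA", "channelB"):
        values = _numeric_column(df, col, path, body)
        nonpos = np.where(~(values > 0))[0]
        if len(nonpos):
            row = int(nonpos[0])
            line_no = [n for n, line in body if line.strip() != ""][row + 1]
            raise FormatError(
                path, f"non-positive intensity {values[row]} in column {col}", line=line_no
            )
        df[col] = values
    array = TwoChannelArray(
        array_id=meta["array_id"],
        timepoint=meta["timepoint"],
        replicate=int(meta["replicate"]),
        dye_swapped=_parse_bool(meta["dye_swapped"], path, "dye_swapped"),
        probes=df[list(ARRAY_COLUMNS)].reset_index(drop=True),
        loess_normalized=_parse_bool(meta.get("loess_normalized", "false"), path, "loess_normalized"),
    )
    return array.validate()


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def write_annotations(annotations: AnnotationTable, path) -> None:
    df = annotations.table[list(ANNOTATION_COLUMNS)].sort_values(
        ["term_id", "gene_id"], kind="mergesort"
    )
    meta = {}
    if annotations.universe is not None:
        meta["universe"] = ",".join(sorted(annotations.universe))
    _write_tsv(df.reset_index(drop=True), path, meta)


def read_annotations(path) -> AnnotationTable:
    """Read a gene→term table; duplicate (gene, term) rows are dropped with a warning."""
    meta, body, header_line = _split_meta(path)
    lines = [line for _, line in body if line.strip() != ""]
    if len(lines) <= 1:  # header only: valid empty table
        df = pd.DataFrame(columns=list(ANNOTATION_COLUMNS))
    else:
        df = _read_body(path, body, header_line, ANNOTATION_COLUMNS)
    n_before = len(df)
    df = df.drop_duplicates(subset=["gene_id", "term_id"]).reset_index(drop=True)
    if len(df) < n_before:
        log.warning(
            "%s: dropped %d duplicate (gene, term) row(s)", path, n_before - len(df)
        )
    universe = None
    if "universe" in meta and meta["universe"]:
        universe = frozenset(meta["universe"].split(","))
    return AnnotationTable(table=df[list(ANNOTATION_COLUMNS)], universe=universe)


# ---------------------------------------------------------------------------
# ratio tables and gene lists
# ---------------------------------------------------------------------------


def write_ratio_table(table: RatioTable, path) -> None:
    df = table.ratios.copy()
    df.index.name = "gene_id"
    _write_tsv(df, path, {"provenance": table.provenance}, index=True)


def read_ratio_table(path) -> RatioTable:
    meta, body, header_line = _split_meta(path)
    df = _read_body(path, body, header_line, ("gene_id",))
    timepoints = [c for c in df.columns if c != "gene_id"]
    if len(timepoints) < 2:
        raise FormatError(path, "ratio table needs at least two timepoint columns")
    for col in timepoints:
        df[col] = _numeric_column(df, col, path, body)
    return RatioTable(
        ratios=df.set_index("gene_id")[timepoints],
        provenance=meta.get("provenance", ""),
    )


def write_gene_list(genes, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"gene_id": list(genes)})
    _write_tsv(df, path, meta)


def read_gene_list(path) -> list:
    _, body, header_line = _split_meta(path)
    df = _read_body(path, body, header_line, ("gene_id",))
    return df["gene_id"].tolist()
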