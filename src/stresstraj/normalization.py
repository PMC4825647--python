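"""Normalization chain for two-channel arrays.

The stages run in this order, mirroring a GeneSpring-era Agilent workflow:

1. :func:`loess_dye_normalize` — optional intensity-dependent dye correction:
   the per-probe log-ratio M = log2(B/A) is recentred by a degree-1 loess fit
   of M on the mean log-intensity A = (log2 A + log2 B)/2, and the channels
   are reconstituted so A is preserved per probe.  Skipped when the scanner
   already applied it.
2. :func:`summarize_probes` — replicate probes of the same gene are collapsed
   to their geometric mean, per channel.
3. :func:`floor_log2_shift` — intensities below a floor (default 1) are set
   to the floor, log2 is applied, and each channel is shifted so its chosen
   percentile (default the 75th, linear-interpolation quantile rule) is 0.

The percentile shift is applied per channel per array by default; a pooled
variant (one shift for both channels of an array) is available because the
two conventions differ only by a per-array constant in the log-ratio and
either may match a historical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import (
    TwoChannelArray,
    _numeric_column,
    _parse_bool,
    _read_body,
    _split_meta,
    _write_tsv,
)

#: minimum probe count for a stable local-regression fit
MIN_LOESS_PROBES = 30


@dataclass
class NormalizedArray:
    """Per-gene normalized log2 intensities for one hybridization.

    ``values`` has one row per gene with the post-shift log2 intensity and a
    floored flag for each channel.  ``shiftA``/``shiftB`` record the per-array
    percentile used in the shift so the transform is invertible.
    """

    array_id: str
    timepoint: str
    replicate: int
    dye_swapped: bool
    values: pd.DataFrame  # index gene_id; columns log2A, log2B, flooredA, flooredB
    shiftA: float
    shiftB: float
    floor: float = 1.0
    percentile: float = 75.0
    pooled_shift: bool = False

    @property
    def mutant_channel(self) -> str:
        return "A" if self.dye_swapped else "B"

    @property
    def wildtype_channel(self) -> str:
        return "B" if self.dye_swapped else "A"

    def log2_for(self, genotype: str) -> pd.Series:
        ch = self.mutant_channel if genotype == "mutant" else self.wildtype_channel
        return self.values[f"log2{ch}"]

    def floored_for(self, genotype: str) -> pd.Series:
        ch = self.mutant_channel if genotype == "mutant" else self.wildtype_channel
        return self.values[f"floored{ch}"]

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def loess_dye_normalize(
    array: TwoChannelArray, span: float = 0.4, iterations: int = 2
) -> TwoChannelArray:
    """Remove intensity-dependent dye bias from one array.

    Fits a weighted local linear regression of M = log2(B/A) on
    A = (log2 A + log2 B)/2 with the given ``span`` (fraction of probes per
    local fit) and subtracts the fit, preserving A per probe.  Requires at
    least :data:`MIN_LOESS_PROBES` probes.
    """
    array.validate()
    if array.n_probes < MIN_LOESS_PROBES:
        raise ValueError(
            f"loess dye normalization needs at least {MIN_LOESS_PROBES} probes, "
            f"got {array.n_probes}"
        )
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    la = np.log2(array.channel("A"))
    lb = np.log2(array.channel("B"))
    m = lb - la
    a = 0.5 * (la + lb)
    delta = 0.01 * (a.max() - a.min())
    fit = lowess(m, a, frac=span, it=iterations, delta=delta, return_sorted=False)
    m_corr = m - fit
    probes = array.probes.copy()
    probes["channelA"] = np.exp2(a - m_corr / 2.0)
    probes["channelB"] = np.exp2(a + m_corr / 2.0)
    return replace(array, probes=probes, loess_normalized=True)


def summarize_probes(array: TwoChannelArray) -> TwoChannelArray:
    """Collapse replicate probes of each gene to their geometric mean.

    Genes with a single probe pass through unchanged.  Output rows are
    sorted by gene id with ``probe_id`` set to the gene id; the result is
    exp(mean(log(probe intensities))) per gene and channel.
    """
    array.validate()
    vals = array.probes[["channelA", "channelB"]].to_numpy(dtype=float)
    if np.any(vals == 0):
        raise ValueError("geometric mean undefined for zero intensity")
    logged = array.probes.assign(
        channelA=np.log(vals[:, 0]), channelB=np.log(vals[:, 1])
    )
    summarized = (
        logged.groupby("gene_id", sort=True)[["channelA", "channelB"]]
        .mean()
        .apply(np.exp)
        .reset_index()
    )
    summarized.insert(0, "probe_id", summarized["gene_id"])
    return replace(array, probes=summarized[["probe_id", "gene_id", "channelA", "channelB"]])


def floor_log2_shift(
    array: TwoChannelArray,
    floor: float = 1.0,
    percentile: float = 75.0,
    pooled_channels: bool = False,
) -> NormalizedArray:
    """Floor, log2-transform and percentile-shift a summarized array.

    Intensities below ``floor`` are raised to ``floor``; values are log2
    transformed; each channel is shifted by its own ``percentile`` of the
    log2 values (or by the pooled percentile of both channels when
    ``pooled_channels``), so that percentile becomes 0.
    """
    array.validate()
    if array.probes["gene_id"].duplicated().any():
        raise ValueError("floor_log2_shift expects a summarized array (one row per gene)")
    if not 0 <= percentile <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    cha = array.channel("A")
    chb = array.channel("B")
    la = np.log2(np.maximum(cha, floor))
    lb = np.log2(np.maximum(chb, floor))
    if pooled_channels:
        shift = float(np.percentile(np.concatenate([la, lb]), percentile))
        shift_a = shift_b = shift
    else:
        shift_a = float(np.percentile(la, percentile))
        shift_b = float(np.percentile(lb, percentile))
    values = pd.DataFrame(
        {
            "log2A": la - shift_a,
            "log2B": lb - shift_b,
            "flooredA": cha < floor,
            "flooredB": chb < floor,
        },
        index=pd.Index(array.probes["gene_id"], name="gene_id"),
    )
    return NormalizedArray(
        array_id=array.array_id,
        timepoint=array.timepoint,
        replicate=array.replicate,
        dye_swapped=array.dye_swapped,
        values=values,
        shiftA=shift_a,
        shiftB=shift_b,
        floor=floor,
        percentile=percentile,
        pooled_shift=pooled_channels,
    )


def normalize_array(
    array: TwoChannelArray,
    loess: str = "auto",
    span: float = 0.4,
    floor: float = 1.0,
    percentile: float = 75.0,
    pooled_channels: bool = False,
) -> NormalizedArray:
    """Run the full chain on one array.

    ``loess`` is "on", "off", or "auto" (apply unless the array's metadata
    says the scanner already dye-normalized it).
    """
    if loess not in ("auto", "on", "off"):
        raise ValueError(f"loess must be 'auto', 'on' or 'off', got {loess!r}")
    apply_loess = loess == "on" or (loess == "auto" and not array.loess_normalized)
    if apply_loess:
        array = loess_dye_normalize(array, span=span)
    return floor_log2_shift(
        summarize_probes(array),
        floor=floor,
        percentile=percentile,
        pooled_channels=pooled_channels,
    )


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------


def write_normalized(norm: NormalizedArray, path) -> None:
    meta = {
        "array_id": norm.array_id,
        "timepoint": norm.timepoint,
        "replicate": norm.replicate,
        "dye_swapped": str(norm.dye_swapped).lower(),
        "shiftA": repr(norm.shiftA),
        "shiftB": repr(norm.shiftB),
        "floor": repr(norm.floor),
        "percentile": repr(norm.percentile),
        "pooled_shift": str(norm.pooled_shift).lower(),
    }
    df = norm.values.copy()
    df.index.name = "gene_id"
    _write_tsv(df, path, meta, index=True)


def read_normalized(path) -> NormalizedArray:
    meta, body, header_line = _split_meta(path)
    df = _read_body(path, body, header_line, ("gene_id", "log2A", "log2B", "flooredA", "flooredB"))
    for col in ("log2A", "log2B"):
        df[col] = _numeric_column(df, col, path, body)
    for col in ("flooredA", "flooredB"):
        df[col] = df[col].map(lambda raw: _parse_bool(raw, path, col))
    return NormalizedArray(
        array_id=meta["array_id"],
        timepoint=meta["timepoint"],
        replicate=int(meta["replicate"]),
        dye_swapped=_parse_bool(meta["dye_swapped"], path, "dye_swapped"),
        values=df.set_index("gene_id")[["log2A", "log2B", "flooredA", "flooredB"]],
        shiftA=float(meta["shiftA"]),
        shiftB=float(meta["shiftB"]),
        floor=float(meta.get("floor", 1.0)),
        percentile=float(meta.get("percentile", 75.0)),
        pooled_shift=_parse_bool(meta.get("pooled_shift", "false"), path, "pooled_shift"),
    )
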