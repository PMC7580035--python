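"""Genome gridding and mutation counting.

The background model is trained on fixed-length bins (default 1 Mb)
tiling each chromosome.  Bins overlapping mappability-blacklist or
assembly-gap intervals by even a single base are flagged unusable and
excluded from training; a trailing remainder shorter than the bin length
is discarded outright so that every retained bin has identical length.

Pooled mutation counts are tabulated per disease and per bin: for
disease ``d`` with samples ``s = 1..s_d`` the pooled count in bin ``i``
is ``y_i^d = sum_s y_i^{d,s}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import any_overlap, merge_intervals

logger = logging.getLogger(__name__)

#: chromosomes retained when the human-genome flag is set (no chrY).
HUMAN_CHROMS = frozenset(
    {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)} | {"chrX", "X"}
)

BIN_COLUMNS = ["chrom", "start", "end", "index", "usable"]


def make_bins(
    chrom_sizes: dict[str, int], bin_length: int, human: bool = False
) -> pd.DataFrame:
    """Tile every chromosome with non-overlapping bins of fixed length.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    bin_length
        Bin length ``l`` in bp; the trailing remainder shorter than ``l``
        is discarded so all bins have equal length.
    human
        If True keep only autosomes and chrX (sex-imbalance removal for
        the human genome); synthetic genomes keep all chromosomes.

    Returns
    -------
    DataFrame with columns chrom, start, end, index, usable (all True).
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if bin_length <= 0:
        raise ValueError("bin_length must be positive")
    frames = []
    index0 = 0
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        if human and chrom not in HUMAN_CHROMS:
            continue
        n = int(size) // int(bin_length)
        if n == 0:
            continue
        starts = np.arange(n, dtype=np.int64) * bin_length
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_length,
                    "index": np.arange(index0, index0 + n),
                    "usable": True,
                }
            )
        )
        index0 += n
    if not frames:
        warnings.warn("bin_length exceeds every chromosome; no bins produced")
        return pd.DataFrame(columns=BIN_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "index": np.int64, "usable": bool}
        )
    return pd.concat(frames, ignore_index=True)


def apply_blacklist(
    bins: pd.DataFrame,
    excludable: pd.DataFrame | None = None,
    gaps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Flag bins overlapping blacklist or gap intervals as unusable.

    Any overlap of >= 1 bp disqualifies the whole bin.  Interval frames
    need columns chrom/start/end in 0-based half-open coordinates.
    """
    bins = bins.copy()
    pieces = [df for df in (excludable, gaps) if df is not None and len(df)]
    if not pieces:
        return bins
    bad = pd.concat(pieces, ignore_index=True)
    usable = bins["usable"].to_numpy().copy()
    for chrom, grp in bad.groupby("chrom"):
        mask = (bins["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        blocks = merge_intervals(zip(grp["start"], grp["end"]))
        hit = any_overlap(
            bins.loc[mask, "start"].to_numpy(), bins.loc[mask, "end"].to_numpy(), blocks
        )
        usable[mask] &= ~hit
    bins["usable"] = usable
    return bins


@dataclass
class CountsMatrix:
    """Pooled mutation counts per disease and bin.

    ``values`` is indexed by disease (rows) and bin index (columns);
    ``per_sample`` optionally holds the disaggregated counts, and
    ``sample_counts`` records the number of samples ``s_d`` per disease.
    ``dropped`` counts variants that fell in unusable bins, remainder
    regions or unknown chromosomes, per disease.
    """

    values: pd.DataFrame
    sample_counts: dict[str, int]
    per_sample: dict[str, pd.DataFrame] | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return list(self.values.index)

    def counts(self, disease: str) -> np.ndarray:
        return self.values.loc[disease].to_numpy()


def count_mutations(
    catalog: pd.DataFrame, bins: pd.DataFrame, per_sample: bool = False
) -> CountsMatrix:
    """Assign variants to usable bins and pool counts per disease.

    ``catalog`` needs columns chrom, pos (0-based), sample, disease.
    Duplicate calls at the same position in the same sample are counted
    once; the same position in different samples counts once per sample.
    Variants landing in unusable bins, in discarded remainder regions or
    on chromosomes absent from the grid are tallied as dropped.
    """
    required = {"chrom", "pos", "sample", "disease"}
    missing = required - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog lacks columns {sorted(missing)}")
    if len(catalog) and (catalog["pos"] < 0).any():
        raise ValueError("negative variant position")

    catalog = catalog.drop_duplicates(subset=["disease", "sample", "chrom", "pos"])

    bin_index = {}
    if len(bins):
        lengths = (bins["end"] - bins["start"]).unique()
        if len(lengths) != 1:
            raise ValueError("bins must have uniform length")
        l = int(lengths[0])
        for chrom, grp in bins.groupby("chrom"):
            grp = grp.sort_values("start")
            bin_index[chrom] = (
                grp["start"].to_numpy(),
                grp["index"].to_numpy(),
                grp["usable"].to_numpy(),
            )
    else:
        l = 0

    n_slots = int(bins["index"].max()) + 1 if len(bins) else 0
    assigned = np.full(len(catalog), -1, dtype=np.int64)
    pos = catalog["pos"].to_numpy(dtype=np.int64)
    for chrom, (starts, idx, usable) in bin_index.items():
        mask = (catalog["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        p = pos[mask]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < starts[np.clip(j, 0, len(starts) - 1)] + l)
        local = np.full(mask.sum(), -1, dtype=np.int64)
        good = ok & usable[np.clip(j, 0, len(starts) - 1)]
        local[good] = idx[j[good]]
        assigned[mask] = local

    unknown = ~catalog["chrom"].isin(bin_index)
    if unknown.any():
        names = sorted(catalog.loc[unknown, "chrom"].unique())
        logger.warning("variants on chromosomes absent from grid: %s", names)

    diseases = sorted(catalog["disease"].unique()) if len(catalog) else []
    values = pd.DataFrame(
        0, index=pd.Index(diseases, name="disease"), columns=bins["index"], dtype=np.int64
    )
    dropped: dict[str, int] = {}
    per_sample_tables: dict[str, pd.DataFrame] | None = {} if per_sample else None
    sample_counts: dict[str, int] = {}
    for d in diseases:
        dmask = (catalog["disease"] == d).to_numpy()
        sample_counts[d] = int(catalog.loc[dmask, "sample"].nunique())
        hits = assigned[dmask]
        in_bin = hits >= 0
        dropped[d] = int((~in_bin).sum())
        if n_slots:
            counted = np.bincount(hits[in_bin], minlength=n_slots)
            values.loc[d] = counted[values.columns.to_numpy()]
        if per_sample:
            sub = catalog.loc[dmask].assign(bin=hits)
            sub = sub[sub["bin"] >= 0]
            tab = (
                sub.groupby(["sample", "bin"]).size().unstack(fill_value=0)
                .reindex(columns=values.columns, fill_value=0)
            )
            per_sample_tables[d] = tab
    return CountsMatrix(
        values=values,
        sample_counts=sample_counts,
        per_sample=per_sample_tables,
        dropped=dropped,
    )
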