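"""Readers and writers for the standard text formats of the pipeline.

chrom.sizes, BED3/4/12, bedGraph (and bigWig when pyBigWig is
installed), 4-column tabular variant catalogs, VCF, GMT gene sets, and
the deterministic result tables.  Variant positions are 1-based on
input (tabular/VCF) and converted to the internal 0-based convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import BurdenResult, TestRegion

logger = logging.getLogger(__name__)


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chrom<TAB>length text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed chrom.sizes line {ln}")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_bed(path) -> pd.DataFrame:
    """BED3/4 intervals; raises with the line number on malformed input."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {ln}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {ln}") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}: bad coordinates at BED line {ln}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_bed_regions(path) -> list[TestRegion]:
    """BED file as TestRegions; BED12 blocks become multi-interval regions."""
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {ln}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            intervals = None
            if len(parts) >= 12:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                intervals = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            regions.append(
                TestRegion(chrom=chrom, start=start, end=end, name=name, intervals=intervals)
            )
    return regions


def write_bins_bed(bins: pd.DataFrame, path) -> None:
    """Emit training bins as BED4 (name = global bin index)."""
    with open(path, "w") as fh:
        for row in bins.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.index}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph track as a chrom/start/end/value frame."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_track(path, bins: pd.DataFrame | None = None) -> pd.DataFrame:
    """Signal track: bedGraph text, or bigWig (requires pyBigWig)."""
    p = str(path)
    if p.endswith((".bw", ".bigwig", ".bigWig")):
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(p)
        rows = []
        for chrom in bw.chroms():
            for start, end, value in bw.intervals(chrom) or []:
                rows.append((chrom, start, end, value))
        bw.close()
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return read_bedgraph(p)


def read_variants_table(path) -> pd.DataFrame:
    """4-column tabular catalog: chrom, pos (1-based), sample, disease."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos1", "sample", "disease"],
        dtype={"chrom": str, "pos1": np.int64, "sample": str, "disease": str},
    )
    if (df["pos1"] < 1).any():
        raise ValueError("tabular variant positions are 1-based; found pos < 1")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos1"] - 1,
            "sample": df["sample"],
            "disease": df["disease"],
        }
    )


def write_variants_table(catalog: pd.DataFrame, path) -> None:
    out = catalog.copy()
    out["pos"] = out["pos"] + 1
    out[["chrom", "pos", "sample", "disease"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_vcf(path, sample: str, disease: str, pass_only: bool = False) -> pd.DataFrame:
    """Positions-only VCF reader: one catalog row per record.

    FILTER is ignored unless ``pass_only`` is set, in which case only
    records with FILTER PASS (or '.') are kept.
    """
    try:
        from cyvcf2 import VCF  # optional dependency
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        VCF = None
    rows = []
    if VCF is not None:
        for rec in VCF(str(path)):
            if pass_only and rec.FILTER is not None:
                continue
            rows.append((rec.CHROM, rec.POS - 1))
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split("\t")
                if pass_only and parts[6] not in {"PASS", "."}:
                    continue
                rows.append((parts[0], int(parts[1]) - 1))
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in rows],
            "pos": [p for _, p in rows],
            "sample": sample,
            "disease": disease,
        }
    )


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name<TAB>description<TAB>member1<TAB>member2..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed GMT line {ln}")
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


_P_FMT = "%.6g"


def write_result_table(result: BurdenResult, prefix) -> tuple[Path, Path]:
    """Write per-disease and combined burden tables as TSV.

    P-values are serialised with 6 significant digits; ordering is
    deterministic (disease, chrom, start, region).
    """
    prefix = Path(prefix)
    per_path = prefix.with_suffix(".per_disease.tsv")
    comb_path = prefix.with_suffix(".combined.tsv")
    result.per_disease.to_csv(per_path, sep="\t", index=False, float_format=_P_FMT)
    result.combined.to_csv(comb_path, sep="\t", index=False, float_format=_P_FMT)
    return per_path, comb_path


def read_result_table(per_path, comb_path) -> BurdenResult:
    per = pd.read_csv(per_path, sep="\t")
    comb = pd.read_csv(comb_path, sep="\t")
    return BurdenResult(per_disease=per, combined=comb)
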