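"""Gene-annotation handling and derived test sets.

Reads GENCODE-dialect GTF (1-based, closed coordinates on input;
0-based half-open internally), keeps protein-coding genes with KNOWN
status where those attributes exist, merges transcripts into per-gene
exon unions, and derives strand-aware promoter (default 2500 nt
upstream) and TSS (default 100 nt upstream) windows, one per
transcript, deduplicated.  Generic interval intersection supports
TFBS-within-promoter style screens.
"""

from __future__ import annotations

import logging

import gffutils

from .burden import TestRegion
from .intervals import merge_intervals, overlaps

logger = logging.getLogger(__name__)

PROMOTER_LEN = 2500
TSS_LEN = 100


class GeneModel:
    """One gene: strand, attributes and transcript interval lists.

    Coordinates are stored 0-based half-open.  ``transcripts`` maps
    transcript id -> dict with ``start``, ``end`` (transcript span) and
    ``exons`` / ``cds`` interval lists.
    """

    def __init__(self, gene_id, name, chrom, strand, gene_type=None, gene_status=None):
        if strand not in {"+", "-"}:
            raise ValueError(f"gene {gene_id}: strand must be + or -")
        self.gene_id = gene_id
        self.name = name
        self.chrom = chrom
        self.strand = strand
        self.gene_type = gene_type
        self.gene_status = gene_status
        self.transcripts: dict[str, dict] = {}

    def add_transcript(self, tx_id: str, start: int, end: int):
        self.transcripts[tx_id] = {"start": start, "end": end, "exons": [], "cds": []}


def _attr(feature, key):
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def read_gtf(path) -> list[GeneModel]:
    """Parse a GENCODE-style GTF into gene models (all genes, unfiltered)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for tx in db.features_of_type("transcript"):
        gid = _attr(tx, "gene_id")
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid,
                name=_attr(tx, "gene_name") or gid,
                chrom=tx.seqid,
                strand=tx.strand,
                gene_type=_attr(tx, "gene_type"),
                gene_status=_attr(tx, "gene_status"),
            )
        # GTF is 1-based closed; internal coordinates 0-based half-open
        genes[gid].add_transcript(_attr(tx, "transcript_id"), tx.start - 1, tx.end)
    for kind in ("exon", "CDS"):
        key = "cds" if kind == "CDS" else "exons"
        for feat in db.features_of_type(kind):
            gid = _attr(feat, "gene_id")
            txid = _attr(feat, "transcript_id")
            model = genes.get(gid)
            if model is None or txid not in model.transcripts:
                continue
            model.transcripts[txid][key].append((feat.start - 1, feat.end))
    return list(genes.values())


def select_coding_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Protein-coding genes, restricted to KNOWN status when present.

    Annotation dialects that dropped the gene_status attribute pass the
    status filter with a warning.
    """
    have_status = any(g.gene_status is not None for g in genes)
    if not have_status:
        logger.warning("gene_status absent from annotation; skipping KNOWN filter")
    out = []
    for g in genes:
        if g.gene_type is not None and g.gene_type != "protein_coding":
            continue
        if have_status and g.gene_status is not None and g.gene_status != "KNOWN":
            continue
        out.append(g)
    return out


def merge_transcripts(gene: GeneModel, cds_only: bool = False) -> list[tuple[int, int]]:
    """Union of exon (or CDS) intervals across all transcripts.

    Transcripts without recorded exons contribute their full span.
    Returns sorted, non-overlapping half-open intervals; a gene with no
    transcripts is skipped (empty list) with a warning.
    """
    if not gene.transcripts:
        logger.warning("gene %s has no transcripts; skipped", gene.gene_id)
        return []
    key = "cds" if cds_only else "exons"
    pieces = []
    for tx in gene.transcripts.values():
        ivs = tx[key]
        if not ivs and not cds_only:
            ivs = [(tx["start"], tx["end"])]
        pieces.extend(ivs)
    return merge_intervals(pieces) if pieces else []


def gene_region(gene: GeneModel, cds_only: bool = False) -> TestRegion | None:
    """Merged-transcript TestRegion for one gene (None when empty)."""
    ivs = merge_transcripts(gene, cds_only=cds_only)
    if not ivs:
        return None
    return TestRegion(
        chrom=gene.chrom,
        start=ivs[0][0],
        end=ivs[-1][1],
        name=gene.name,
        intervals=ivs,
    )


def derive_promoters_tss(
    genes: list[GeneModel],
    promoter_len: int = PROMOTER_LEN,
    tss_len: int = TSS_LEN,
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[list[TestRegion], list[TestRegion]]:
    """Strand-aware upstream windows, one per transcript, deduplicated.

    For a transcript on the + strand starting at 0-based position ``t0``
    the window of length L is ``[t0 - L, t0)``; on the - strand with
    transcript end ``t1`` (half-open) it is ``[t1, t1 + L)``.  Windows
    are clipped at chromosome bounds with a warning.
    """

    def windows(length: int) -> list[TestRegion]:
        seen = set()
        out = []
        for g in genes:
            for tx_id, tx in g.transcripts.items():
                if g.strand == "+":
                    start, end = tx["start"] - length, tx["start"]
                else:
                    start, end = tx["end"], tx["end"] + length
                if start < 0:
                    logger.warning("window for %s clipped at chromosome start", tx_id)
                    start = 0
                if chrom_sizes is not None:
                    size = chrom_sizes.get(g.chrom)
                    if size is not None and end > size:
                        logger.warning("window for %s clipped at chromosome end", tx_id)
                        end = size
                if end <= start:
                    continue
                key = (g.chrom, start, end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    TestRegion(chrom=g.chrom, start=start, end=end, name=f"{g.name}:{tx_id}")
                )
        return out

    return windows(promoter_len), windows(tss_len)


def intersect_regions(
    a: list[TestRegion], b: list[TestRegion], mode: str = "overlap"
) -> list[TestRegion]:
    """Elements of ``a`` that overlap (>= 1 bp) or lie within ``b``."""
    if mode not in {"overlap", "within"}:
        raise ValueError("mode must be 'overlap' or 'within'")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in b:
        by_chrom.setdefault(r.chrom, []).extend(r.intervals)
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    out = []
    for r in a:
        blocks = merged.get(r.chrom, [])
        if mode == "overlap":
            hit = any(
                overlaps(s, e, bs, be)
                for s, e in r.intervals
                for bs, be in blocks
            )
        else:
            hit = all(
                any(bs <= s and e <= be for bs, be in blocks) for s, e in r.intervals
            )
        if hit:
            out.append(r)
    return out
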