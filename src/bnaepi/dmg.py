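"""Gene-level annotation of DMRs and metaplot profiling of gene regions.

A differentially methylated gene (DMG) is a gene whose body or 2.0-kb
promoter overlaps a DMR by at least one base; overlaps confined to the
2.0-kb downstream flank do not qualify.  Functional regions are strand
aware: the promoter abuts the transcription start on the gene's 5' side
(coordinates above the gene end for minus-strand genes), the downstream
flank abuts the transcription end on the 3' side, and introns are the gene
body minus its exons.

Metaplots divide each functional region into 20 equal bins (computed on
fractional coordinates so all bins are equal width to within one base),
pool coverage-filtered site levels over genes per context and condition,
and orient every region 5'→3' relative to its gene's strand.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation import CONTEXTS, add_levels

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2_000
REGION_KINDS = ("promoter", "body", "downstream", "exon", "intron")


def functional_regions(
    gene: Mapping,
    flank: int = DEFAULT_FLANK,
    chrom_length: int | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Strand-aware promoter/body/downstream/exon/intron intervals of a gene.

    Intervals are 1-based inclusive, in genomic order within each kind.
    Regions are clipped at chromosome boundaries (with a warning); a
    single-exon gene has an empty intron set.
    """
    start, end, strand = int(gene["start"]), int(gene["end"]), gene["strand"]
    exons = [(int(s), int(e)) for s, e in gene["exons"]]
    if strand == "+":
        promoter = (start - flank, start - 1)
        downstream = (end + 1, end + flank)
    else:
        promoter = (end + 1, end + flank)
        downstream = (start - flank, start - 1)

    def clip(iv):
        s, e = iv
        cs = max(1, s)
        ce = min(chrom_length, e) if chrom_length is not None else e
        if (cs, ce) != (s, e):
            logger.warning(
                "region of gene %s clipped at chromosome edge", gene["gene_id"]
            )
        return (cs, ce) if cs <= ce else None

    introns = []
    prev_end = start - 1
    for s, e in sorted(exons):
        if s > prev_end + 1:
            introns.append((prev_end + 1, s - 1))
        prev_end = e
    if prev_end < end:
        introns.append((prev_end + 1, end))

    regions = {
        "promoter": [clip(promoter)],
        "body": [(start, end)],
        "downstream": [clip(downstream)],
        "exon": sorted(exons),
        "intron": introns,
    }
    return {k: [iv for iv in v if iv is not None] for k, v in regions.items()}


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def assign_dmgs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map DMRs to genes by ≥1-base overlap with promoter or gene body.

    Returns (dmg table, counts).  The table has one row per (gene, DMR)
    association with the overlap kind (promoter, body or promoter+body) and
    the DMR's direction.  A gene hit by several DMRs appears in one gene's
    count once per direction; ``counts`` reports hyper and hypo gene counts
    (a dual-direction gene contributes to both), their sum, and the number
    of distinct genes.
    """
    rows = []
    for g_idx, gene in genes.iterrows():
        regions = functional_regions(gene, flank)
        promoter = regions["promoter"]
        body = (int(gene["start"]), int(gene["end"]))
        on_chrom = dmrs[dmrs["chrom"] == gene["chrom"]]
        for d_idx, dmr in on_chrom.iterrows():
            in_prom = any(
                _overlaps(dmr["start"], dmr["end"], s, e) for s, e in promoter
            )
            in_body = _overlaps(dmr["start"], dmr["end"], body[0], body[1])
            if not (in_prom or in_body):
                continue
            kind = ("promoter+body" if in_prom and in_body
                    else "promoter" if in_prom else "body")
            rows.append((gene["gene_id"], d_idx, kind, dmr["direction"]))
    table = pd.DataFrame(rows, columns=["gene_id", "dmr_index", "kind",
                                        "direction"])
    hyper = table.loc[table["direction"] == "hyper", "gene_id"].nunique()
    hypo = table.loc[table["direction"] == "hypo", "gene_id"].nunique()
    counts = {
        "hyper": int(hyper),
        "hypo": int(hypo),
        "directional_total": int(hyper + hypo),
        "unique_genes": int(table["gene_id"].nunique()),
    }
    return table, counts


def metaplot(
    report_0h: pd.DataFrame,
    report_72h: pd.DataFrame,
    genes: pd.DataFrame,
    n_bins: int = 20,
    flank: int = DEFAULT_FLANK,
    min_coverage: int = 3,
    region_kinds: Sequence[str] = REGION_KINDS,
) -> pd.DataFrame:
    """Binned mean methylation level per region kind, context and condition.

    Each gene region (promoter, body, downstream, exon chain, intron chain)
    is scaled to ``n_bins`` equal bins oriented 5'→3' on the gene's strand;
    covered site levels are pooled over genes.  Genes whose region chain is
    shorter than ``n_bins`` bases are skipped for that region.  Returns a
    long frame (region, context, condition, bin, mean_level, n_sites) with
    exactly ``n_bins`` bins per (region, context, condition), NaN where no
    site fell in a bin.
    """
    levels = {
        "0h": add_levels(report_0h, min_coverage),
        "72h": add_levels(report_72h, min_coverage),
    }
    # per (condition, chrom): sorted positions with context code and level
    indexed: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for cond, lv in levels.items():
        for chrom, sub in lv.groupby("chrom", observed=True):
            sub = sub.sort_values("pos")
            indexed[(cond, chrom)] = (
                sub["pos"].to_numpy(),
                sub["context"].to_numpy(),
                sub["level"].to_numpy(),
            )

    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    n_skipped = 0
    for _, gene in genes.iterrows():
        regions = functional_regions(gene, flank)
        for kind in region_kinds:
            chain = regions[kind]
            total = sum(e - s + 1 for s, e in chain)
            if total < n_bins or total == 0:
                n_skipped += 1
                continue
            for cond in ("0h", "72h"):
                key = (cond, gene["chrom"])
                if key not in indexed:
                    continue
                pos, ctx, lvl = indexed[key]
                offset = 0
                for s, e in chain:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    if hi > lo:
                        frac_pos = offset + (pos[lo:hi] - s)
                        if gene["strand"] == "-":
                            frac = (total - 1 - frac_pos) / total
                        else:
                            frac = frac_pos / total
                        b = np.minimum((frac * n_bins).astype(int), n_bins - 1)
                        for bi, ci, li in zip(b, ctx[lo:hi], lvl[lo:hi]):
                            k = (kind, ci, cond, int(bi))
                            sums[k] = sums.get(k, 0.0) + li
                            counts[k] = counts.get(k, 0) + 1
                    offset += e - s + 1
    if n_skipped:
        logger.info("skipped %d gene regions shorter than %d bases",
                    n_skipped, n_bins)

    rows = []
    for kind in region_kinds:
        for ctx in CONTEXTS:
            for cond in ("0h", "72h"):
                for bi in range(n_bins):
                    k = (kind, ctx, cond, bi)
                    n = counts.get(k, 0)
                    mean = sums[k] / n if n else np.nan
                    rows.append((kind, ctx, cond, bi, mean, n))
    return pd.DataFrame(
        rows,
        columns=["region", "context", "condition", "bin", "mean_level",
                 "n_sites"],
    )


# ---------------------------------------------------------------------------
# gene-model I/O

def read_gene_models(path) -> pd.DataFrame:
    """Read the tab-separated gene-model table written by the simulator."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    exons = []
    for starts, ends in zip(df["exon_starts"], df["exon_ends"]):
        ss = [int(x) for x in str(starts).split(",")]
        ee = [int(x) for x in str(ends).split(",")]
        exons.append(list(zip(ss, ee)))
    df = df.drop(columns=["exon_starts", "exon_ends"])
    df["exons"] = exons
    return df


def read_gff3(path, source: str = "gff3") -> pd.DataFrame:
    """Convert GFF3 gene/exon features to the internal 1-based gene frame."""
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                      dtype={"chrom": str})

    def attr(s, key):
        for part in str(s).split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return None

    genes = raw[raw["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].map(lambda s: attr(s, "ID"))
    exons = raw[raw["type"] == "exon"].copy()
    exons["parent"] = exons["attributes"].map(lambda s: attr(s, "Parent"))

    out = []
    for _, g in genes.iterrows():
        ex = exons[exons["parent"] == g["gene_id"]]
        ivs = sorted(zip(ex["start"].astype(int), ex["end"].astype(int)))
        if not ivs:
            ivs = [(int(g["start"]), int(g["end"]))]
        out.append({
            "gene_id": g["gene_id"],
            "chrom": g["chrom"],
            "source": source,
            "start": int(g["start"]),
            "end": int(g["end"]),
            "strand": g["strand"],
            "subgenome": "",
            "exons": ivs,
        })
    return pd.DataFrame(out)
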