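"""Cytosine-report handling and genome-wide methylation summaries.

Whole-genome bisulfite sequencing yields, per cytosine, a count of reads
calling it methylated (mC) and unmethylated (umC).  This module parses and
emits Bismark CX-report-style tables, classifies cytosines into the three
plant sequence contexts (CG, CHG, CHH; H = A, T or C, read on the cytosine's
own strand), computes coverage-filtered methylation levels
ML = mC / (mC + umC), estimates the bisulfite non-conversion rate from an
unmethylated lambda spike-in, and aggregates levels into chromosome-,
subgenome-, context- and fixed-window summaries.

Coordinates are 1-based inclusive throughout; windows are fixed
(non-sliding) tiles.  CG cytosines on opposite strands are kept as separate
observations.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from ._sequences import COMPLEMENT_BYTES

logger = logging.getLogger(__name__)

#: column order of the CX-report dialect read and written by this module
CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]

CONTEXTS = ("CG", "CHG", "CHH")

#: name of the unmethylated spike-in contig used as conversion control
LAMBDA_CONTIG = "lambda_control"


def subgenome_of(chrom: str) -> str:
    """Subgenome label for a chromosome name (A_n, C_n or control).

    Chromosome names beginning with ``A``/``C`` (optionally prefixed with
    ``chr``) are assigned to the A_n and C_n subgenomes of allotetraploid
    *B. napus*; anything else (e.g. the lambda control contig) is ``control``.
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name[:1].upper() == "A":
        return "A_n"
    if name[:1].upper() == "C":
        return "C_n"
    return "control"


def call_cytosine_contexts(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of a genome.

    Each C on the forward strand, and each G on the forward strand (a C on
    the reverse complement), is classified by the two bases downstream on
    its own strand: CG if the next base is G, CHG if the base after next is
    G, else CHH.  Cytosines whose downstream dinucleotide runs off the
    chromosome end or contains N are unclassifiable and omitted (logged).

    Returns a frame with columns chrom, pos (1-based), strand, context,
    trinucleotide, sorted by (chrom, pos, strand).
    """
    frames = []
    n_dropped = 0
    for chrom in seqs:
        b = np.frombuffer(seqs[chrom].upper().encode("ascii"), dtype=np.uint8)
        n = len(b)
        C, G, N = ord("C"), ord("G"), ord("N")

        # forward strand: C at i with downstream b[i+1], b[i+2]
        idx = np.nonzero(b == C)[0]
        n_dropped += int(np.sum(idx > n - 3))
        idx = idx[idx <= n - 3]
        n1, n2 = b[idx + 1], b[idx + 2]
        ok = (n1 != N) & (n2 != N)
        n_dropped += int(np.sum(~ok))
        idx, n1, n2 = idx[ok], n1[ok], n2[ok]
        ctx_f = np.where(n1 == G, "CG", np.where(n2 == G, "CHG", "CHH"))
        tri_f = _tri_strings(b[idx], n1, n2)

        # reverse strand: G at i; downstream on the minus strand are the
        # complements of b[i-1], b[i-2]
        jdx = np.nonzero(b == G)[0]
        n_dropped += int(np.sum(jdx < 2))
        jdx = jdx[jdx >= 2]
        p1, p2 = b[jdx - 1], b[jdx - 2]
        ok = (p1 != N) & (p2 != N)
        n_dropped += int(np.sum(~ok))
        jdx, p1, p2 = jdx[ok], p1[ok], p2[ok]
        ctx_r = np.where(p1 == C, "CG", np.where(p2 == C, "CHG", "CHH"))
        tri_r = _tri_strings(
            COMPLEMENT_BYTES[b[jdx]], COMPLEMENT_BYTES[p1], COMPLEMENT_BYTES[p2]
        )

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([idx, jdx]) + 1,
                    "strand": np.repeat(["+", "-"], [len(idx), len(jdx)]),
                    "context": np.concatenate([ctx_f, ctx_r]),
                    "trinucleotide": np.concatenate([tri_f, tri_r]),
                }
            )
        )
    if n_dropped:
        logger.info("dropped %d unclassifiable cytosines (edge or N)", n_dropped)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "trinucleotide"]
    )
    return out.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def _tri_strings(b0: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    stacked = np.stack([b0, b1, b2], axis=1).astype(np.uint8)
    return np.frombuffer(stacked.tobytes(), dtype="S3").astype("U3")


def read_cx_report(path) -> pd.DataFrame:
    """Read a CX-report TSV (7 columns, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=CX_COLUMNS,
                     dtype={"chrom": str, "strand": str, "context": str,
                            "trinucleotide": str})
    return df


def write_cx_report(report: pd.DataFrame, path) -> None:
    """Write a CX-report TSV; field order and strand symbols are preserved."""
    report[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def methylation_level(mc: int, umc: int, min_coverage: int = 3) -> float | None:
    """ML = mC/(mC+umC) if total coverage reaches ``min_coverage``, else None.

    Sites below the coverage filter are excluded from all downstream
    statistics; zero total coverage never raises.
    """
    total = mc + umc
    if total < min_coverage or total == 0:
        return None
    return mc / total


def add_levels(report: pd.DataFrame, min_coverage: int = 3) -> pd.DataFrame:
    """Vectorized methylation level; rows failing the coverage filter dropped."""
    total = report["count_methylated"] + report["count_unmethylated"]
    keep = (total >= min_coverage) & (total > 0)
    out = report.loc[keep].copy()
    out["level"] = out["count_methylated"] / total[keep]
    return out


def nonconversion_rate(report: pd.DataFrame, contig: str = LAMBDA_CONTIG) -> float:
    """Bisulfite non-conversion rate from the unmethylated spike-in.

    Pooled Σ mC / Σ (mC + umC) over every cytosine of the control contig,
    with no coverage filter.  Raises if the control contig is absent.
    """
    lam = report[report["chrom"] == contig]
    if lam.empty:
        raise ValueError(f"no cytosines on control contig {contig!r}: "
                         "conversion control missing from report")
    total = int(lam["count_methylated"].sum() + lam["count_unmethylated"].sum())
    if total == 0:
        raise ValueError(f"control contig {contig!r} has zero coverage")
    return float(lam["count_methylated"].sum()) / total


def summarize(
    report: pd.DataFrame,
    grouping: str = "context",
    min_coverage: int = 3,
    exclude_control: bool = True,
) -> pd.DataFrame:
    """Mean per-site methylation level by chromosome, subgenome or context.

    Context is kept as a stratifier in every grouping.  Groups with no
    covered sites get n_sites = 0 and NaN mean.
    """
    if grouping not in ("chromosome", "subgenome", "context"):
        raise ValueError(f"unknown grouping {grouping!r}")
    lv = add_levels(report, min_coverage)
    if exclude_control:
        lv = lv[lv["chrom"] != LAMBDA_CONTIG]
    if lv.empty:
        raise ValueError("no sites pass the coverage filter")
    if grouping == "chromosome":
        lv = lv.assign(group=lv["chrom"])
    elif grouping == "subgenome":
        lv = lv.assign(group=lv["chrom"].map(subgenome_of))
    else:
        lv = lv.assign(group=lv["context"])
    out = (
        lv.groupby(["group", "context"], observed=True)["level"]
        .agg(mean_level="mean", n_sites="size")
        .reset_index()
    )
    return out


def density_tracks(
    report: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    unit: int = 50_000,
    min_coverage: int = 3,
) -> pd.DataFrame:
    """Per-window methylated-cytosine density and mean level per context.

    Chromosomes are tiled into fixed windows [1, unit], [unit+1, 2·unit], …
    (1-based inclusive); the last partial window is kept.  Windows with no
    covered sites report density 0 and NaN mean.
    """
    if unit <= 0:
        raise ValueError("unit must be positive")
    lv = add_levels(report, min_coverage)
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // unit))
        sub = lv[lv["chrom"] == chrom]
        win = (sub["pos"] - 1) // unit
        grouped = sub.groupby([win, "context"], observed=True)["level"].agg(
            ["size", "mean"]
        )
        for w in range(n_win):
            start = w * unit + 1
            end = min((w + 1) * unit, length)
            for ctx in CONTEXTS:
                if (w, ctx) in grouped.index:
                    size, mean = grouped.loc[(w, ctx)]
                else:
                    size, mean = 0, np.nan
                rows.append((chrom, start, end, ctx, int(size), mean))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "density", "mean_level"]
    )


def write_bedgraph(tracks: pd.DataFrame, path, value: str = "mean_level") -> None:
    """Export window tracks as BEDGraph (0-based half-open on export)."""
    out = tracks.dropna(subset=[value]).copy()
    out["start0"] = out["start"] - 1
    out[["chrom", "start0", "end", value]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fasta(path) -> dict[str, str]:
    """Genome FASTA into a name→sequence mapping (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
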