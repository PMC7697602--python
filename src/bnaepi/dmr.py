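"""Differential-methylation calling between nitrogen sufficiency and limitation.

The procedure compares two single-library methylomes (0 h = N sufficiency,
72 h = N limitation).  Per cytosine, a fold change of the two methylation
ratios (with a small pseudocount) flags differential sites at the 1.2-fold
threshold, two-sided.  The genome is then tiled into fixed bins per context;
within each bin the per-site levels of the two conditions form two groups
compared by the tie-corrected Kruskal–Wallis rank-sum test (chi-square
approximation, 1 df for two groups — asymptotically the two-sided
Mann–Whitney test).  p-values are Benjamini–Hochberg adjusted within each
context family; bins with q below alpha and enough concordant differential
sites are reported as DMRs, with boundaries trimmed to the first/last
differential site and direction assigned from the mean levels: hyper when
methylation is higher under N limitation than under N sufficiency, hypo
otherwise.

All DMR coordinates are 1-based inclusive, so length = end − start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import CONTEXTS, add_levels

DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_PSEUDO = 0.01

DMR_COLUMNS = ["chrom", "start", "end", "length", "ml_72h", "ml_0h",
               "direction", "context", "n_sites", "n_differential", "p", "q"]


def site_fold_change(
    ml_72h: float,
    ml_0h: float,
    pseudo: float = DEFAULT_PSEUDO,
    threshold: float = DEFAULT_FC_THRESHOLD,
) -> tuple[float, bool, str]:
    """Per-site methylation fold change and differential call.

    fold_change = (ml_72h + pseudo) / (ml_0h + pseudo); the site is
    differential when the change exceeds the threshold in either direction
    (> threshold or < 1/threshold).  Direction follows the sign of
    ml_72h − ml_0h.  Returns (fold_change, is_differential, direction).
    """
    fc = (ml_72h + pseudo) / (ml_0h + pseudo)
    differential = fc > threshold or fc < 1.0 / threshold
    if not differential:
        direction = "none"
    else:
        direction = "hyper" if ml_72h > ml_0h else "hypo"
    return fc, differential, direction


def site_differentials(
    report_0h: pd.DataFrame,
    report_72h: pd.DataFrame,
    min_coverage: int = 3,
    pseudo: float = DEFAULT_PSEUDO,
    threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Join the two condition reports on jointly covered sites.

    The coverage filter applies per condition; a site enters the
    differential analysis only if it passes in both.  Returns one row per
    joint site with ml_0h, ml_72h, fold_change, is_differential, direction.
    """
    a = add_levels(report_0h, min_coverage)[
        ["chrom", "pos", "strand", "context", "level"]
    ].rename(columns={"level": "ml_0h"})
    b = add_levels(report_72h, min_coverage)[
        ["chrom", "pos", "strand", "level"]
    ].rename(columns={"level": "ml_72h"})
    joint = a.merge(b, on=["chrom", "pos", "strand"], how="inner")
    fc = (joint["ml_72h"] + pseudo) / (joint["ml_0h"] + pseudo)
    joint["fold_change"] = fc
    joint["is_differential"] = (fc > threshold) | (fc < 1.0 / threshold)
    joint["direction"] = np.where(
        ~joint["is_differential"],
        "none",
        np.where(joint["ml_72h"] > joint["ml_0h"], "hyper", "hypo"),
    )
    return joint


@dataclass
class Bin:
    """A fixed genomic tile of one context with paired per-site levels."""

    chrom: str
    start: int
    end: int
    context: str
    positions: np.ndarray
    ml_0h: np.ndarray
    ml_72h: np.ndarray
    is_differential: np.ndarray
    direction: np.ndarray
    p: float = field(default=np.nan)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def make_bins(
    differentials: pd.DataFrame,
    bin_size: int = 100,
    min_sites: int = 5,
) -> list[Bin]:
    """Tile jointly covered sites into fixed per-context bins.

    Bin frames are [1, bin_size], [bin_size+1, 2·bin_size], … per
    chromosome; a (frame, context) bin is retained only if it holds at
    least ``min_sites`` jointly covered sites of that context.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    d = differentials
    frame = (d["pos"] - 1) // bin_size
    bins: list[Bin] = []
    for (chrom, w, ctx), grp in d.groupby(
        [d["chrom"], frame, d["context"]], observed=True, sort=True
    ):
        if len(grp) < min_sites:
            continue
        grp = grp.sort_values("pos")
        bins.append(
            Bin(
                chrom=chrom,
                start=int(w) * bin_size + 1,
                end=(int(w) + 1) * bin_size,
                context=ctx,
                positions=grp["pos"].to_numpy(),
                ml_0h=grp["ml_0h"].to_numpy(),
                ml_72h=grp["ml_72h"].to_numpy(),
                is_differential=grp["is_differential"].to_numpy(),
                direction=grp["direction"].to_numpy(),
            )
        )
    return bins


def kruskal_wallis_bin_test(ml_0h, ml_72h) -> float:
    """Tie-corrected Kruskal–Wallis p for the two condition groups of a bin.

    With two groups this is the chi-square (1 df) approximation and agrees
    asymptotically with the two-sided Mann–Whitney rank-sum test.  If every
    value is identical across both groups there is no rank information and
    p = 1.
    """
    a = np.asarray(ml_0h, dtype=float)
    b = np.asarray(ml_72h, dtype=float)
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(stats.kruskal(a, b).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    bins: list[Bin],
    alpha: float = 0.05,
    min_differential_sites: int = 3,
) -> pd.DataFrame:
    """Test bins, adjust within context, and emit directional DMRs.

    A bin becomes a DMR when its BH-adjusted p is below ``alpha`` and at
    least ``min_differential_sites`` of its sites are flagged differential
    in the majority direction.  DMR boundaries are trimmed to the first and
    last differential site, which yields sub-bin lengths; direction is
    hyper when the mean level at 0 h is below the mean at 72 h, else hypo.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for b in bins:
        if np.isnan(b.p):
            b.p = kruskal_wallis_bin_test(b.ml_0h, b.ml_72h)

    rows = []
    for ctx in CONTEXTS:
        ctx_bins = [b for b in bins if b.context == ctx]
        if not ctx_bins:
            continue
        q = bh_adjust([b.p for b in ctx_bins])
        for b, qv in zip(ctx_bins, q):
            if qv >= alpha:
                continue
            diff_dirs = b.direction[b.is_differential]
            if len(diff_dirs) == 0:
                continue
            n_hyper = int(np.sum(diff_dirs == "hyper"))
            n_hypo = len(diff_dirs) - n_hyper
            if max(n_hyper, n_hypo) < min_differential_sites:
                continue
            diff_pos = b.positions[b.is_differential]
            start, end = int(diff_pos.min()), int(diff_pos.max())
            ml0, ml72 = float(b.ml_0h.mean()), float(b.ml_72h.mean())
            direction = "hyper" if ml0 < ml72 else "hypo"
            rows.append(
                (b.chrom, start, end, end - start + 1, ml72, ml0, direction,
                 b.context, b.n_sites, len(diff_dirs), b.p, qv)
            )
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def call_dmrs_from_reports(
    report_0h: pd.DataFrame,
    report_72h: pd.DataFrame,
    min_coverage: int = 3,
    bin_size: int = 100,
    min_sites: int = 5,
    alpha: float = 0.05,
    min_differential_sites: int = 3,
    pseudo: float = DEFAULT_PSEUDO,
    threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.DataFrame:
    """Full site→bin→test→DMR pipeline on a pair of CX reports."""
    diffs = site_differentials(report_0h, report_72h, min_coverage, pseudo,
                               threshold)
    bins = make_bins(diffs, bin_size, min_sites)
    return call_dmrs(bins, alpha, min_differential_sites)


def write_dmrs(dmrs: pd.DataFrame, path) -> None:
    """DMR table as TSV, 1-based inclusive coordinates."""
    dmrs.to_csv(path, sep="\t", index=False)


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """Optional 0-based half-open BED export."""
    out = dmrs.copy()
    out["start0"] = out["start"] - 1
    out["name"] = out["context"] + "_" + out["direction"]
    out[["chrom", "start0", "end", "name", "q"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# reference DMR table at N-metabolism genes

def load_reference_dmrs() -> pd.DataFrame:
    """Published DMRs at key nitrogen-metabolism genes in shoots and roots.

    Sixteen curated rapeseed DMRs (coordinates, lengths, methylation levels
    in both conditions, printed hyper/hypo label, context, gene annotation)
    used to validate the coordinate convention and the direction rule.
    """
    ref = resources.files("bnaepi").joinpath("data/reference_dmrs.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def validate_reference_dmrs(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Check each reference DMR row against the coordinate and direction rules.

    Adds ``length_ok`` (end − start + 1 equals the printed length),
    ``expected_direction`` (hyper iff ml_0h < ml_72h) and
    ``direction_consistent`` (printed label matches the rule).  Rows with
    ``direction_consistent == False`` are internally inconsistent in the
    source table and are surfaced rather than silently corrected.
    """
    t = (table if table is not None else load_reference_dmrs()).copy()
    t["length_ok"] = (t["end"] - t["start"] + 1) == t["length"]
    t["expected_direction"] = np.where(t["ml_0h"] < t["ml_72h"], "hyper", "hypo")
    t["direction_consistent"] = t["expected_direction"] == t["direction"]
    return t
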