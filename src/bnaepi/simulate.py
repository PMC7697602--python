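"""Synthetic study generator: genomes, methylomes, small-RNA counts, degradomes.

The downstream statistics in this package were developed against data that
are not publicly deposited, so every stage is exercised on synthetic inputs
with known ground truth.  The generator emulates the study design: two
conditions (0 h = nitrogen sufficiency, 72 h = nitrogen limitation) sampled
in shoot and root tissue; an allotetraploid genome with A_n and C_n
subgenome chromosomes where the A_n subgenome is methylated at a lower mean
level; context-dependent mean methylation (CG > CHG > CHH); planted
differentially methylated regions with known sign; beta-binomial count
noise around ~30x coverage; an unmethylated lambda spike-in contig for the
non-conversion control; negative-binomially distributed miRNA counts in
three biological replicates with planted log2 effects and a configurable
first-base bias toward uridine; and degradome 5'-end tag profiles with a
single dominant peak at the planted cleavage position.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._sequences import random_seq, revcomp, to_rna
from .methylation import (
    LAMBDA_CONTIG,
    call_cytosine_contexts,
    subgenome_of,
    write_cx_report,
    write_fasta,
)

# fixed per-stage stream keys so each stage is independently reproducible
_STREAMS = {"genome": 11, "meth_0h": 12, "meth_72h": 13, "mirna": 14,
            "transcripts": 15, "degradome": 16}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stage]])


@dataclass
class PlantedDMR:
    """Ground-truth differentially methylated interval (1-based inclusive).

    ``delta`` is the signed level difference (72 h − 0 h) added to the site
    mean inside the interval in the limitation condition only.
    """

    chrom: str
    start: int
    end: int
    context: str
    delta: float

    def __post_init__(self):
        if self.delta == 0:
            raise ValueError("planted DMR must have nonzero delta")
        if self.end < self.start or self.start < 1:
            raise ValueError("invalid planted DMR interval")


@dataclass
class PlantedMiRNA:
    """Ground-truth miRNA with planted differential-expression effect."""

    name: str
    length: int = 21
    log2_effect: float = 0.0
    base_mean: float = 100.0

    def __post_init__(self):
        if not 18 <= self.length <= 30:
            raise ValueError("miRNA length must be in [18, 30] nt")
        if self.base_mean < 0:
            raise ValueError("base_mean must be nonnegative")


@dataclass
class PlantedCleavage:
    """Ground-truth miRNA cleavage site on a synthetic transcript.

    ``site_start`` is the 1-based transcript position of the 5'-most base of
    the duplex window (the base paired to the miRNA 3' end).
    """

    mirna_name: str
    transcript_id: str
    site_start: int
    n_wobbles: int = 0
    n_mismatches: int = 0
    peak_reads: int = 50

    def __post_init__(self):
        if self.peak_reads < 1:
            raise ValueError("peak_reads must be >= 1")
        if self.site_start < 1:
            raise ValueError("site_start must be >= 1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults are the study conditions the package is tested under:
    30x mean coverage, context means ordered CG > CHG > CHH, the A_n
    subgenome offset below C_n, beta-binomial overdispersion rho = 0.05, a
    ~0.5% bisulfite non-conversion rate on the lambda contig, three small-RNA
    replicates per condition, and a 0.6 first-base bias toward uridine.
    """

    seed: int = 1
    n_chromosomes: int = 1            # per subgenome
    chromosome_length: int = 50_000
    n_genes: int = 20
    coverage_mean: float = 30.0
    context_means: dict = field(
        default_factory=lambda: {"CG": 0.55, "CHG": 0.25, "CHH": 0.10}
    )
    subgenome_offset: float = 0.05    # A_n mean sits this far below C_n
    overdispersion: float = 0.05      # beta-binomial rho
    non_conversion: float = 0.005
    lambda_length: int = 2_000
    dmr_plan: list = field(default_factory=list)
    mirna_plan: list = field(default_factory=list)
    cleavage_plan: list = field(default_factory=list)
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    first_base_bias: float = 0.6
    transcript_length: int = 300

    def validate(self) -> None:
        for ctx, m in self.context_means.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"context mean for {ctx} outside [0, 1]")
        if not 0.0 <= self.non_conversion <= 1.0:
            raise ValueError("non_conversion outside [0, 1]")
        if self.dmr_plan:
            longest = max(d.end - d.start + 1 for d in self.dmr_plan)
            if self.chromosome_length < 10 * longest:
                raise ValueError(
                    "chromosome_length must be >= 10x the largest planted DMR"
                )
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.overdispersion < 0 or self.overdispersion >= 1:
            raise ValueError("overdispersion rho must be in [0, 1)")


# ---------------------------------------------------------------------------
# genome and gene models

def simulate_genome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with A_n/C_n chromosomes, a lambda contig, and genes.

    Chromosomes are named A01.., C01..; genes are non-overlapping, strand
    assigned, with 1–4 exons each.  Returns (sequences, gene table); the
    gene table has one row per gene with exon structure as python lists.
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    seqs: dict[str, str] = {}
    for sub in ("A", "C"):
        for i in range(config.n_chromosomes):
            seqs[f"{sub}{i + 1:02d}"] = random_seq(rng, config.chromosome_length)
    seqs[LAMBDA_CONTIG] = random_seq(rng, config.lambda_length)

    chroms = [c for c in seqs if c != LAMBDA_CONTIG]
    genes = []
    per_chrom = np.array_split(np.arange(config.n_genes), len(chroms))
    for chrom, gene_ids in zip(chroms, per_chrom):
        k = len(gene_ids)
        if k == 0:
            continue
        # each gene needs its body plus clear flanks; place sequentially
        slot = config.chromosome_length // k
        if slot < 1_200:
            raise ValueError(
                f"chromosome {chrom} too short for {k} genes: "
                f"{config.chromosome_length} bp"
            )
        for j, g in enumerate(gene_ids):
            body_len = int(rng.integers(600, min(2_000, slot - 400)))
            lo = j * slot + 200
            hi = (j + 1) * slot - body_len - 200
            start = int(rng.integers(lo, max(lo + 1, hi)))
            end = start + body_len - 1
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _split_exons(rng, start, end)
            genes.append(
                {
                    "gene_id": f"BnaSYN{g + 1:04d}",
                    "chrom": chrom,
                    "source": "bnaepi_sim",
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "subgenome": subgenome_of(chrom),
                    "exons": exons,
                }
            )
    cols = ["gene_id", "chrom", "source", "start", "end", "strand",
            "subgenome", "exons"]
    gene_df = pd.DataFrame(genes, columns=cols)
    return seqs, gene_df


def _split_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    """Partition [start, end] into 1–4 exons separated by introns."""
    length = end - start + 1
    n_exons = int(rng.integers(1, 5))
    if n_exons == 1 or length < n_exons * 120:
        return [(start, end)]
    # 2*n_exons - 1 alternating segments (exon, intron, ..., exon)
    n_seg = 2 * n_exons - 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    exons = []
    for i in range(0, n_seg, 2):
        s = start + int(bounds[i])
        e = start + int(bounds[i + 1]) - 1
        if e >= s:
            exons.append((s, e))
    exons[0] = (start, exons[0][1])
    exons[-1] = (exons[-1][0], end)
    return exons


# ---------------------------------------------------------------------------
# methylome

def simulate_methylome(
    genome: Mapping[str, str],
    config: SimulationConfig,
    condition: str,
) -> pd.DataFrame:
    """Per-cytosine CX report for one condition ("0h" or "72h").

    Every cytosine on both strands gets its context from the sequence,
    Poisson coverage around ``coverage_mean``, and a beta-binomial
    methylated count around the context/subgenome mean — shifted by the
    planted delta inside planted DMR intervals in the 72 h condition only.
    The lambda contig draws plain binomial counts at the non-conversion
    rate (the spike-in is unmethylated by construction).
    """
    if condition not in ("0h", "72h"):
        raise ValueError("condition must be '0h' or '72h'")
    config.validate()
    for dmr in config.dmr_plan:
        if dmr.chrom not in genome:
            raise ValueError(f"planted DMR chrom {dmr.chrom!r} not in genome")
        if dmr.end > len(genome[dmr.chrom]):
            raise ValueError(f"planted DMR {dmr.chrom}:{dmr.start}-{dmr.end} "
                             "outside chromosome")
    rng = _rng(config.seed, f"meth_{condition}")

    sites = call_cytosine_contexts(genome)
    mean = np.empty(len(sites))
    is_lambda = (sites["chrom"] == LAMBDA_CONTIG).to_numpy()
    for ctx, m in config.context_means.items():
        mean[(sites["context"] == ctx).to_numpy()] = m
    sub = sites["chrom"].map(subgenome_of).to_numpy()
    mean[sub == "A_n"] -= config.subgenome_offset
    if condition == "72h":
        for dmr in config.dmr_plan:
            hit = (
                (sites["chrom"] == dmr.chrom)
                & (sites["context"] == dmr.context)
                & (sites["pos"] >= dmr.start)
                & (sites["pos"] <= dmr.end)
            ).to_numpy()
            mean[hit] += dmr.delta
    mean = np.clip(mean, 1e-6, 1 - 1e-6)

    cov = rng.poisson(config.coverage_mean, size=len(sites))
    rho = config.overdispersion
    if rho > 0:
        conc = (1.0 - rho) / rho
        p = rng.beta(mean * conc, (1.0 - mean) * conc)
    else:
        p = mean
    # the spike-in is truly unmethylated: plain binomial at the
    # non-conversion rate, no biological overdispersion
    p = np.where(is_lambda, config.non_conversion, p)
    mc = rng.binomial(cov, p)

    report = sites[["chrom", "pos", "strand", "context", "trinucleotide"]].copy()
    report.insert(3, "count_methylated", mc)
    report.insert(4, "count_unmethylated", cov - mc)
    return report


# ---------------------------------------------------------------------------
# small RNAs

def simulate_mirna_counts(config: SimulationConfig) -> pd.DataFrame:
    """Mature miRNA sequences plus a replicate count matrix.

    Counts are negative-binomial with mean ``base_mean`` at 0 h and
    ``base_mean * 2**log2_effect`` at 72 h (var = m + disp·m²).  Sequences
    are random RNA with the configured first-base bias toward U.  Rows whose
    counts are all zero are flagged ``low_count``.
    """
    if not config.mirna_plan:
        raise ValueError("mirna_plan is empty")
    rng = _rng(config.seed, "mirna")
    samples = [f"{cond}_rep{r + 1}" for cond in ("0h", "72h")
               for r in range(config.n_replicates)]
    rows = []
    for mir in config.mirna_plan:
        first = "U" if rng.random() < config.first_base_bias else "ACG"[
            rng.integers(0, 3)]
        seq = first + random_seq(rng, mir.length - 1, "ACGU")
        counts = []
        for cond in ("0h", "72h"):
            m = mir.base_mean * (2.0 ** mir.log2_effect if cond == "72h" else 1.0)
            counts.extend(_nb_draw(rng, m, config.nb_dispersion,
                                   config.n_replicates))
        rows.append([mir.name, seq] + counts)
    table = pd.DataFrame(rows, columns=["name", "sequence"] + samples)
    table["low_count"] = (table[samples] == 0).all(axis=1)
    return table


def _nb_draw(rng, mean: float, disp: float, size: int) -> list[int]:
    if mean <= 0:
        return [0] * size
    if disp <= 0:
        return list(rng.poisson(mean, size=size))
    n = 1.0 / disp
    p = n / (n + mean)
    return list(rng.negative_binomial(n, p, size=size))


# ---------------------------------------------------------------------------
# transcripts and degradome

def simulate_transcripts(
    mirna_seqs: Mapping[str, str], config: SimulationConfig
) -> dict[str, str]:
    """Random transcripts with miRNA target sites implanted per the plan.

    Each planted cleavage implants the reverse complement of its miRNA at
    ``site_start``, then introduces ``n_wobbles`` G:U pairs and
    ``n_mismatches`` non-pairing substitutions at distinct positions away
    from the cleavage-determining position 10.
    """
    rng = _rng(config.seed, "transcripts")
    transcripts: dict[str, str] = {}
    for cl in config.cleavage_plan:
        if cl.transcript_id not in transcripts:
            transcripts[cl.transcript_id] = random_seq(
                rng, config.transcript_length, "ACGU"
            )
        mirna = to_rna(mirna_seqs[cl.mirna_name])
        site = list(to_rna(revcomp(mirna.replace("U", "T"))))
        m = len(mirna)
        if cl.site_start + m - 1 > len(transcripts[cl.transcript_id]):
            raise ValueError(
                f"planted duplex for {cl.mirna_name} does not fit transcript "
                f"{cl.transcript_id}"
            )
        # positions along the miRNA available for perturbation (1-based,
        # avoid 9-11 so the cleavage-defining core stays paired)
        avail = [i for i in range(1, m + 1) if not 9 <= i <= 11]
        wobblable = [i for i in avail if mirna[i - 1] in "GU"]
        w_pos = list(rng.choice(wobblable, size=cl.n_wobbles, replace=False)) \
            if cl.n_wobbles else []
        mm_pool = [i for i in avail if i not in w_pos]
        mm_pos = list(rng.choice(mm_pool, size=cl.n_mismatches, replace=False)) \
            if cl.n_mismatches else []
        for i in w_pos:
            # miRNA base i pairs with site index m - i (0-based)
            site[m - i] = "U" if mirna[i - 1] == "G" else "G"
        for i in mm_pos:
            site[m - i] = _non_pairing(rng, mirna[i - 1])
        t = list(transcripts[cl.transcript_id])
        t[cl.site_start - 1: cl.site_start - 1 + m] = site
        transcripts[cl.transcript_id] = "".join(t)
    return transcripts


def _non_pairing(rng, mirna_base: str) -> str:
    pairs = {"A": "U", "U": "AG", "G": "CU", "C": "G"}[mirna_base]
    options = [b for b in "ACGU" if b not in pairs]
    return options[rng.integers(0, len(options))]


def simulate_degradome(
    transcripts: Mapping[str, str],
    mirna_seqs: Mapping[str, str],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Degradome 5'-end tag profile per transcript (long format).

    Uniform low background (0–2 reads per position) plus ``peak_reads``
    added at the position opposite miRNA nucleotide 10 of each planted
    duplex.  Returns columns transcript_id, pos (1-based), reads.
    """
    rng = _rng(config.seed, "degradome")
    profiles = {
        tid: rng.integers(0, 3, size=len(seq)) for tid, seq in transcripts.items()
    }
    for cl in config.cleavage_plan:
        m = len(mirna_seqs[cl.mirna_name])
        cleave = cl.site_start + m - 10  # base paired to miRNA nt 10
        prof = profiles[cl.transcript_id]
        if not 1 <= cleave <= len(prof):
            raise ValueError(
                f"cleavage position {cleave} outside transcript "
                f"{cl.transcript_id}"
            )
        prof[cleave - 1] += cl.peak_reads
    frames = [
        pd.DataFrame({"transcript_id": tid, "pos": np.arange(1, len(p) + 1),
                      "reads": p})
        for tid, p in profiles.items()
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["transcript_id", "pos", "reads"]
    )


# ---------------------------------------------------------------------------
# file output

def write_gene_models(genes: pd.DataFrame, path) -> None:
    """Tab-separated gene models with exon structure columns."""
    out = genes.drop(columns=["exons"]).copy()
    out["exon_starts"] = [",".join(str(s) for s, _ in ex) for ex in genes["exons"]]
    out["exon_ends"] = [",".join(str(e) for _, e in ex) for ex in genes["exons"]]
    out.to_csv(path, sep="\t", index=False)


def write_mirna_fasta(table: pd.DataFrame, path) -> None:
    write_fasta(dict(zip(table["name"], table["sequence"])), path)


def simulate_all(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run every generator stage and write the standard file set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome, genes = simulate_genome(config)
    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["genes"] = outdir / "gene_models.tsv"
    write_gene_models(genes, paths["genes"])

    for cond in ("0h", "72h"):
        report = simulate_methylome(genome, config, cond)
        paths[f"cx_{cond}"] = outdir / f"cx_report_{cond}.tsv"
        write_cx_report(report, paths[f"cx_{cond}"])

    if config.mirna_plan:
        table = simulate_mirna_counts(config)
        paths["mirna_fasta"] = outdir / "mirnas.fa"
        write_mirna_fasta(table, paths["mirna_fasta"])
        paths["mirna_counts"] = outdir / "mirna_counts.tsv"
        sample_cols = [c for c in table.columns
                       if c.startswith(("0h_", "72h_"))]
        table[["name"] + sample_cols].to_csv(
            paths["mirna_counts"], sep="\t", index=False
        )
        if config.cleavage_plan:
            mirna_seqs = dict(zip(table["name"], table["sequence"]))
            transcripts = simulate_transcripts(mirna_seqs, config)
            paths["transcripts"] = outdir / "transcripts.fa"
            write_fasta(transcripts, paths["transcripts"])
            profile = simulate_degradome(transcripts, mirna_seqs, config)
            paths["degradome"] = outdir / "degradome.tsv"
            profile.to_csv(paths["degradome"], sep="\t", index=False)
    return paths
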