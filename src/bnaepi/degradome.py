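"""miRNA–target duplex scoring and degradome cleavage-site identification.

A candidate target site is an ungapped antiparallel duplex between a mature
miRNA and a transcript window of the same length.  Pairs are scored per
position: Watson-Crick (A:U, G:C) cost 0, the G:U wobble costs 0.5, and any
other combination is a mismatch costing 1.0, so a perfect duplex scores 0.
Plant AGO slicing cuts the target between the bases paired to miRNA
nucleotides 10 and 11; the reported cleavage coordinate is the transcript
base paired to miRNA nucleotide 10 (counting from the miRNA 5' end).

Degradome (PARE) libraries sequence uncapped 5' ends, so a genuine cleavage
leaves a read pile-up at the cleavage position.  Hits are categorized by
how the pile-up ranks within the transcript-wide profile, the scheme used
to draw t-plots:

* 0 — more than one read, the unique transcript-wide maximum;
* 1 — more than one read, tied for the maximum;
* 2 — more than one read, above the transcript median but below the max;
* 3 — more than one read, at or below the median;
* 4 — exactly one read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequences import to_rna

WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

MISMATCH_COST = 1.0
WOBBLE_COST = 0.5
DEFAULT_MAX_SCORE = 4.5


def pair_class(mirna_base: str, target_base: str) -> str:
    """Classify one duplex position: 'wc', 'wobble' or 'mismatch'."""
    pair = (mirna_base, target_base)
    if pair in WATSON_CRICK:
        return "wc"
    if pair in WOBBLE:
        return "wobble"
    return "mismatch"


@dataclass
class DuplexAlignment:
    """One ungapped miRNA–transcript duplex window.

    ``start``/``end`` are 1-based inclusive transcript coordinates; the
    miRNA 3' end pairs with ``start`` and the 5' end with ``end``.
    ``pair_classes`` is ordered along the miRNA 5'→3'.
    """

    mirna_name: str
    mirna_seq: str
    transcript_id: str
    start: int
    end: int
    pair_classes: tuple
    score: float

    @property
    def n_wobbles(self) -> int:
        return self.pair_classes.count("wobble")

    @property
    def n_mismatches(self) -> int:
        return self.pair_classes.count("mismatch")


def align_duplex(
    mirna_seq: str,
    transcript_seq: str,
    max_score: float = DEFAULT_MAX_SCORE,
    mirna_name: str = "mirna",
    transcript_id: str = "transcript",
) -> list[DuplexAlignment]:
    """All transcript windows pairing with the miRNA at or under max_score.

    Slides the miRNA antiparallel along the transcript (both normalized to
    the RNA alphabet, so DNA input gives identical results); windows are
    returned sorted by score, then position.  A miRNA longer than the
    transcript yields an empty list.
    """
    mi = to_rna(mirna_seq)
    tr = to_rna(transcript_seq)
    if not mi or not tr:
        raise ValueError("empty sequence")
    m, L = len(mi), len(tr)
    if m > L:
        return []
    hits = []
    for s in range(L - m + 1):
        # miRNA nt i (1-based from 5') pairs with transcript pos s + m - i
        classes = tuple(
            pair_class(mi[i], tr[s + m - 1 - i]) for i in range(m)
        )
        score = (MISMATCH_COST * classes.count("mismatch")
                 + WOBBLE_COST * classes.count("wobble"))
        if score <= max_score:
            hits.append(
                DuplexAlignment(
                    mirna_name=mirna_name,
                    mirna_seq=mi,
                    transcript_id=transcript_id,
                    start=s + 1,
                    end=s + m,
                    pair_classes=classes,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (h.score, h.start))
    return hits


@dataclass
class CleavageHit:
    """A duplex with its inferred cleavage position and t-plot category."""

    alignment: DuplexAlignment
    cleavage_pos: int
    peak_reads: int
    category: int


def detect_cleavage(
    duplex: DuplexAlignment, profile: Sequence[int]
) -> CleavageHit | None:
    """Read the degradome profile at the duplex's cleavage position.

    ``profile`` holds per-position 5'-end read counts over the whole
    transcript (length = transcript length).  The cleavage position is the
    base paired to miRNA nucleotide 10, i.e. window end − 9.  Returns None
    when no degradome read supports the position.
    """
    prof = np.asarray(profile)
    if duplex.end > len(prof):
        raise ValueError("duplex window beyond profile length")
    pos = duplex.end - 9
    reads = int(prof[pos - 1])
    if reads == 0:
        return None
    if reads == 1:
        category = 4
    else:
        maximum = int(prof.max())
        if reads == maximum:
            category = 0 if int(np.sum(prof == maximum)) == 1 else 1
        elif reads > float(np.median(prof)):
            category = 2
        else:
            category = 3
    return CleavageHit(alignment=duplex, cleavage_pos=pos, peak_reads=reads,
                       category=category)


def tplot_data(hit: CleavageHit, profile: Sequence[int]) -> pd.DataFrame:
    """Per-position read series with the cleavage coordinate flagged.

    This is the data behind a t-plot: the degradome tag distribution along
    the target with the candidate slice site marked (the red arrow of the
    published presentation).
    """
    prof = np.asarray(profile)
    return pd.DataFrame(
        {
            "position": np.arange(1, len(prof) + 1),
            "reads": prof,
            "is_cleavage_site": np.arange(1, len(prof) + 1) == hit.cleavage_pos,
        }
    )


def find_cleavage_hits(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Mapping[str, Sequence[int]],
    max_score: float = DEFAULT_MAX_SCORE,
) -> pd.DataFrame:
    """Scan all miRNA × transcript pairs and tabulate supported cleavages.

    For each pair, every duplex window at or under ``max_score`` is checked
    against the transcript's degradome profile; windows without read
    support are dropped.  Returns one row per supported hit sorted by
    (category, score).
    """
    rows = []
    for mname, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            if tid not in profiles:
                continue
            for dup in align_duplex(mseq, tseq, max_score, mname, tid):
                hit = detect_cleavage(dup, profiles[tid])
                if hit is None:
                    continue
                rows.append(
                    (mname, tid, dup.start, dup.end, dup.score,
                     dup.n_wobbles, dup.n_mismatches, hit.cleavage_pos,
                     hit.peak_reads, hit.category)
                )
    out = pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "window_start", "window_end", "score",
                 "n_wobbles", "n_mismatches", "cleavage_pos", "peak_reads",
                 "category"],
    )
    return out.sort_values(["category", "score", "mirna", "transcript"],
                           ignore_index=True)


def read_degradome_profiles(path, transcripts: Mapping[str, str]) -> dict:
    """Load a long-format degradome TSV into per-transcript read arrays."""
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for tid, sub in df.groupby("transcript_id"):
        arr = np.zeros(len(transcripts[tid]), dtype=int)
        arr[sub["pos"].to_numpy() - 1] = sub["reads"].to_numpy()
        profiles[tid] = arr
    return profiles
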