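"""Mitochondrial consensus calling, B-deletion correction, distances.

Consensus rules: a position is called as the majority base only when it is
covered by at least ``min_cov`` non-redundant (deduplicated) reads and the
majority base accounts for at least ``identity`` of the non-N observations;
otherwise the position is N.  A damage-restricted (PMD) consensus uses the
same identity rule with a 4x minimum coverage to absorb the higher per-read
damage load.

Haplogroup-B mitogenomes carry a diagnostic 9-bp deletion (one copy of the
tandem CCCCCTCTA repeat at reference positions 8,271-8,279).  Reads from
such samples produce a locally erroneous consensus against the reference
frame; :func:`correct_b_deletion` re-examines the window by exhaustive
gapped alignment and rewrites the motif positions as '-' when the sample
supports the deletion.

Pairwise distances use global complete-case site removal: any position with
missing data (N) or a deletion ('-') in any sequence is dropped from all
comparisons, and the number of retained positions is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import (
    B_DELETION_END,
    B_DELETION_MOTIF,
    B_DELETION_START,
)


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusSeq:
    """A called consensus in a fixed coordinate frame.

    ``sequence`` is over {A, C, G, T, N, -}; ``coverage`` is per-position
    non-redundant read depth (N observations do not count).
    """

    sequence: str
    coverage: np.ndarray

    @property
    def called_fraction(self) -> float:
        n = len(self.sequence)
        return sum(1 for c in self.sequence if c != "N") / n if n else 0.0

    def __len__(self) -> int:
        return len(self.sequence)


def filter_reads(reads: pd.DataFrame, min_len: int = 20,
                 min_mapq: int = 30) -> pd.DataFrame:
    """Drop reads shorter than ``min_len`` (default: remove reads <20 bp,
    which limits nonspecific mapping of exogenous fragments) or mapping
    below ``min_mapq``."""
    if reads.empty:
        return reads.copy()
    length = reads["end"] - reads["start"] + 1
    keep = (length >= min_len) & (reads["mapq"] >= min_mapq)
    return reads.loc[keep].reset_index(drop=True)


def build_pileup(reads: pd.DataFrame, length: int) -> list[dict[str, int]]:
    """Per-position base counts (N observations excluded) for a read stack
    aligned gaplessly at 1-based ``start`` coordinates."""
    pile: list[dict[str, int]] = [dict() for _ in range(length)]
    for row in reads.itertuples():
        for i, b in enumerate(row.seq):
            if b == "N":
                continue
            pos = row.start - 1 + i
            if 0 <= pos < length:
                d = pile[pos]
                d[b] = d.get(b, 0) + 1
    return pile


def call_consensus(reads: pd.DataFrame, length: int, min_cov: int = 2,
                   identity: float = 0.80) -> ConsensusSeq:
    """Majority-rule consensus under coverage and identity thresholds.

    A position is called iff non-redundant coverage >= min_cov and the
    majority base fraction >= identity (threshold inclusive; the fraction
    is computed over non-N observations).  A 1-1 split at min_cov=2 cannot
    reach 80% and yields N.  All other positions are N.
    """
    pile = build_pileup(reads, length)
    seq = []
    cov = np.zeros(length, dtype=int)
    for pos, counts in enumerate(pile):
        total = sum(counts.values())
        cov[pos] = total
        if total < min_cov:
            seq.append("N")
            continue
        best = max(sorted(counts), key=counts.get)  # sorted: deterministic ties
        if counts[best] / total >= identity:
            seq.append(best)
        else:
            seq.append("N")
    return ConsensusSeq(sequence="".join(seq), coverage=cov)


def call_pmd_consensus(pmd_reads: pd.DataFrame, length: int, min_cov: int = 4,
                       identity: float = 0.80) -> ConsensusSeq:
    """Consensus restricted to PMD-passing (damage-bearing) reads, with an
    increased 4x minimum non-redundant coverage."""
    return call_consensus(pmd_reads, length, min_cov=min_cov, identity=identity)


def consensus_concordance(a: ConsensusSeq, b: ConsensusSeq) -> tuple[int, int]:
    """(#agreeing, #co-called) positions between two consensus calls in the
    same frame; positions N in either are not co-called."""
    agree = total = 0
    for x, y in zip(a.sequence, b.sequence):
        if x != "N" and y != "N":
            total += 1
            if x == y:
                agree += 1
    return agree, total


# ---------------------------------------------------------------------------
# haplogroup-B 9-bp deletion correction
# ---------------------------------------------------------------------------

@dataclass
class DeletionReport:
    detected: bool
    length: int
    start: int  # 1-based reference coordinates, canonical motif copy
    end: int
    score_deletion: int
    score_reference: int


def _window_score(sample: str, ref: str) -> int:
    """Matches between equal-length windows, ignoring N in the sample."""
    return sum(1 for s, r in zip(sample, ref) if s == r and s != "N")


def correct_b_deletion(consensus: ConsensusSeq, reference: str,
                       window: int = 30,
                       min_margin: int = 5) -> tuple[ConsensusSeq, DeletionReport]:
    """Detect and annotate the haplogroup-B 9-bp deletion.

    The reference must carry the CCCCCTCTA motif at positions 8,271-8,279
    (1-based); otherwise a configuration error is raised.  The consensus may
    be in the sample frame (9 bp shorter than the reference) or in the
    reference frame; in either case an exhaustive gapped alignment over a
    +/-``window`` bp neighbourhood compares the no-deletion hypothesis with
    every placement of a single 9-bp gap.  If a gap placement beats the
    reference alignment by at least ``min_margin`` matches, the consensus is
    rewritten into the reference frame with '-' over the canonical motif
    positions and a deletion of length 9 is reported.
    """
    dlen = B_DELETION_END - B_DELETION_START + 1  # 9
    ref_motif = reference[B_DELETION_START - 1:B_DELETION_END]
    if ref_motif != B_DELETION_MOTIF:
        raise ConsensusError(
            f"reference lacks {B_DELETION_MOTIF} at positions "
            f"{B_DELETION_START}-{B_DELETION_END} (found {ref_motif!r})")

    sample = consensus.sequence
    win_lo = B_DELETION_START - 1 - window          # 0-based inclusive
    win_hi = B_DELETION_END + window                # 0-based exclusive
    ref_win = reference[win_lo:win_hi]
    W = len(ref_win)

    # sample window in sample coordinates; before win_lo the frames agree
    sample_win = sample[win_lo:win_lo + W]

    # hypothesis 0: no deletion
    score_ref = _window_score(sample_win, ref_win)

    # hypothesis 1: one 9-bp gap at offset g within the window
    best_gap_score = -1
    best_g = None
    s_short = sample[win_lo:win_lo + W - dlen]  # sample frame is 9 bp shorter
    for g in range(0, W - dlen + 1):
        aligned = s_short[:g] + "-" * dlen + s_short[g:]
        score = _window_score(aligned, ref_win)
        if score > best_gap_score:
            best_gap_score = score
            best_g = g

    canonical_start0 = B_DELETION_START - 1 - win_lo
    detected = best_gap_score >= score_ref + min_margin
    if not detected:
        report = DeletionReport(False, 0, 0, 0, best_gap_score, score_ref)
        return consensus, report

    # rewrite into the reference frame: '-' over the canonical motif copy
    # (tandem-repeat gap placements are equivalent; best_g only scores them)
    new_win = (sample[win_lo:B_DELETION_START - 1]
               + "-" * dlen
               + sample[B_DELETION_START - 1:win_lo + W - dlen])
    new_seq = sample[:win_lo] + new_win + sample[win_lo + W - dlen:]
    if len(sample) == len(reference):
        # consensus was already in the reference frame (misaligned locus):
        # keep the frame by trimming the displaced tail
        new_seq = new_seq[:len(reference)]
    # pad coverage into the reference frame
    cov = consensus.coverage
    if len(new_seq) == len(reference) and len(cov) == len(reference) - dlen:
        new_cov = np.concatenate([
            cov[:B_DELETION_START - 1],
            np.zeros(dlen, dtype=cov.dtype),
            cov[B_DELETION_START - 1:],
        ])
    else:
        new_cov = cov
    report = DeletionReport(True, dlen, B_DELETION_START, B_DELETION_END,
                            best_gap_score, score_ref)
    return ConsensusSeq(sequence=new_seq, coverage=new_cov), report


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    matrix: pd.DataFrame   # labelled square matrix of nucleotide differences
    bp_analysed: int       # positions entering all comparisons

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def pairwise_distances(sequences: dict[str, str],
                       site_policy: str = "global_complete_case") -> DistanceMatrix:
    """Pairwise nucleotide differences over shared well-called positions.

    global_complete_case (default): positions with N or '-' in *any*
    sequence are removed from *all* comparisons; ``bp_analysed`` is the
    number of retained positions.  pairwise_complete_case: each pair drops
    only its own missing positions (bp_analysed then reports the minimum
    over pairs).
    """
    names = list(sequences)
    arrs = [np.frombuffer(sequences[n].encode(), dtype="S1") for n in names]
    L = len(arrs[0])
    if any(len(a) != L for a in arrs):
        raise ConsensusError("sequences must share one coordinate frame")
    stack = np.vstack(arrs)
    missing = (stack == b"N") | (stack == b"-")
    k = len(names)
    D = np.zeros((k, k), dtype=int)

    if site_policy == "global_complete_case":
        keep = ~missing.any(axis=0)
        if not keep.any():
            raise ConsensusError("no positions retained after complete-case removal")
        sub = stack[:, keep]
        bp = int(keep.sum())
        for i in range(k):
            for j in range(i + 1, k):
                d = int((sub[i] != sub[j]).sum())
                D[i, j] = D[j, i] = d
    elif site_policy == "pairwise_complete_case":
        bp = L
        for i in range(k):
            for j in range(i + 1, k):
                keep = ~(missing[i] | missing[j])
                if not keep.any():
                    raise ConsensusError(f"no shared positions for pair {names[i]}, {names[j]}")
                d = int((stack[i, keep] != stack[j, keep]).sum())
                D[i, j] = D[j, i] = d
                bp = min(bp, int(keep.sum()))
    else:
        raise ValueError(f"unknown site policy {site_policy!r}")
    return DistanceMatrix(matrix=pd.DataFrame(D, index=names, columns=names),
                          bp_analysed=bp)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
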