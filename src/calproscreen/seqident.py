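"""Pairwise global protein alignment and percent-identity profiling.

The aligner is a Needleman–Wunsch/Gotoh dynamic program with affine gaps:
a gap of length *k* costs ``gap_open + (k - 1) * gap_extend``, end gaps are
penalized like internal ones, and the traceback tie-break prefers diagonal
over up over left so results are deterministic. Defaults follow common
global-alignment practice for proteins (BLOSUM62, gap open 10, extend 0.5).

Percent identity is reported, by default, as identical columns over the full
alignment length (gapped columns included in the denominator); the
``denominator="aligned"`` option divides by columns where both rows carry a
residue instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .fasta import SequenceRecord

GAP = "-"


class AlignmentError(ValueError):
    pass


@lru_cache(maxsize=None)
def load_substitution_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def _matrix_alphabet(matrix) -> set[str]:
    if hasattr(matrix, "alphabet"):
        return set(matrix.alphabet)
    return {k[0] for k in matrix} | {k[1] for k in matrix}


def _check_alphabet(seq: SequenceRecord, matrix) -> None:
    alphabet = _matrix_alphabet(matrix)
    for pos, ch in enumerate(seq.residues, start=1):
        if ch not in alphabet:
            raise AlignmentError(
                f"sequence {seq.id!r}: residue {ch!r} at position {pos} "
                f"is absent from the substitution matrix"
            )


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_both_aligned: int
    n_differences: int
    percent_identity: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _score_lookup(matrix, x: str, y: str) -> float:
    try:
        return float(matrix[x, y])
    except (KeyError, IndexError):
        try:
            return float(matrix[y, x])
        except (KeyError, IndexError):
            raise AlignmentError(f"substitution matrix has no entry for ({x}, {y})")


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    Parameters
    ----------
    matrix : Bio.Align substitution matrix or dict keyed by residue pairs;
        BLOSUM62 when omitted.
    gap_open, gap_extend : positive penalties; a length-*k* gap costs
        ``gap_open + (k - 1) * gap_extend``.
    denominator : "alignment" divides identical columns by the full alignment
        length; "aligned" divides by columns with residues in both rows.
    """
    if matrix is None:
        matrix = load_substitution_matrix()
    if denominator not in ("alignment", "aligned"):
        raise AlignmentError(f"unknown identity denominator {denominator!r}")
    _check_alphabet(a, matrix)
    _check_alphabet(b, matrix)

    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    NEG = -np.inf
    # state matrices: M = residue-residue, X = gap in b (up), Y = gap in a (left)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)

    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _score_lookup(matrix, sa[i], sb[j])

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        # X depends only on row i-1: vectorize; switching gap direction
        # (Y -> X) re-opens a gap
        Xi[1:] = np.maximum.reduce(
            [Mi1[1:] - gap_open, Xi1[1:] - gap_extend, Yi1[1:] - gap_open]
        )
        Xi[0] = X[i, 0]
        Srow = S[i - 1]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = Srow[j - 1] + best_prev
            Yi[j] = max(
                Mi[j - 1] - gap_open,
                Yi[j - 1] - gap_extend,
                Xi[j - 1] - gap_open,
            )

    # final state: prefer M over X over Y on ties (diag > up > left)
    end_scores = (M[n, m], X[n, m], Y[n, m])
    score = max(end_scores)
    state = ("M", "X", "Y")[end_scores.index(score)]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = ("M", "X", "Y")[prev.index(max(prev))]
            i, j = i - 1, j - 1
        elif state == "X":
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            prev = (
                M[i - 1, j] - gap_open,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open,
            )
            state = ("M", "X", "Y")[prev.index(max(prev))]
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            prev = (
                M[i, j - 1] - gap_open,
                X[i, j - 1] - gap_open,
                Y[i, j - 1] - gap_extend,
            )
            state = ("M", "X", "Y")[prev.index(max(prev))]
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    assert aligned_a.replace(GAP, "") == sa and aligned_b.replace(GAP, "") == sb

    n_identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != GAP
    )
    n_both = sum(1 for x, y in zip(aligned_a, aligned_b) if x != GAP and y != GAP)
    length = len(aligned_a)
    n_diff = length - n_identical
    denom = length if denominator == "alignment" else n_both
    pct = 100.0 * n_identical / denom if denom else 0.0
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        n_identical=n_identical,
        n_both_aligned=n_both,
        n_differences=n_diff,
        percent_identity=pct,
    )


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # square, percent

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="id")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def identity_matrix(
    seqs: list[SequenceRecord],
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "alignment",
) -> IdentityMatrix:
    """All-vs-all percent-identity matrix from pairwise global alignments.

    Symmetric with exact 100s on the diagonal; each unordered pair is aligned
    once.
    """
    if len(seqs) < 2:
        raise AlignmentError("identity_matrix needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in identity_matrix input")
    k = len(seqs)
    values = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            res = global_align(
                seqs[i], seqs[j], matrix=matrix, gap_open=gap_open,
                gap_extend=gap_extend, denominator=denominator,
            )
            values[i, j] = values[j, i] = res.percent_identity
    return IdentityMatrix(labels=ids, values=values)


@dataclass
class ConservationProfile:
    frequencies: pd.DataFrame  # one row per column; residue/gap frequencies
    consensus: str
    threshold: float

    def to_csv(self, path: str | Path) -> None:
        df = self.frequencies.copy()
        df.insert(0, "consensus", list(self.consensus))
        df.insert(
            1, "top_frequency",
            self.frequencies.drop(columns=[GAP], errors="ignore").max(axis=1),
        )
        df.to_csv(path, index_label="column")


def consensus_profile(msa: list[str], threshold: float = 0.5) -> ConservationProfile:
    """Per-column residue frequencies and majority consensus of an MSA.

    A column's consensus character is its most frequent residue when that
    residue occurs in at least ``threshold`` of *all* rows (gap rows count in
    the denominator), '.' otherwise. Frequency ties break alphabetically.
    """
    if not msa:
        raise AlignmentError("empty alignment")
    if not 0 < threshold <= 1:
        raise AlignmentError("threshold must be in (0, 1]")
    width = len(msa[0])
    for r, row in enumerate(msa):
        if len(row) != width:
            raise AlignmentError(f"ragged alignment: row {r} has length {len(row)}, expected {width}")
    n = len(msa)
    records = []
    consensus = []
    for col in range(width):
        counts: dict[str, int] = {}
        for row in msa:
            ch = row[col].upper()
            counts[ch] = counts.get(ch, 0) + 1
        freqs = {ch: c / n for ch, c in counts.items()}
        residue_freqs = {ch: f for ch, f in freqs.items() if ch != GAP}
        if residue_freqs:
            best = min(
                residue_freqs, key=lambda ch: (-residue_freqs[ch], ch)
            )
            consensus.append(best if residue_freqs[best] >= threshold else ".")
        else:
            consensus.append(".")
        records.append(freqs)
    freq_df = pd.DataFrame.from_records(records).fillna(0.0)
    freq_df = freq_df[sorted(freq_df.columns)]
    return ConservationProfile(
        frequencies=freq_df, consensus="".join(consensus), threshold=threshold
    )
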