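"""Local protein alignment with EMBOSS-water semantics.

Smith-Waterman with affine gaps (Gotoh's three-state recurrence): a gap of
length L costs ``gap_open + (L - 1) * gap_extend``, i.e. the opening
penalty is charged on the first gap residue.  Percent identity is
identities over alignment length, percent similarity counts residue pairs
with a positive substitution score; both denominators include gap columns
(the EMBOSS convention).

Traceback ties are broken deterministically: diagonal, then gap-in-second
(up), then gap-in-first (left), starting from the highest-scoring cell with
the smallest (i, j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices


class AlignmentError(ValueError):
    pass


class SubstitutionMatrix:
    """Symmetric residue scoring matrix with an optional wildcard residue."""

    def __init__(self, array, name: str = "", wildcard: str | None = "X"):
        self.array = array
        self.name = name or getattr(array, "name", "")
        self.alphabet = set(str(array.alphabet))
        self.wildcard = wildcard if wildcard in self.alphabet else None

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls(substitution_matrices.load("BLOSUM62"), name="BLOSUM62")

    def _canon(self, a: str) -> str:
        if a in self.alphabet:
            return a
        if self.wildcard is not None:
            return self.wildcard
        raise AlignmentError(f"residue {a!r} not covered by matrix {self.name}")

    def score(self, a: str, b: str) -> float:
        return float(self.array[self._canon(a), self._canon(b)])


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment and its summary statistics."""

    aligned_a: str
    aligned_b: str
    score: float
    start_a: int  # 0-based start of the aligned region in sequence a
    start_b: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def identities(self) -> int:
        return sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y)

    def similarities(self, matrix: SubstitutionMatrix) -> int:
        n = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x != "-" and y != "-" and matrix.score(x, y) > 0:
                n += 1
        return n

    def gaps(self) -> int:
        return self.aligned_a.count("-") + self.aligned_b.count("-")

    def percent_identity(self) -> float:
        return 100.0 * self.identities() / self.length

    def percent_similarity(self, matrix: SubstitutionMatrix) -> float:
        return 100.0 * self.similarities(matrix) / self.length

    def rescore(self, matrix: SubstitutionMatrix, gap_open: float, gap_extend: float) -> float:
        """Recompute the score from the aligned strings (consistency check)."""
        total, in_gap = 0.0, False
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" or y == "-":
                total -= gap_open if not in_gap else gap_extend
                in_gap = True
            else:
                total += matrix.score(x, y)
                in_gap = False
        return total


_DIAG, _UP, _LEFT, _STOP = 1, 2, 3, 0


def smith_waterman(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LocalAlignment:
    """Optimal local alignment of two protein sequences under affine gaps."""
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    n, m = len(a), len(b)
    neg = -np.inf
    # H: best ending in a match state; E: gap in b (consumes a, "up");
    # F: gap in a (consumes b, "left")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.int8)  # state that fed H's max
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = opened from H, 0 = extended
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.int8)

    sub = np.empty((n, m))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            sub[i, j] = matrix.score(x, y)

    best, best_ij = 0.0, (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - gap_open
            e_ext = E[i - 1, j] - gap_extend
            if e_open >= e_ext:
                E[i, j], ptr_e[i, j] = e_open, 1
            else:
                E[i, j], ptr_e[i, j] = e_ext, 0
            f_open = H[i, j - 1] - gap_open
            f_ext = F[i, j - 1] - gap_extend
            if f_open >= f_ext:
                F[i, j], ptr_f[i, j] = f_open, 1
            else:
                F[i, j], ptr_f[i, j] = f_ext, 0
            diag = H[i - 1, j - 1] + sub[i - 1, j - 1]
            # tie preference: diagonal, then up (E), then left (F); max() is
            # stable so the first of equal candidates wins
            h, p = max(
                [(diag, _DIAG), (E[i, j], _UP), (F[i, j], _LEFT)],
                key=lambda t: t[0],
            )
            if h <= 0.0:
                h, p = 0.0, _STOP
            H[i, j], ptr_h[i, j] = h, p
            if h > best:
                best, best_ij = h, (i, j)

    if best == 0.0:
        raise AlignmentError("no positive-scoring local alignment")

    # traceback
    i, j = best_ij
    out_a, out_b = [], []
    state = "H"
    while True:
        if state == "H":
            p = ptr_h[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif p == _UP:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            out_a.append(a[i - 1])
            out_b.append("-")
            opened = ptr_e[i, j]
            i -= 1
            if opened:
                state = "H"
        else:  # F
            out_a.append("-")
            out_b.append(b[j - 1])
            opened = ptr_f[i, j]
            j -= 1
            if opened:
                state = "H"

    return LocalAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(best),
        start_a=i,
        start_b=j,
    )


def homology_summary(
    rows: list[tuple[str, float, float]], exclude: str | None = None
) -> tuple[float, float]:
    """Mean percent identity and similarity over pairwise-alignment rows,
    rounded to one decimal (reporting convention), optionally excluding the
    self-comparison row."""
    kept = [(i, s) for name, i, s in rows if name != exclude]
    if not kept:
        raise AlignmentError("no rows left after exclusion")
    mean_i = sum(i for i, _ in kept) / len(kept)
    mean_s = sum(s for _, s in kept) / len(kept)
    return round(mean_i, 1), round(mean_s, 1)


def pairwise_report(
    query_name: str,
    query_seq: str,
    subjects: list[tuple[str, str]],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Align a query protein against each subject, one summary row apiece."""
    import pandas as pd

    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    rows = []
    for name, seq in subjects:
        aln = smith_waterman(query_seq, seq, matrix, gap_open, gap_extend)
        rows.append(
            {
                "query": query_name,
                "subject": name,
                "pct_identity": round(aln.percent_identity(), 1),
                "pct_similarity": round(aln.percent_similarity(matrix), 1),
                "score": aln.score,
                "length": aln.length,
            }
        )
    return pd.DataFrame(rows)
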