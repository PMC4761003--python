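"""Smith–Waterman local alignment for displaying siRNA/target matches.

The search itself is Hamming-only; the alignment exists so each reported hit
can be rendered base-by-base.  On ≤3-mismatch 19-mer pairs any scheme with a
positive match score and non-positive gap penalty produces a gapless optimum,
so the default scoring (match +2, mismatch −1, gap −2) is a display choice,
not a biological claim, and is configurable.

Gaps are linear (no affine opening cost).  Traceback ties are broken
deterministically: diagonal, then up (gap in the subject), then left (gap in
the query); among equal-scoring end cells the first in row-major order wins.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EmptyInputError, ParameterError

__all__ = ["Scoring", "Alignment", "smith_waterman", "window_alignment", "edit_string"]


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self):
        if self.match <= 0:
            raise ParameterError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ParameterError("mismatch and gap penalties must be <= 0")


@dataclass(frozen=True)
class Alignment:
    """A local alignment; spans are 1-based closed on the original inputs."""

    score: float
    aligned_query: str
    aligned_subject: str
    match_line: str
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    @property
    def n_substitutions(self) -> int:
        return sum(
            1
            for q, s in zip(self.aligned_query, self.aligned_subject)
            if q != "-" and s != "-" and q != s
        )

    @property
    def n_gaps(self) -> int:
        return sum(
            1
            for q, s in zip(self.aligned_query, self.aligned_subject)
            if q == "-" or s == "-"
        )

    def as_text(self) -> str:
        return "\n".join((self.aligned_query, self.match_line, self.aligned_subject))


def smith_waterman(query: str, subject: str, scoring: Scoring | None = None) -> Alignment:
    """Optimal local alignment by the standard dynamic program with linear gaps."""
    if not query or not subject:
        raise EmptyInputError("smith_waterman requires non-empty sequences")
    sc = scoring or Scoring()
    n, m = len(query), len(subject)

    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (sc.match if qi == subject[j - 1] else sc.mismatch)
            up = prev[j] + sc.gap
            left = row[j - 1] + sc.gap
            h = diag
            if up > h:
                h = up
            if left > h:
                h = left
            if h < 0:
                h = 0.0
            row[j] = h
            if h > best:  # strict: keeps the first (row-major) maximum
                best, bi, bj = h, i, j

    if best == 0:
        return Alignment(0.0, "", "", "", (0, 0), (0, 0))

    aq, asub = [], []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        diag = H[i - 1][j - 1] + (sc.match if query[i - 1] == subject[j - 1] else sc.mismatch)
        if h == diag:
            aq.append(query[i - 1])
            asub.append(subject[j - 1])
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + sc.gap:  # up: consume query, gap in subject
            aq.append(query[i - 1])
            asub.append("-")
            i -= 1
        else:  # left: consume subject, gap in query
            aq.append("-")
            asub.append(subject[j - 1])
            j -= 1
    aq.reverse()
    asub.reverse()
    aligned_q, aligned_s = "".join(aq), "".join(asub)
    match_line = "".join(
        "|" if a == b and a != "-" else " " for a, b in zip(aligned_q, aligned_s)
    )
    return Alignment(
        score=best,
        aligned_query=aligned_q,
        aligned_subject=aligned_s,
        match_line=match_line,
        query_span=(i + 1, bi),
        subject_span=(j + 1, bj),
    )


def window_alignment(query: str, window: str, scoring: Scoring | None = None) -> Alignment:
    """Full-length gapless alignment of a query against its equal-length
    matched window.

    This is the display form for hits found by the Hamming search: a strictly
    local alignment would trim a terminal mismatch (raising its score by
    dropping the penalty) or tie with gapped co-optima, and then the rendered
    substitution count would no longer equal the hit's mismatch level.  The
    score is the column sum under ``scoring`` (≥ 29 with the defaults for any
    ≤3-mismatch 19-mer pair).
    """
    if not query or not window:
        raise EmptyInputError("window_alignment requires non-empty sequences")
    if len(query) != len(window):
        raise ParameterError("window_alignment requires equal-length sequences")
    sc = scoring or Scoring()
    score = sum(sc.match if a == b else sc.mismatch for a, b in zip(query, window))
    match_line = "".join("|" if a == b else " " for a, b in zip(query, window))
    n = len(query)
    return Alignment(
        score=float(score),
        aligned_query=query,
        aligned_subject=window,
        match_line=match_line,
        query_span=(1, n),
        subject_span=(1, n),
    )


def edit_string(aln: Alignment) -> str:
    """Compact CIGAR-like run-length edit string: = match, X substitution,
    I query-only column (gap in subject), D subject-only column."""
    ops = []
    for q, s in zip(aln.aligned_query, aln.aligned_subject):
        if q == "-":
            ops.append("D")
        elif s == "-":
            ops.append("I")
        elif q == s:
            ops.append("=")
        else:
            ops.append("X")
    out, i = [], 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)
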