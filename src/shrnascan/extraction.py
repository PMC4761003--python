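"""Locate and extract the siRNA duplex from shRNA-coding clone reads.

An shRNA-coding clone carries the siRNA stem as an inverted repeat
(sense + loop + antisense) downstream of a known vector sequence, so the
siRNA can be located by matching that vector flank and capturing a fixed
number of bases after it.  Because of the inverted repeat, the sequencing
direction of the read does not matter: both the read and its reverse
complement are scanned, and either yields the same duplex.

The pattern grammar mirrors the web-form convention: a literal flank followed
by a single fixed-length capture group, e.g. ``tatagaaaaaa(.{ 19 })``
(capture the 19 bases after the vector sequence TATAGAAAAAA).  An empty
pattern means "the whole input is the siRNA"; a bare capture group means
"the first N bases are".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from ._seq import normalize, reverse_complement, validate_iupac
from .errors import (
    EmptyInputError,
    NoSiteError,
    PatternSyntaxError,
    TruncatedCaptureError,
)

__all__ = [
    "PatternMode",
    "PatternSpec",
    "SirnaDuplex",
    "parse_pattern",
    "extract_sirna",
    "gc_content",
    "at_content",
]


class PatternMode(str, Enum):
    FLANKED = "flanked"
    WHOLE_SEQUENCE = "whole_sequence"
    PREFIX_CAPTURE = "prefix_capture"


@dataclass(frozen=True)
class PatternSpec:
    """Parsed siRNA-locating pattern: literal flanks around a fixed-length capture."""

    mode: PatternMode
    leading_flank: str = ""
    capture_length: int | None = None
    trailing_flank: str = ""


@dataclass(frozen=True)
class SirnaDuplex:
    """A passenger/guide 19-mer pair with provenance coordinates.

    ``source_start``/``source_end`` are 0-based half-open coordinates of the
    captured window on the input read as given (for reverse-orientation
    matches they are mapped back onto the input strand).  ``guide`` is always
    the reverse complement of ``passenger``.
    """

    passenger: str
    guide: str
    source_name: str
    source_start: int
    source_end: int
    source_orientation: str  # "forward" | "reverse"
    gc_percent: float
    has_ambiguous: bool = False

    def __post_init__(self):
        if self.guide != reverse_complement(self.passenger):
            raise ValueError("guide must be the reverse complement of passenger")
        if self.source_end - self.source_start != len(self.passenger):
            raise ValueError("source coordinates do not span the passenger length")


_CAPTURE_RE = re.compile(r"\(\.\{\s*(\d+)\s*\}\)")
_FLANK_RE = re.compile(r"^[ACGTacgt]*$")


def parse_pattern(spec_text: str) -> PatternSpec:
    """Parse a pattern expression into a :class:`PatternSpec`.

    ``""`` selects whole-sequence mode, ``"(.{ 19 })"`` prefix-capture mode,
    and ``"tatagaaaaaa(.{ 19 })"`` flanked mode.  Whitespace inside the braces
    is tolerated, matching the printed form of the web-form default.
    """
    text = spec_text.strip()
    if not text:
        return PatternSpec(mode=PatternMode.WHOLE_SEQUENCE)
    captures = list(_CAPTURE_RE.finditer(text))
    if len(captures) == 0:
        raise PatternSyntaxError(
            f"pattern {text!r} has no capture group of the form '(.{{N}})'"
        )
    if len(captures) > 1:
        raise PatternSyntaxError(
            f"pattern {text!r} has {len(captures)} capture groups; exactly one is allowed"
        )
    cap = captures[0]
    n = int(cap.group(1))
    if n <= 0:
        raise PatternSyntaxError(f"capture length must be positive, got {cap.group(0)!r}")
    leading, trailing = text[: cap.start()], text[cap.end() :]
    for tok in (leading, trailing):
        if not _FLANK_RE.match(tok):
            raise PatternSyntaxError(f"flank {tok!r} contains non-ACGT characters")
    if not leading and not trailing:
        return PatternSpec(mode=PatternMode.PREFIX_CAPTURE, capture_length=n)
    return PatternSpec(
        mode=PatternMode.FLANKED,
        leading_flank=leading.upper(),
        capture_length=n,
        trailing_flank=trailing.upper(),
    )


def gc_content(seq: str) -> float:
    """Percent G+C over the full length; N counts in the denominator only."""
    if not seq:
        raise EmptyInputError("empty sequence for GC content")
    norm = validate_iupac(seq, "GC-content input")
    gc = sum(1 for c in norm if c in "GC")
    return 100.0 * gc / len(norm)


def at_content(seq: str) -> float:
    """Percent A+T (U counted as T)."""
    norm = validate_iupac(seq, "AT-content input")
    at = sum(1 for c in norm if c in "AT")
    return 100.0 * at / len(norm)


def _read_name_seq(read) -> tuple[str, str]:
    # Accept a Biopython SeqRecord or a (name, sequence) pair.
    if hasattr(read, "id") and hasattr(read, "seq"):
        return str(read.id), str(read.seq)
    name, seq = read
    return str(name), str(seq)


def _scan_strand(seq: str, pattern: PatternSpec) -> tuple[list[tuple[int, int]], bool]:
    """All complete capture windows on one strand; flag if any was truncated."""
    n = pattern.capture_length
    lead, trail = pattern.leading_flank, pattern.trailing_flank
    windows: list[tuple[int, int]] = []
    truncated = False
    if lead:
        start = 0
        while (i := seq.find(lead, start)) >= 0:
            cs, ce = i + len(lead), i + len(lead) + n
            if ce + len(trail) > len(seq):
                truncated = True
            elif not trail or seq[ce : ce + len(trail)] == trail:
                windows.append((cs, ce))
            start = i + 1
    else:  # trailing-only flank: capture the N bases before each flank match
        start = 0
        while (i := seq.find(trail, start)) >= 0:
            cs, ce = i - n, i
            if cs < 0:
                truncated = True
            else:
                windows.append((cs, ce))
            start = i + 1
    return windows, truncated


def _make_duplex(
    captured: str,
    name: str,
    start: int,
    end: int,
    orientation: str,
    treat_as_guide: bool,
) -> SirnaDuplex:
    if treat_as_guide:
        passenger = reverse_complement(captured)
    else:
        passenger = captured
    return SirnaDuplex(
        passenger=passenger,
        guide=reverse_complement(passenger),
        source_name=name,
        source_start=start,
        source_end=end,
        source_orientation=orientation,
        gc_percent=gc_content(passenger),
        has_ambiguous="N" in captured,
    )


def extract_sirna(read, pattern: PatternSpec, treat_as_guide: bool = False) -> list[SirnaDuplex]:
    """Extract every siRNA duplex a clone read encodes.

    In flanked mode the read is scanned in forward orientation and then as
    its reverse complement; forward matches (left to right) are reported
    before reverse ones.  The captured strand is the passenger unless
    ``treat_as_guide`` is set, in which case it is the guide and the
    passenger is its reverse complement.

    Raises :class:`NoSiteError` when no flank matches in either orientation
    and :class:`TruncatedCaptureError` when the only matches run past the
    read end.  Ambiguous bases (N) inside a captured window flag the duplex
    (``has_ambiguous``) but are not fatal.
    """
    name, raw = _read_name_seq(read)
    seq = validate_iupac(raw, f"read {name!r}")

    if pattern.mode is PatternMode.WHOLE_SEQUENCE:
        return [_make_duplex(seq, name, 0, len(seq), "forward", treat_as_guide)]

    n = pattern.capture_length
    assert n is not None
    if pattern.mode is PatternMode.PREFIX_CAPTURE:
        if len(seq) < n:
            raise TruncatedCaptureError(name)
        return [_make_duplex(seq[:n], name, 0, n, "forward", treat_as_guide)]

    # flanked mode
    duplexes: list[SirnaDuplex] = []
    any_truncated = False
    fwd_windows, trunc = _scan_strand(seq, pattern)
    any_truncated |= trunc
    for cs, ce in fwd_windows:
        duplexes.append(_make_duplex(seq[cs:ce], name, cs, ce, "forward", treat_as_guide))
    rc = reverse_complement(seq)
    rev_windows, trunc = _scan_strand(rc, pattern)
    any_truncated |= trunc
    for cs, ce in rev_windows:
        # map the window back onto the input read's coordinates
        duplexes.append(
            _make_duplex(rc[cs:ce], name, len(seq) - ce, len(seq) - cs, "reverse", treat_as_guide)
        )
    if not duplexes:
        if any_truncated:
            raise TruncatedCaptureError(name)
        raise NoSiteError(name)
    return duplexes
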