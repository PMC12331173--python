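"""Binary presence/absence alignments and their gap-form encoding.

An input multiple sequence alignment is reduced to a 0/1 matrix: any residue
(including ambiguity codes) counts as presence, configured gap characters as
absence.  Two all-1 sentinel columns are added, at site 0 and site m+1, so
that every maximal run of 0s inside a row is flanked by 1s.  User-facing site
coordinates are 1-based (1..m); the sentinels are internal and never reported
as indel endpoints.

The *gap form* of an alignment stores, per row, the sorted list of maximal
0-intervals.  It is a lossless encoding whose size depends on the number of
gaps rather than on the number of columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, AllZeroColumnError

__all__ = [
    "Interval",
    "BinaryAlignment",
    "GapForm",
    "AlignmentStats",
    "read_alignment",
    "write_alignment_fasta",
    "to_gap_form",
    "from_gap_form",
    "read_gap_form",
    "write_gap_form",
    "compute_stats",
    "DEFAULT_GAP_CHARS",
]

DEFAULT_GAP_CHARS = frozenset({"-", "."})

#: Closed interval of sites, 1-based.
Interval = tuple[int, int]


@dataclass
class BinaryAlignment:
    """Presence/absence matrix over sites ``0..m+1`` with all-1 sentinels.

    Parameters
    ----------
    taxa:
        Ordered row names.
    matrix:
        uint8 array of shape ``(len(taxa), m + 2)``; column 0 and column
        ``m + 1`` must contain only 1s.
    """

    taxa: list[str]
    matrix: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentFormatError("matrix shape does not match taxa")
        if self.matrix.shape[1] < 2:
            raise AlignmentFormatError("alignment must have at least m=0 columns")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentFormatError("duplicate row names")
        if not np.all(self.matrix[:, 0] == 1) or not np.all(self.matrix[:, -1] == 1):
            raise AlignmentFormatError("sentinel columns 0 and m+1 must be all-1")
        if np.any((self.matrix != 0) & (self.matrix != 1)):
            raise AlignmentFormatError("matrix values must be 0 or 1")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    @property
    def m(self) -> int:
        """Number of original (interior) columns."""
        return self.matrix.shape[1] - 2

    @property
    def n(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> np.ndarray:
        """Full row including sentinel sites 0 and m+1."""
        try:
            return self.matrix[self._index[taxon]]
        except KeyError:
            raise AlignmentFormatError(f"unknown row {taxon!r}") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def validate_columns(self) -> None:
        """Reject interior columns consisting only of 0s."""
        interior = self.matrix[:, 1:-1]
        bad = np.flatnonzero(~interior.any(axis=0))
        if bad.size:
            sites = ", ".join(str(k + 1) for k in bad[:10])
            raise AllZeroColumnError(f"column(s) {sites} contain only gaps")

    def drop_all_zero_columns(self) -> tuple["BinaryAlignment", dict[int, int]]:
        """Remove interior all-0 columns.

        Returns the repaired alignment together with the old→new 1-based site
        map of the retained interior columns.
        """
        interior = self.matrix[:, 1:-1]
        keep = np.flatnonzero(interior.any(axis=0))
        site_map = {int(old) + 1: new + 1 for new, old in enumerate(keep)}
        cols = [0] + [int(k) + 1 for k in keep] + [self.m + 1]
        return BinaryAlignment(list(self.taxa), self.matrix[:, cols]), site_map


@dataclass
class GapForm:
    """Per-row sorted lists of maximal 0-intervals within ``[1, m]``."""

    taxa: list[str]
    m: int
    gaps: dict[str, tuple[Interval, ...]]

    def __post_init__(self) -> None:
        for t in self.taxa:
            ivs = tuple(sorted(self.gaps.get(t, ())))
            prev_end = -1  # intervals must be disjoint and non-adjacent
            for i, j in ivs:
                if not (1 <= i <= j <= self.m):
                    raise AlignmentFormatError(
                        f"interval [{i},{j}] of row {t!r} outside [1,{self.m}]"
                    )
                if i <= prev_end + 1:
                    raise AlignmentFormatError(
                        f"intervals of row {t!r} overlap or are adjacent at [{i},{j}]"
                    )
                prev_end = j
            self.gaps[t] = ivs


@dataclass(frozen=True)
class AlignmentStats:
    """Summary parameters: rows ``n``, columns ``m``, boundary count ``b``.

    A boundary is a pair of consecutive sites (k, k+1), k in 0..m, whose
    columns differ.  The bottom-up state size and the arc counts of the site
    graphs are linear in ``b``, which for real alignments is typically much
    smaller than ``m``.
    """

    n: int
    m: int
    b: int


def binarize_rows(
    rows: dict[str, str], gap_chars: frozenset[str] | set[str] = DEFAULT_GAP_CHARS
) -> BinaryAlignment:
    """Build a :class:`BinaryAlignment` from raw aligned strings.

    Non-gap characters map to 1, gap characters to 0; sentinel all-1 columns
    are appended on both sides.  Column validity is *not* checked here; see
    :func:`read_alignment` for the user-facing policy.
    """
    if not rows:
        raise AlignmentFormatError("empty alignment")
    taxa = list(rows)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise AlignmentFormatError(f"rows have unequal lengths: {sorted(lengths)}")
    m = lengths.pop()
    gap = set(gap_chars)
    mat = np.ones((len(taxa), m + 2), dtype=np.uint8)
    for r, t in enumerate(taxa):
        mat[r, 1 : m + 1] = [0 if ch in gap else 1 for ch in rows[t]]
    return BinaryAlignment(taxa, mat)


def read_alignment(
    fasta_text: str,
    gap_chars: frozenset[str] | set[str] = DEFAULT_GAP_CHARS,
    drop_all_zero: bool = False,
    validate: bool = True,
) -> BinaryAlignment | tuple[BinaryAlignment, dict[int, int]]:
    """Read an aligned FASTA string into a binary alignment.

    With ``drop_all_zero`` the function removes interior all-0 columns and
    returns ``(alignment, old→new site map)``; by default such columns are a
    hard error, since a column in which no sequence retains a character has
    no deletion-only explanation.  ``validate=False`` skips the column check
    (useful for row subsets, e.g. pairwise distance inputs).
    """
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise AlignmentFormatError("empty or non-FASTA alignment input")
    rows: dict[str, str] = {}
    for rec in records:
        if rec.id in rows:
            raise AlignmentFormatError(f"duplicate row name {rec.id!r}")
        rows[rec.id] = str(rec.seq)
    aln = binarize_rows(rows, gap_chars)
    if drop_all_zero:
        return aln.drop_all_zero_columns()
    if validate:
        aln.validate_columns()
    return aln


def write_alignment_fasta(
    aln: BinaryAlignment, residues: dict[str, str] | None = None
) -> str:
    """Serialize rows as FASTA using ``x`` for presence and ``-`` for absence.

    ``residues`` optionally maps row names to original residue strings of
    length m; for those rows the original characters are re-inserted at
    presence sites (pass-through mode for leaves).
    """
    records = []
    for t in aln.taxa:
        bits = aln.row(t)[1:-1]
        if residues and t in residues:
            src = residues[t]
            if len(src) != aln.m:
                raise AlignmentFormatError(
                    f"residue string for {t!r} has length {len(src)}, expected {aln.m}"
                )
            chars = [src[k] if bits[k] else "-" for k in range(aln.m)]
        else:
            chars = ["x" if v else "-" for v in bits]
        records.append(SeqRecord(Seq("".join(chars)), id=t, description=""))
    out = io.StringIO()
    SeqIO.write(records, out, "fasta")
    return out.getvalue()


def zero_runs(row: np.ndarray) -> tuple[Interval, ...]:
    """Maximal 0-runs of a sentinel-flanked row, as closed 1-based intervals."""
    z = np.flatnonzero(row == 0)
    if z.size == 0:
        return ()
    breaks = np.flatnonzero(np.diff(z) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [z.size - 1]))
    return tuple((int(z[s]), int(z[e])) for s, e in zip(starts, ends))


def to_gap_form(aln: BinaryAlignment) -> GapForm:
    """Encode each row as its set of maximal 0-intervals."""
    return GapForm(
        taxa=list(aln.taxa),
        m=aln.m,
        gaps={t: zero_runs(aln.row(t)) for t in aln.taxa},
    )


def from_gap_form(gf: GapForm) -> BinaryAlignment:
    """Inverse of :func:`to_gap_form` (exact round trip)."""
    mat = np.ones((len(gf.taxa), gf.m + 2), dtype=np.uint8)
    for r, t in enumerate(gf.taxa):
        for i, j in gf.gaps.get(t, ()):
            mat[r, i : j + 1] = 0
    return BinaryAlignment(list(gf.taxa), mat)


def write_gap_form(gf: GapForm) -> str:
    """Line-oriented gap-form text: ``taxon<TAB>i1-j1,i2-j2,...``."""
    lines = [f"#m={gf.m}"]
    for t in gf.taxa:
        spans = ",".join(f"{i}-{j}" for i, j in gf.gaps.get(t, ()))
        lines.append(f"{t}\t{spans}")
    return "\n".join(lines) + "\n"


def read_gap_form(text: str) -> GapForm:
    """Parse the gap-form text format produced by :func:`write_gap_form`."""
    m: int | None = None
    taxa: list[str] = []
    gaps: dict[str, tuple[Interval, ...]] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#m="):
            m = int(line[3:])
            continue
        if "\t" not in line:
            raise AlignmentFormatError(f"line {lineno}: expected 'taxon<TAB>spans'")
        t, spans = line.split("\t", 1)
        ivs: list[Interval] = []
        for part in spans.split(","):
            part = part.strip()
            if not part:
                continue
            try:
                i, j = part.split("-")
                ivs.append((int(i), int(j)))
            except ValueError:
                raise AlignmentFormatError(
                    f"line {lineno}: bad interval {part!r}"
                ) from None
        taxa.append(t)
        gaps[t] = tuple(ivs)
    if m is None:
        raise AlignmentFormatError("gap-form input lacks a '#m=' header")
    if not taxa:
        raise AlignmentFormatError("gap-form input has no rows")
    return GapForm(taxa=taxa, m=m, gaps=gaps)


def compute_stats(aln: BinaryAlignment) -> AlignmentStats:
    """Count rows, interior columns and boundaries (differing adjacent columns)."""
    diff = aln.matrix[:, 1:] != aln.matrix[:, :-1]
    return AlignmentStats(n=aln.n, m=aln.m, b=int(diff.any(axis=0).sum()))
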