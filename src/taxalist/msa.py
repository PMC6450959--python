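"""Query-anchored multiple sequence alignments.

A query protein is aligned against homologous subject sequences; every aligned
section of a subject is stored as one :class:`AlignedSegment` in *query*
coordinates (1-based, inclusive).  Columns where the subject has a gap are kept
as GAP placeholders; columns where the *query* has a gap (a subject insertion)
consume no query position and are recorded as insertion events so that the two
aligned residues flanking every gap can be flagged as boundary (BND) residues.
BND residues are down-weighted by all downstream identity measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residues flagged on each side of a gap
BND_FLANK = 2
#: minimum aligned length: min(MIN_SECTION_RESIDUES, ceil(MIN_SECTION_FRACTION * query length))
MIN_SECTION_RESIDUES = 70
MIN_SECTION_FRACTION = 0.7
#: sections with percent identity <= this are discarded
MIN_SECTION_PIDENT = 40.0


class MsaError(ValueError):
    """Malformed alignment input or out-of-range access."""


@dataclass(frozen=True)
class QuerySequence:
    """A query protein: id plus residues over the 20-letter alphabet."""

    protein_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise MsaError(f"query {self.protein_id!r}: empty sequence")
        bad = set(self.residues) - AA_SET
        if bad:
            raise MsaError(
                f"query {self.protein_id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.residues):
            raise MsaError(f"position {pos} outside query of length {len(self)}")
        return self.residues[pos - 1]


@dataclass(frozen=True)
class AlignedSegment:
    """One contiguously aligned subject section in query coordinates.

    ``residues[i]`` is the subject residue at query position ``q_start + i``
    (``'-'`` where the subject has a gap).  ``insertions`` maps a query
    position ``p`` (``q_start - 1 <= p <= q_end``) to the subject text inserted
    between ``p`` and ``p + 1``.  ``bnd`` and ``section_identity`` are
    populated by :func:`mark_bnd`.
    """

    subject_id: str
    taxid: int
    q_start: int
    q_end: int
    residues: str
    insertions: tuple[tuple[int, str], ...] = ()
    bnd: tuple[int, ...] = ()  # 1-based query positions flagged BND
    section_identity: int | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise MsaError(
                f"{self.subject_id}: q_start {self.q_start} > q_end {self.q_end}"
            )
        if len(self.residues) != self.q_end - self.q_start + 1:
            raise MsaError(
                f"{self.subject_id}: residue string length {len(self.residues)} "
                f"does not cover [{self.q_start}, {self.q_end}]"
            )

    def covers(self, pos: int) -> bool:
        return self.q_start <= pos <= self.q_end

    def residue_at(self, pos: int) -> str:
        if not self.covers(pos):
            raise MsaError(
                f"{self.subject_id}: position {pos} outside [{self.q_start}, {self.q_end}]"
            )
        return self.residues[pos - self.q_start]

    def bnd_at(self, pos: int) -> bool:
        return pos in self.bnd

    @property
    def aligned_length(self) -> int:
        """Number of non-gap subject residues in the section."""
        return len(self.residues) - self.residues.count(GAP)


@dataclass
class MSA:
    """A query sequence plus its aligned segments, indexable by position."""

    query: QuerySequence
    segments: list[AlignedSegment]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.query)
        for seg in self.segments:
            if seg.q_start < 1 or seg.q_end > n:
                raise MsaError(
                    f"segment {seg.subject_id} [{seg.q_start}, {seg.q_end}] outside "
                    f"query of length {n}"
                )

    def segments_at(self, pos: int) -> list[tuple[int, AlignedSegment]]:
        """(index, segment) pairs for segments covering ``pos``."""
        if not 1 <= pos <= len(self.query):
            raise MsaError(f"position {pos} outside query of length {len(self.query)}")
        return [(i, s) for i, s in enumerate(self.segments) if s.covers(pos)]

    def invalidate_cache(self) -> None:
        self._cache.clear()


# ---------------------------------------------------------------------------
# BND marking and section identity
# ---------------------------------------------------------------------------

def mark_bnd(segment: AlignedSegment, query: QuerySequence) -> AlignedSegment:
    """Flag boundary residues and compute section identity.

    For every maximal subject-gap run inside the segment, and for every
    subject-insertion event (query-side gap), the ``BND_FLANK`` nearest aligned
    residues on each side are flagged.  Flags never extend past segment ends
    and never sit on a gap.  Idempotent: flags are recomputed from scratch.
    Section identity counts residues identical to the query, with BND
    positions counted as mismatches.
    """
    res = segment.residues
    n = len(res)
    aligned = [i for i in range(n) if res[i] != GAP]
    aligned_arr = np.asarray(aligned, dtype=int)
    flags: set[int] = set()

    def flag_left_of(col: int) -> None:
        # BND_FLANK nearest aligned columns strictly left of `col`
        k = int(np.searchsorted(aligned_arr, col, side="left"))
        for i in aligned[max(0, k - BND_FLANK):k]:
            flags.add(i)

    def flag_right_of(col: int) -> None:
        k = int(np.searchsorted(aligned_arr, col, side="right"))
        for i in aligned[k:k + BND_FLANK]:
            flags.add(i)

    # subject-side gap runs
    i = 0
    while i < n:
        if res[i] == GAP:
            j = i
            while j < n and res[j] == GAP:
                j += 1
            flag_left_of(i)
            flag_right_of(j - 1)
            i = j
        else:
            i += 1

    # query-side gap events: insertion after query position p sits between
    # columns (p - q_start) and (p - q_start + 1)
    for p, _text in segment.insertions:
        col = p - segment.q_start
        flag_left_of(col + 1)
        flag_right_of(col)

    bnd_positions = tuple(sorted(segment.q_start + i for i in flags))

    ident = 0
    for i in aligned:
        if i in flags:
            continue
        if res[i] == query.residue(segment.q_start + i):
            ident += 1
    return replace(segment, bnd=bnd_positions, section_identity=ident)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_query_fasta(path) -> QuerySequence:
    """Read the first record of a FASTA file as the query."""
    queries = read_queries_fasta(path)
    return next(iter(queries.values()))


def read_queries_fasta(path) -> dict[str, QuerySequence]:
    """Read all records of a FASTA file as queries, keyed by protein id."""
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    out: dict[str, QuerySequence] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            pid = header.split()[0]
            out[pid] = QuerySequence(pid, seq.upper())
    if not out:
        raise MsaError(f"{path}: no FASTA records")
    return out


def _parse_alignment_texts(
    subject_id: str,
    q_start: int,
    q_end: int,
    query_text: str,
    subject_text: str,
    query: QuerySequence,
    line_no: int | str,
) -> AlignedSegment:
    if len(query_text) != len(subject_text):
        raise MsaError(
            f"line {line_no}: query/subject alignment strings differ in length"
        )
    ungapped = query_text.replace(GAP, "")
    if len(ungapped) != q_end - q_start + 1:
        raise MsaError(
            f"line {line_no} ({subject_id}): ungapped query text has "
            f"{len(ungapped)} residues but coordinates span {q_end - q_start + 1}"
        )
    expected = query.residues[q_start - 1:q_end]
    if ungapped.upper() != expected:
        raise MsaError(
            f"line {line_no} ({subject_id}): aligned query text disagrees with "
            f"query sequence at [{q_start}, {q_end}]"
        )
    residues: list[str] = []
    insertions: dict[int, str] = {}
    pos = q_start - 1  # last consumed query position
    for qc, sc in zip(query_text.upper(), subject_text.upper()):
        if qc == GAP:
            insertions[pos] = insertions.get(pos, "") + sc
            continue
        pos += 1
        if sc == GAP:
            residues.append(GAP)
        elif sc in AA_SET:
            residues.append(sc)
        else:
            logger.warning(
                "%s line %s: unknown residue %r at query position %d masked to gap",
                subject_id, line_no, sc, pos,
            )
            residues.append(GAP)
    return AlignedSegment(
        subject_id=subject_id,
        taxid=-1,  # caller fills in
        q_start=q_start,
        q_end=q_end,
        residues="".join(residues),
        insertions=tuple(sorted(insertions.items())),
    )


def read_segments(path, query: QuerySequence) -> list[AlignedSegment]:
    """Read homolog alignments (segment TSV or aligned FASTA) against ``query``.

    The TSV dialect has one row per aligned section:
    ``subject_id  taxid  q_start  q_end  query_text  subject_text`` where the
    two text fields are equal-length alignment strings with ``-`` for gaps.
    The aligned-FASTA dialect holds the query first and one query-length row
    per subject (header ``>subject_id taxid=<int>``).  Segments are returned
    BND-marked with section identity populated, unfiltered.
    """
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        segments = _read_aligned_fasta(path, query)
    else:
        segments = _read_segment_tsv(path, query)
    return [mark_bnd(s, query) for s in segments]


def _read_segment_tsv(path, query: QuerySequence) -> list[AlignedSegment]:
    by_key: dict[tuple, AlignedSegment] = {}
    order: list[tuple] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise MsaError(
                    f"{path} line {line_no}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            subject_id, taxid_s, qs_s, qe_s, qtext, stext = fields
            try:
                taxid, qs, qe = int(taxid_s), int(qs_s), int(qe_s)
            except ValueError as exc:
                raise MsaError(f"{path} line {line_no}: {exc}") from exc
            seg = _parse_alignment_texts(
                subject_id, qs, qe, qtext, stext, query, line_no
            )
            seg = replace(seg, taxid=taxid)
            key = (subject_id, qs, qe)
            if key in by_key:
                logger.warning(
                    "%s line %d: duplicate segment %s [%d, %d]; last one wins",
                    path, line_no, subject_id, qs, qe,
                )
            else:
                order.append(key)
            by_key[key] = seg
    return [by_key[k] for k in order]


def _read_aligned_fasta(path, query: QuerySequence) -> list[AlignedSegment]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        records = list(SimpleFastaParser(fh))
    if not records:
        raise MsaError(f"{path}: empty aligned FASTA")
    q_header, q_seq = records[0]
    if q_seq.upper() != query.residues:
        raise MsaError(
            f"{path}: first record {q_header.split()[0]!r} does not match the query"
        )
    segments = []
    for header, seq in records[1:]:
        parts = header.split()
        subject_id = parts[0]
        taxid = None
        for p in parts[1:]:
            if p.startswith("taxid="):
                taxid = int(p.split("=", 1)[1])
        if taxid is None:
            raise MsaError(f"{path}: record {subject_id!r} missing taxid= tag")
        if len(seq) != len(query):
            raise MsaError(
                f"{path}: record {subject_id!r} length {len(seq)} != query "
                f"length {len(query)}"
            )
        seq = seq.upper()
        non_gap = [i for i, c in enumerate(seq) if c != GAP]
        if not non_gap:
            continue
        qs, qe = non_gap[0] + 1, non_gap[-1] + 1
        residues = "".join(
            c if c in AA_SET or c == GAP else GAP for c in seq[qs - 1:qe]
        )
        segments.append(
            AlignedSegment(
                subject_id=subject_id, taxid=taxid,
                q_start=qs, q_end=qe, residues=residues,
            )
        )
    return segments


def write_segments(path, segments: list[AlignedSegment], query: QuerySequence) -> None:
    """Serialize segments to the TSV dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        for seg in segments:
            ins = dict(seg.insertions)
            qchars: list[str] = []
            schars: list[str] = []
            if seg.q_start - 1 in ins:
                text = ins[seg.q_start - 1]
                qchars.append(GAP * len(text))
                schars.append(text)
            for i, sc in enumerate(seg.residues):
                pos = seg.q_start + i
                qchars.append(query.residue(pos))
                schars.append(sc)
                if pos in ins and pos >= seg.q_start:
                    text = ins[pos]
                    qchars.append(GAP * len(text))
                    schars.append(text)
            fh.write(
                "\t".join(
                    [
                        seg.subject_id,
                        str(seg.taxid),
                        str(seg.q_start),
                        str(seg.q_end),
                        "".join(qchars),
                        "".join(schars),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering and depth
# ---------------------------------------------------------------------------

def min_section_length(query_length: int) -> int:
    return min(MIN_SECTION_RESIDUES, math.ceil(MIN_SECTION_FRACTION * query_length))


def segment_percent_identity(segment: AlignedSegment) -> float:
    """Identity over aligned (non-gap) columns; BND columns count as mismatch."""
    if segment.section_identity is None:
        raise MsaError(f"{segment.subject_id}: section identity not computed")
    n = segment.aligned_length
    return 100.0 * segment.section_identity / n if n else 0.0


def passes_filter(segment: AlignedSegment, query: QuerySequence) -> bool:
    return (
        segment_percent_identity(segment) > MIN_SECTION_PIDENT
        and segment.aligned_length >= min_section_length(len(query))
    )


def filter_segments(
    segments: list[AlignedSegment], query: QuerySequence
) -> list[AlignedSegment]:
    """Drop low-identity (<= 40%) and short sections; order preserved."""
    return [s for s in segments if passes_filter(s, query)]


def alignment_depth(msa: MSA, pos: int) -> int:
    """Number of segments with local identity >= 4 at ``pos``."""
    from .measures import li_at

    if not 1 <= pos <= len(msa.query):
        raise MsaError(f"position {pos} outside query of length {len(msa.query)}")
    return sum(1 for i, _seg in msa.segments_at(pos) if li_at(msa, i, pos) >= 4)
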