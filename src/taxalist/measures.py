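"""Taxonomy-aware conservation measures on a query-anchored MSA.

Four per-position quantities drive everything downstream:

* **LI** (local identity): identical residues between a segment and the query
  in a 9-residue window centered at the position, excluding the position
  itself (range 0..8).  Gap and BND columns count as mismatches; a BND residue
  *at* the position forces LI = 0.
* **SI** (section identity): identical residues over the whole aligned
  section, BND counted as mismatch; used only to break LI ties.
* **VST** (variant shared taxa): the ST of the best segment carrying the
  alternate residue at the position — highest LI, ties broken by highest SI,
  then highest ST, then subject id.
* **STP** (shared-taxa profile): for each ST in 1..31, the maximum LI among
  segments whose residue at the position differs from the query reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import GAP, MSA, AlignedSegment, MsaError, QuerySequence
from .taxonomy import MAX_ST, SharedTaxaIndex

WINDOW = 9
HALF_WINDOW = WINDOW // 2
LI_MAX = WINDOW - 1
N_ST = MAX_ST - 1  # STP is indexed by ST = 1..31


def local_identity(
    query: QuerySequence, segment: AlignedSegment, pos: int, window: int = WINDOW
) -> int:
    """LI of ``segment`` at query position ``pos``."""
    if not segment.covers(pos):
        raise MsaError(
            f"{segment.subject_id}: position {pos} outside "
            f"[{segment.q_start}, {segment.q_end}]"
        )
    if segment.bnd_at(pos):
        return 0
    half = window // 2
    count = 0
    for p in range(max(1, pos - half), min(len(query), pos + half) + 1):
        if p == pos or not segment.covers(p):
            continue
        r = segment.residue_at(p)
        if r != GAP and not segment.bnd_at(p) and r == query.residue(p):
            count += 1
    return count


def li_profile(
    query: QuerySequence, segment: AlignedSegment, window: int = WINDOW
) -> np.ndarray:
    """Vectorized LI over the segment's covered range (index 0 = q_start)."""
    n = segment.q_end - segment.q_start + 1
    qslice = query.residues[segment.q_start - 1:segment.q_end]
    seg = np.frombuffer(segment.residues.encode(), dtype="S1")
    qarr = np.frombuffer(qslice.encode(), dtype="S1")
    bnd = np.zeros(n, dtype=bool)
    for p in segment.bnd:
        bnd[p - segment.q_start] = True
    match = ((seg == qarr) & (seg != GAP.encode()) & ~bnd).astype(np.int64)
    kernel = np.ones(window, dtype=np.int64)
    windowed = np.convolve(match, kernel, mode="same")
    li = windowed - match
    li[bnd] = 0
    return li


def section_identity(segment: AlignedSegment, query: QuerySequence) -> int:
    """Identical residues over the whole section; BND counts as mismatch."""
    count = 0
    for i, r in enumerate(segment.residues):
        pos = segment.q_start + i
        if r != GAP and not segment.bnd_at(pos) and r == query.residue(pos):
            count += 1
    return count


def _li_cache(msa: MSA) -> list[np.ndarray]:
    cached = msa._cache.get("li")
    if cached is None:
        cached = [li_profile(msa.query, s) for s in msa.segments]
        msa._cache["li"] = cached
    return cached


def _si_cache(msa: MSA) -> list[int]:
    cached = msa._cache.get("si")
    if cached is None:
        cached = [
            s.section_identity
            if s.section_identity is not None
            else section_identity(s, msa.query)
            for s in msa.segments
        ]
        msa._cache["si"] = cached
    return cached


def li_at(msa: MSA, segment_index: int, pos: int) -> int:
    """Cached LI of segment ``segment_index`` at ``pos``."""
    seg = msa.segments[segment_index]
    if not seg.covers(pos):
        raise MsaError(f"{seg.subject_id}: position {pos} not covered")
    return int(_li_cache(msa)[segment_index][pos - seg.q_start])


@dataclass(frozen=True)
class VSTResult:
    """Outcome of the best-matching-segment search for one substitution."""

    matched: bool
    vst: int | None
    li_max: int
    si: int
    source_segment: AlignedSegment | None

    @classmethod
    def no_match(cls) -> "VSTResult":
        return cls(matched=False, vst=None, li_max=0, si=0, source_segment=None)


def variant_shared_taxa(
    msa: MSA, pos: int, alt_aa: str, st_index: SharedTaxaIndex
) -> VSTResult:
    """VST for substituting the reference at ``pos`` by ``alt_aa``.

    Among segments whose residue at ``pos`` equals ``alt_aa`` (a gap never
    matches), pick the highest LI; ties broken by highest SI, then highest ST,
    then subject id (stable, order-independent).
    """
    ref = msa.query.residue(pos)
    if alt_aa == ref:
        raise MsaError(f"position {pos}: alternate equals reference {ref!r}")
    li_cache = _li_cache(msa)
    si_cache = _si_cache(msa)
    best_key = None
    best: VSTResult | None = None
    for i, seg in enumerate(msa.segments):
        if not seg.covers(pos) or seg.residue_at(pos) != alt_aa:
            continue
        li = int(li_cache[i][pos - seg.q_start])
        si = int(si_cache[i])
        st = st_index.st(seg.taxid)
        key = (li, si, st, seg.subject_id)
        if best_key is None or key > best_key:
            best_key = key
            best = VSTResult(
                matched=True, vst=st, li_max=li, si=si, source_segment=seg
            )
    return best if best is not None else VSTResult.no_match()


@dataclass(frozen=True)
class STProfile:
    """Per-ST maximum LI at a position; ``values[st - 1]`` holds ST = st."""

    values: np.ndarray  # shape (31,), ints in 0..8

    def __getitem__(self, st: int) -> int:
        if not 1 <= st <= N_ST:
            raise IndexError(f"ST {st} outside 1..{N_ST}")
        return int(self.values[st - 1])


def shared_taxa_profile(
    msa: MSA, pos: int, st_index: SharedTaxaIndex, include_max_st: bool = False
) -> STProfile:
    """STP at ``pos``: max LI per ST over segments differing from the reference.

    Segments with ST 0 never contribute.  Same-species segments (ST = 32) are
    excluded by default; with ``include_max_st`` they are counted at the top
    element (ST 31).
    """
    ref = msa.query.residue(pos)
    li_cache = _li_cache(msa)
    values = np.zeros(N_ST, dtype=np.int64)
    for i, seg in enumerate(msa.segments):
        if not seg.covers(pos):
            continue
        r = seg.residue_at(pos)
        if r == GAP or r == ref:
            continue
        st = st_index.st(seg.taxid)
        if st < 1:
            continue
        if st > N_ST:
            if not include_max_st:
                continue
            st = N_ST
        li = int(li_cache[i][pos - seg.q_start])
        if li > values[st - 1]:
            values[st - 1] = li
    return STProfile(values=values)


def measures_table(msa: MSA, st_index: SharedTaxaIndex):
    """Per-position measures track: depth, max LI, and the 31 STP elements."""
    import pandas as pd

    from .msa import alignment_depth

    li_cache = _li_cache(msa)
    rows = []
    for pos in range(1, len(msa.query) + 1):
        lis = [
            int(li_cache[i][pos - s.q_start])
            for i, s in enumerate(msa.segments)
            if s.covers(pos)
        ]
        stp = shared_taxa_profile(msa, pos, st_index)
        rows.append(
            {
                "protein_id": msa.query.protein_id,
                "pos": pos,
                "depth": alignment_depth(msa, pos),
                "li_max": max(lis) if lis else 0,
                **{f"stp_{st}": stp[st] for st in range(1, N_ST + 1)},
            }
        )
    return pd.DataFrame(rows)
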