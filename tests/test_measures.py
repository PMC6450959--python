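"""Local identity, section identity, VST selection and shared-taxa profiles."""

import numpy as np
import pytest

from taxalist.msa import GAP, MSA, AMINO_ACIDS, AlignedSegment, MsaError, QuerySequence, mark_bnd
from taxalist.measures import (
    N_ST,
    li_at,
    li_profile,
    local_identity,
    measures_table,
    section_identity,
    shared_taxa_profile,
    variant_shared_taxa,
)
from taxalist.taxonomy import Lineage, SharedTaxaIndex


def _index(st_of):
    return SharedTaxaIndex(
        reference_lineage=Lineage(33, tuple(range(1, 34))), st_of=dict(st_of)
    )


def _random_msa(rng, n_seg=12, length=60, gap_rate=0.05):
    query = QuerySequence(
        "q", "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, length))
    )
    segments = []
    for i in range(n_seg):
        qs = int(rng.integers(1, 15))
        qe = int(rng.integers(qs + 20, length + 1))
        res = []
        for p in range(qs, qe + 1):
            r = rng.random()
            if r < gap_rate:
                res.append(GAP)
            elif r < 0.65:
                res.append(query.residues[p - 1])
            else:
                res.append(AMINO_ACIDS[int(rng.integers(0, 20))])
        if all(c == GAP for c in res):
            res[0] = "A"
        segments.append(
            mark_bnd(
                AlignedSegment(
                    subject_id=f"s{i}", taxid=100 + i, q_start=qs, q_end=qe,
                    residues="".join(res),
                ),
                query,
            )
        )
    return MSA(query=query, segments=segments)


def _li_brute(query, seg, pos, window=9):
    if seg.bnd_at(pos):
        return 0
    half = window // 2
    n = 0
    for p in range(pos - half, pos + half + 1):
        if p == pos or p < 1 or p > len(query) or not seg.covers(p):
            continue
        r = seg.residue_at(p)
        if r != GAP and not seg.bnd_at(p) and r == query.residue(p):
            n += 1
    return n


class TestLocalIdentity:
    def test_identical_window_scores_eight(self, fig):
        query, msa, _ = fig
        assert local_identity(query, msa.segments[0], 11) == 8

    def test_bnd_at_position_forces_zero(self):
        query = QuerySequence("q", "MKTLVDAGERSFHWNPYQICL")
        res = query.residues[:9] + GAP + query.residues[10:]
        seg = mark_bnd(
            AlignedSegment(subject_id="s", taxid=1, q_start=1, q_end=21,
                           residues=res),
            query,
        )
        assert seg.bnd_at(11)  # flanking residue of the gap at 10
        assert local_identity(query, seg, 11) == 0

    def test_uncovered_position_raises(self, fig):
        query, msa, _ = fig
        seg = msa.segments[0]
        with pytest.raises(MsaError):
            local_identity(query, AlignedSegment(
                subject_id="s", taxid=1, q_start=1, q_end=5, residues="MKTLV"
            ), 11)

    def test_matches_brute_force_everywhere(self, rng):
        for _ in range(5):
            msa = _random_msa(rng)
            for i, seg in enumerate(msa.segments):
                prof = li_profile(msa.query, seg)
                for pos in range(seg.q_start, seg.q_end + 1):
                    expected = _li_brute(msa.query, seg, pos)
                    assert local_identity(msa.query, seg, pos) == expected
                    assert prof[pos - seg.q_start] == expected
                    assert li_at(msa, i, pos) == expected
                    assert 0 <= expected <= 8

    def test_window_truncated_at_termini(self):
        query = QuerySequence("q", "MKTLVDAGER")
        seg = mark_bnd(
            AlignedSegment(subject_id="s", taxid=1, q_start=1, q_end=10,
                           residues=query.residues),
            query,
        )
        assert local_identity(query, seg, 1) == 4  # only right half available
        assert local_identity(query, seg, 10) == 4


class TestSectionIdentity:
    def test_fully_identical_section(self):
        query = QuerySequence("q", "MKTLVDAGERSFHWNPYQICLAVDESTGHKLMKTLVDAGERSFHWNPYQI")
        seg = mark_bnd(
            AlignedSegment(subject_id="s", taxid=1, q_start=1, q_end=50,
                           residues=query.residues),
            query,
        )
        assert section_identity(seg, query) == 50
        assert seg.section_identity == 50

    def test_bnd_counts_as_mismatch(self):
        query = QuerySequence("q", "MKTLVDAGERSFHWNPYQICLAVDESTGHKLMKTLVDAGERSFHWNPYQIC")
        # one interior gap creates 4 BND flags on identical residues
        res = query.residues[:25] + GAP + query.residues[26:]
        seg = mark_bnd(
            AlignedSegment(subject_id="s", taxid=1, q_start=1, q_end=51,
                           residues=res),
            query,
        )
        assert len(seg.bnd) == 4
        assert seg.section_identity == 51 - 1 - 4  # gap column + 4 BND

    def test_matches_brute_force(self, rng):
        msa = _random_msa(rng)
        for seg in msa.segments:
            brute = sum(
                1
                for p in range(seg.q_start, seg.q_end + 1)
                if seg.residue_at(p) != GAP
                and not seg.bnd_at(p)
                and seg.residue_at(p) == msa.query.residue(p)
            )
            assert section_identity(seg, msa.query) == brute


class TestVariantSharedTaxa:
    def test_toy_substitution_selects_st_22(self, fig):
        _, msa, idx = fig
        v = variant_shared_taxa(msa, 11, "A", idx)
        assert v.matched and v.vst == 22
        assert v.li_max == 7
        assert v.source_segment.subject_id == "seq5"

    def test_no_match_returns_unmatched(self, fig):
        _, msa, idx = fig
        v = variant_shared_taxa(msa, 11, "W", idx)
        assert not v.matched and v.li_max == 0 and v.vst is None

    def test_alt_equal_reference_raises(self, fig):
        _, msa, idx = fig
        with pytest.raises(MsaError):
            variant_shared_taxa(msa, 11, "S", idx)

    def test_tie_breaking_matches_exhaustive_argmax(self, rng):
        # 100 random columns with planted LI and SI ties
        from taxalist.measures import _li_cache, _si_cache

        for _ in range(100):
            msa = _random_msa(rng, n_seg=8, length=40, gap_rate=0.0)
            st_of = {100 + i: int(rng.integers(1, 32)) for i in range(8)}
            # plant ties: clone some segments under new ids/taxids
            clones = []
            for i in range(3):
                src = msa.segments[int(rng.integers(0, 8))]
                taxid = 200 + i
                st_of[taxid] = int(rng.integers(1, 32))
                clones.append(
                    AlignedSegment(
                        subject_id=f"c{i}", taxid=taxid, q_start=src.q_start,
                        q_end=src.q_end, residues=src.residues, bnd=src.bnd,
                        section_identity=src.section_identity,
                    )
                )
            msa = MSA(query=msa.query, segments=msa.segments + clones)
            idx = _index(st_of)
            pos = int(rng.integers(16, 25))
            ref = msa.query.residue(pos)
            alt = AMINO_ACIDS[(AMINO_ACIDS.index(ref) + 1) % 20]
            got = variant_shared_taxa(msa, pos, alt, idx)
            cands = [
                (
                    _li_cache(msa)[i][pos - s.q_start],
                    _si_cache(msa)[i],
                    idx.st(s.taxid),
                    s.subject_id,
                )
                for i, s in enumerate(msa.segments)
                if s.covers(pos) and s.residue_at(pos) == alt
            ]
            if not cands:
                assert not got.matched
            else:
                li, si, st, sid = max(cands)
                assert (got.li_max, got.si, got.vst,
                        got.source_segment.subject_id) == (li, si, st, sid)

    def test_selection_invariant_to_segment_order(self, rng, fig):
        _, msa, idx = fig
        perm = list(range(len(msa.segments)))
        rng.shuffle(perm)
        shuffled = MSA(query=msa.query, segments=[msa.segments[i] for i in perm])
        a = variant_shared_taxa(msa, 11, "A", idx)
        b = variant_shared_taxa(shuffled, 11, "A", idx)
        assert (a.vst, a.li_max, a.si, a.source_segment.subject_id) == (
            b.vst, b.li_max, b.si, b.source_segment.subject_id
        )


class TestSharedTaxaProfile:
    def test_toy_profile_elements(self, fig):
        _, msa, idx = fig
        stp = shared_taxa_profile(msa, 11, idx)
        assert stp[21] == 5
        assert stp[22] == 7

    def test_toy_profile_full_scan(self, fig):
        _, msa, idx = fig
        from taxalist.measures import _li_cache

        stp = shared_taxa_profile(msa, 11, idx)
        for st in range(1, N_ST + 1):
            expected = 0
            for i, seg in enumerate(msa.segments):
                if (
                    seg.residue_at(11) != msa.query.residue(11)
                    and seg.residue_at(11) != GAP
                    and idx.st(seg.taxid) == st
                ):
                    expected = max(expected, int(_li_cache(msa)[i][11 - seg.q_start]))
            assert stp[st] == expected

    def test_all_reference_column_gives_zero_profile(self):
        query = QuerySequence("q", "MKTLVDAGERSFHWNPYQICL")
        segs = [
            mark_bnd(
                AlignedSegment(subject_id=f"s{i}", taxid=100 + i, q_start=1,
                               q_end=21, residues=query.residues),
                query,
            )
            for i in range(5)
        ]
        msa = MSA(query=query, segments=segs)
        idx = _index({100 + i: 10 + i for i in range(5)})
        assert shared_taxa_profile(msa, 11, idx).values.sum() == 0

    def test_matching_reference_segment_never_changes_profile(self, fig):
        query, msa, idx = fig
        extra = mark_bnd(
            AlignedSegment(subject_id="ref_like", taxid=msa.segments[1].taxid,
                           q_start=1, q_end=21, residues=query.residues),
            query,
        )
        grown = MSA(query=query, segments=msa.segments + [extra])
        a = shared_taxa_profile(msa, 11, idx)
        b = shared_taxa_profile(grown, 11, idx)
        assert np.array_equal(a.values, b.values)

    def test_same_species_excluded_by_default(self, fig):
        query, msa, idx = fig
        res = list(query.residues)
        res[10] = "A"
        same_species = mark_bnd(
            AlignedSegment(subject_id="human_dup", taxid=33, q_start=1,
                           q_end=21, residues="".join(res)),
            query,
        )
        grown = MSA(query=query, segments=msa.segments + [same_species])
        assert idx.st(33) == 32
        default = shared_taxa_profile(grown, 11, idx)
        assert np.array_equal(default.values, shared_taxa_profile(msa, 11, idx).values)
        included = shared_taxa_profile(grown, 11, idx, include_max_st=True)
        assert included[31] == 8


class TestMeasuresTable:
    def test_track_shape_and_depth_column(self, fig):
        _, msa, idx = fig
        df = measures_table(msa, idx)
        assert len(df) == 21
        assert df.loc[df.pos == 11, "depth"].item() == 5
        assert df.loc[df.pos == 11, "stp_22"].item() == 7
        assert {f"stp_{i}" for i in range(1, 32)} <= set(df.columns)
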