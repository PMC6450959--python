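"""Synthetic inputs: toy fixtures, random taxonomies, and labeled benchmarks.

The labeled-benchmark generator embodies the method's core hypothesis:
benign substitutions tend to match residues observed in species close to the
reference lineage (high ST) with high local identity, while deleterious
substitutions match only distant species or nothing at all.  A single
``contrast`` knob scales every label dependence, so ``contrast=0`` yields a
signal-free null benchmark.  The generator targets the statistical structure
the scoring pipeline consumes — per-position match/ST/LI patterns — not
realistic sequence evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import LabeledVariant
from .measures import N_ST
from .msa import AMINO_ACIDS, MSA, AlignedSegment, QuerySequence, mark_bnd
from .taxonomy import (
    Lineage,
    SharedTaxaIndex,
    TaxonomyStore,
    build_shared_taxa_index,
)

_AA = np.array(list(AMINO_ACIDS))


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the labeled-benchmark generator.

    ``contrast`` in [0, 1] scales every benign/deleterious asymmetry: the
    ST-dependence of match probabilities, the LI gap, the ST bias of the
    variant's own matching segment, and the swap-ability difference.  The
    no-match rates default to the fractions observed among real deleterious
    (43.4%) and benign (15.1%) variants.  Depth is controlled through the
    per-protein segment count (``depth_profile``: fraction of proteins per
    segment-count range), keeping LI structure and depth independently
    tunable.
    """

    seed: int
    n_proteins: int = 40
    protein_length: int = 200
    lineage_edges: int = 32
    species_per_st: int = 4
    contrast: float = 1.0
    p_no_match_deleterious: float = 0.434
    p_no_match_benign: float = 0.151
    benign_match_st_bias: float = 4.0
    deleterious_match_st_bias: float = 4.0
    st_weights: tuple[float, ...] | None = None  # over ST = 1..31
    depth_profile: tuple[tuple[float, tuple[int, int]], ...] = (
        (0.9, (32, 64)),
        (0.1, (3, 20)),
    )
    position_spacing: int = 10
    deleterious_fraction: float = 0.5
    base_mismatch_rate: float = 0.15
    test_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if not 0.0 <= self.contrast <= 1.0:
            raise SimulationError("contrast must be in [0, 1]")
        if self.st_weights is not None:
            w = np.asarray(self.st_weights, dtype=float)
            if w.shape != (N_ST,) or w.sum() <= 0 or np.any(w < 0):
                raise SimulationError(f"st_weights must be {N_ST} non-negative weights")
        total = sum(f for f, _ in self.depth_profile)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise SimulationError("depth_profile fractions must sum to 1")
        if self.protein_length < self.position_spacing + 10:
            raise SimulationError("protein_length too short for any labeled position")

    @classmethod
    def strong_contrast(cls, seed: int, **kw) -> "SimConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def null(cls, seed: int, **kw) -> "SimConfig":
        """Signal-free configuration: no label dependence anywhere."""
        kw.setdefault("contrast", 0.0)
        kw.setdefault("p_no_match_deleterious", 0.3)
        kw.setdefault("p_no_match_benign", 0.3)
        return cls(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Planted statistical structure
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def match_probability(cfg: SimConfig, st: np.ndarray | int, label: str) -> np.ndarray:
    """Probability that some segment of shared-taxa ``st`` carries a
    non-reference residue at a labeled position."""
    st = np.asarray(st, dtype=float)
    sign = 1.0 if label == "benign" else -1.0
    return 0.1 + 0.6 * cfg.contrast * _sigmoid(sign * (st - 18.0) / 3.0)


def li_support(cfg: SimConfig, label: str) -> np.ndarray:
    """Support of the planted LI for matching segments (uniform over it)."""
    if label == "benign":
        lo = 1 + round(4 * cfg.contrast)
        return np.arange(lo, 9)
    hi = 8 - round(3 * cfg.contrast)
    return np.arange(1, hi + 1)


def variant_st_weights(cfg: SimConfig, label: str) -> np.ndarray:
    """ST distribution of the segment matching the variant's own residue."""
    st = np.arange(1, N_ST + 1, dtype=float)
    if label == "benign":
        w = np.exp(cfg.contrast * st / cfg.benign_match_st_bias)
    else:
        w = np.exp(-cfg.contrast * st / cfg.deleterious_match_st_bias)
    return w / w.sum()


def planted_substitution_matrices(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth substitution rows for (deleterious, benign) alt draws."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA17]))
    off = ~np.eye(20, dtype=bool)
    pr0 = rng.dirichlet(np.full(19, 0.5), size=20)
    pc0 = rng.dirichlet(np.full(19, 0.5), size=20)

    def expand(rows):
        full = np.zeros((20, 20))
        for r in range(20):
            full[r, off[r]] = rows[r]
        return full

    pr0, pc0 = expand(pr0), expand(pc0)
    pr_eff = cfg.contrast * pr0 + (1.0 - cfg.contrast) * pc0
    return pr_eff, pc0


def planted_am(cfg: SimConfig) -> np.ndarray:
    """Expected swap-ability matrix implied by the planted substitution rows."""
    pr, pc = planted_substitution_matrices(cfg)
    off = ~np.eye(20, dtype=bool)
    denom = pr + pc
    am = np.where(off & (denom > 0), pr / np.where(denom > 0, denom, 1.0), np.nan)
    return am


def planted_profiles(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form expected LSTP center and span under the planted model."""
    sts = np.arange(1, N_ST + 1)
    out = {}
    for label in ("deleterious", "benign"):
        p = match_probability(cfg, sts, label)
        mean_lstp = np.mean(np.log10(1.0 + li_support(cfg, label)))
        out[label] = p * mean_lstp
    center = (out["deleterious"] + out["benign"]) / 2.0
    span = out["deleterious"] - out["benign"]
    return center, span


# ---------------------------------------------------------------------------
# Taxonomy generation
# ---------------------------------------------------------------------------

def gen_taxonomy(cfg: SimConfig) -> tuple[TaxonomyStore, SharedTaxaIndex]:
    """A rooted tree with a reference lineage of ``lineage_edges`` edges and
    ``species_per_st`` species at every ST in 1..31.

    Node ids: reference path nodes are 1..(edges+1) (root = 1); each ST has
    an off-path branch node 10000+st and species leaves 100000+st*100+j.
    """
    edges = cfg.lineage_edges
    parent: dict[int, int] = {1: 1}
    for i in range(2, edges + 2):
        parent[i] = i - 1
    species: list[int] = []
    for st in range(1, N_ST + 1):
        branch = 10_000 + st
        parent[branch] = st + 1  # child of the st-th path node below root
        for j in range(cfg.species_per_st):
            leaf = 100_000 + st * 100 + j
            parent[leaf] = branch
            species.append(leaf)
    store = TaxonomyStore(parent=parent)
    reference_taxid = edges + 1
    index = build_shared_taxa_index(
        store, reference_taxid, species + [reference_taxid]
    )
    return store, index


def species_for_st(cfg: SimConfig, st: int, j: int) -> int:
    return 100_000 + st * 100 + (j % cfg.species_per_st)


# ---------------------------------------------------------------------------
# Labeled dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Generated study inputs: taxonomy, per-protein MSAs, labeled splits."""

    config: SimConfig
    store: TaxonomyStore
    st_index: SharedTaxaIndex
    msas: dict[str, MSA]
    train: list[LabeledVariant]
    test: list[LabeledVariant]

    def msas_for(self, variants: list[LabeledVariant]) -> dict[str, MSA]:
        pids = {v.protein_id for v in variants}
        return {p: self.msas[p] for p in pids}

    def write(self, out_dir) -> None:
        """Write query FASTA, per-protein segment TSVs, lineage TSV and
        variant TSVs into ``out_dir``."""
        import os

        from .calibration import write_variants_tsv
        from .msa import write_segments
        from .taxonomy import write_lineage_tsv

        os.makedirs(os.path.join(out_dir, "segments"), exist_ok=True)
        with open(os.path.join(out_dir, "queries.fasta"), "w") as fh:
            for pid in sorted(self.msas):
                fh.write(f">{pid}\n{self.msas[pid].query.residues}\n")
        for pid in sorted(self.msas):
            write_segments(
                os.path.join(out_dir, "segments", f"{pid}.tsv"),
                self.msas[pid].segments,
                self.msas[pid].query,
            )
        lineages = [
            self.store.lineage(t) for t in sorted(self.st_index.st_of)
        ]
        write_lineage_tsv(os.path.join(out_dir, "lineages.tsv"), lineages)
        write_variants_tsv(os.path.join(out_dir, "variants_train.tsv"), self.train)
        write_variants_tsv(os.path.join(out_dir, "variants_test.tsv"), self.test)

    @property
    def reference_taxid(self) -> int:
        return self.config.lineage_edges + 1


def _draw_alt(rng, rows: np.ndarray, ref_idx: int) -> str:
    p = rows[ref_idx].copy()
    p[ref_idx] = 0.0
    p = p / p.sum()
    return str(_AA[rng.choice(20, p=p)])


def _mutate_everywhere(rng, query_arr: np.ndarray, rate: float) -> np.ndarray:
    """Copy of the query with random substitutions at the given rate."""
    out = query_arr.copy()
    mask = rng.random(out.size) < rate
    k = int(mask.sum())
    if k:
        subs = _AA[rng.integers(0, 20, size=k)]
        same = subs == out[mask]
        # rotate residues that landed on the original letter
        idx = (np.searchsorted(_AA, subs[same]) + 1) % 20
        subs[same] = _AA[idx]
        out[mask] = subs
    return out


def gen_labeled_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate MSAs plus labeled train/test variant sets (split by protein)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    store, st_index = gen_taxonomy(cfg)
    pr_eff, pc0 = planted_substitution_matrices(cfg)

    st_w = (
        np.asarray(cfg.st_weights, dtype=float)
        if cfg.st_weights is not None
        else np.ones(N_ST)
    )
    st_w = st_w / st_w.sum()

    depth_fracs = np.asarray([f for f, _ in cfg.depth_profile])
    depth_ranges = [r for _, r in cfg.depth_profile]

    msas: dict[str, MSA] = {}
    variants: dict[str, list[LabeledVariant]] = {}
    positions = list(range(6, cfg.protein_length - 4, cfg.position_spacing))
    if not positions:
        raise SimulationError("no labeled positions fit the protein length")

    for pi in range(cfg.n_proteins):
        pid = f"SYN{pi:04d}"
        query_arr = _AA[rng.integers(0, 20, size=cfg.protein_length)]
        query = QuerySequence(pid, "".join(query_arr))

        bucket = int(rng.choice(len(depth_ranges), p=depth_fracs))
        lo, hi = depth_ranges[bucket]
        n_seg = int(rng.integers(lo, hi + 1))
        seg_sts = list(range(1, min(N_ST, n_seg) + 1))
        rng.shuffle(seg_sts)
        while len(seg_sts) < n_seg:
            seg_sts.append(int(rng.choice(N_ST, p=st_w)) + 1)
        seg_arrays = [
            _mutate_everywhere(rng, query_arr, cfg.base_mismatch_rate)
            for _ in range(n_seg)
        ]
        carrier_of: dict[int, int] = {}
        for i, st in enumerate(seg_sts):
            carrier_of.setdefault(st, i)

        pvars: list[LabeledVariant] = []
        for pos in positions:
            label = (
                "deleterious"
                if rng.random() < cfg.deleterious_fraction
                else "benign"
            )
            ref = query_arr[pos - 1]
            ref_idx = int(np.searchsorted(_AA, ref))
            rows = pr_eff if label == "deleterious" else pc0
            alt = _draw_alt(rng, rows, ref_idx)

            window = [p for p in range(pos - 4, pos + 5) if p != pos]
            # clean baseline: every segment matches the query in the window
            for arr in seg_arrays:
                for p in window:
                    arr[p - 1] = query_arr[p - 1]
                arr[pos - 1] = ref

            support = li_support(cfg, label)
            pool = [a for a in AMINO_ACIDS if a != ref and a != alt]

            def plant(seg_i: int, residue: str) -> None:
                li = int(rng.choice(support))
                arr = seg_arrays[seg_i]
                keep = rng.choice(8, size=li, replace=False)
                for wi, p in enumerate(window):
                    if wi in keep:
                        arr[p - 1] = query_arr[p - 1]
                    else:
                        cur = query_arr[p - 1]
                        choice = _AA[(np.searchsorted(_AA, cur) + 7) % 20]
                        arr[p - 1] = choice
                arr[pos - 1] = residue

            for st, seg_i in carrier_of.items():
                if rng.random() < match_probability(cfg, st, label):
                    plant(seg_i, str(rng.choice(pool)))

            p_no = (
                cfg.p_no_match_deleterious
                if label == "deleterious"
                else cfg.p_no_match_benign
            )
            if rng.random() >= p_no:
                w = variant_st_weights(cfg, label)
                avail = sorted(carrier_of)
                wa = w[[st - 1 for st in avail]]
                st_star = int(rng.choice(avail, p=wa / wa.sum()))
                plant(carrier_of[st_star], alt)

            af = (
                float(rng.uniform(0.00015, 0.0003))
                if label == "deleterious"
                else float(rng.uniform(0.005, 0.05))
            )
            pvars.append(
                LabeledVariant(
                    protein_id=pid, pos=pos, ref_aa=str(ref), alt_aa=alt,
                    label=label, allele_freq=af,
                )
            )

        segments = [
            mark_bnd(
                AlignedSegment(
                    subject_id=f"{pid}_S{i:03d}",
                    taxid=species_for_st(cfg, seg_sts[i], i),
                    q_start=1,
                    q_end=cfg.protein_length,
                    residues="".join(seg_arrays[i]),
                ),
                query,
            )
            for i in range(n_seg)
        ]
        msas[pid] = MSA(query=query, segments=segments)
        variants[pid] = pvars

    pids = sorted(msas)
    rng.shuffle(pids)
    n_test = int(round(cfg.test_fraction * len(pids)))
    test_pids = set(pids[:n_test])
    train = [v for p in pids[n_test:] for v in variants[p]]
    test = [v for p in sorted(test_pids) for v in variants[p]]
    return SyntheticDataset(
        config=cfg, store=store, st_index=st_index, msas=msas,
        train=train, test=test,
    )


# ---------------------------------------------------------------------------
# Canonical toy fixture
# ---------------------------------------------------------------------------

#: 21-residue toy query; the illustrated position tau = 11 carries S
FIG_QUERY = "MKTLVDAGERSFHWNPYQICL"
FIG_TAU = 11

# per-subject (ST, residue at tau, {window position: residue} overrides);
# every unlisted position is identical to the query.  The resulting local
# identities at tau are 8, 6, 5, 3, 7, 4 and 2.
_FIG_SUBJECTS = [
    ("seq1", 29, "S", {}),
    ("seq2", 25, "T", {7: "V", 8: "A"}),
    ("seq3", 21, "G", {7: "S", 9: "D", 15: "K"}),
    ("seq4", 21, "N", {8: "T", 9: "A", 12: "Y", 13: "R", 14: "G"}),
    ("seq5", 22, "A", {12: "L"}),
    ("seq6", 22, "A", {7: "C", 8: "D", 9: "K", 10: "W"}),
    ("seq7", 13, "D", {7: "G", 8: "E", 9: "R", 10: "D", 12: "W", 13: "E"}),
]


def fig_fixture() -> tuple[QuerySequence, MSA, SharedTaxaIndex]:
    """The toy seven-subject MSA used for the worked examples.

    Substituting the reference S at tau by A gives VST 22 (A occurs in the
    two ST-22 subjects; the one with LI 7 wins), and the shared-taxa profile
    at tau holds 5 at element 21 and 7 at element 22.
    """
    query = QuerySequence("FIG_QUERY", FIG_QUERY)
    edges = 32
    parent: dict[int, int] = {1: 1}
    for i in range(2, edges + 2):
        parent[i] = i - 1
    segments = []
    taxids = []
    used: dict[int, int] = {}
    for name, st, tau_res, overrides in _FIG_SUBJECTS:
        j = used.get(st, 0)
        used[st] = j + 1
        branch = 10_000 + st
        leaf = 100_000 + st * 100 + j
        parent[branch] = st + 1
        parent[leaf] = branch
        taxids.append(leaf)
        residues = list(FIG_QUERY)
        residues[FIG_TAU - 1] = tau_res
        for p, aa in overrides.items():
            residues[p - 1] = aa
        segments.append(
            mark_bnd(
                AlignedSegment(
                    subject_id=name, taxid=leaf, q_start=1,
                    q_end=len(FIG_QUERY), residues="".join(residues),
                ),
                query,
            )
        )
    store = TaxonomyStore(parent=parent)
    st_index = build_shared_taxa_index(store, edges + 1, taxids + [edges + 1])
    return query, MSA(query=query, segments=segments), st_index
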