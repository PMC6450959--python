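"""Training of every learned component and the serialized model.

The trainable parts are, in pipeline order:

1. PM2 center/span profiles — the mean log shared-taxa profile of positions
   carrying only deleterious variants vs. positions carrying only benign
   variants; the center is their midpoint and the span their difference.
2. AM count matrices — rare and common substitution counts, row-normalized
   per reference amino acid.
3. Depth-compensation tables — per-depth-bin PM2 ranges (so PM2 can be
   shifted onto a common scale), per-bin smoothed deleterious probabilities
   (multiplied into PVM/PM1/PM2), and global raw-score medians used as a
   fallback for positions with alignment depth below 3.
4. Fusion parameters — per-module rescale ranges, weights learned by a
   coordinate-ascent grid search maximizing AUC, and the per-node and final
   redistribution maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combine import (
    C_DEFAULT,
    DEFAULT_TOPOLOGY,
    MODULES,
    MonotoneMap,
    fuse,
    rescale,
    weight,
)
from .measures import N_ST
from .scoring import ALPHA, AmMatrix, ModuleScores, Pm2Profiles, lstp_transform
from .msa import AA_INDEX, MSA
from .taxonomy import MAX_ST, SharedTaxaIndex

LABELS = ("deleterious", "benign")
DEPTH_FALLBACK = 3
#: geometric depth-bin edges above the fallback bin [0, 3)
DEFAULT_DEPTH_EDGES = (3, 10, 32, 100, 316, 1000)
MIN_BIN_OCCUPANCY = 200
MODEL_SCHEMA_VERSION = 1


class CalibrationError(ValueError):
    """Degenerate or missing training data."""


@dataclass(frozen=True)
class LabeledVariant:
    """A protein substitution with a benign/deleterious label."""

    protein_id: str
    pos: int
    ref_aa: str
    alt_aa: str
    label: str
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise CalibrationError(
                f"{self.protein_id}:{self.pos}: reference equals alternate"
            )
        if self.label not in LABELS:
            raise CalibrationError(f"unknown label {self.label!r}")


def read_variants_tsv(path) -> list[LabeledVariant]:
    """Variant TSV with header ``protein_id pos ref alt label allele_freq``."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        af = getattr(row, "allele_freq", None)
        out.append(
            LabeledVariant(
                protein_id=str(row.protein_id),
                pos=int(row.pos),
                ref_aa=str(row.ref),
                alt_aa=str(row.alt),
                label=str(row.label),
                allele_freq=None if af is None or pd.isna(af) else float(af),
            )
        )
    return out


def write_variants_tsv(path, variants: list[LabeledVariant]) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": v.protein_id,
                "pos": v.pos,
                "ref": v.ref_aa,
                "alt": v.alt_aa,
                "label": v.label,
                "allele_freq": "" if v.allele_freq is None else v.allele_freq,
            }
            for v in variants
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PM2 profiles
# ---------------------------------------------------------------------------

def partition_positions(
    variants: list[LabeledVariant],
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """Positions carrying only deleterious vs. only benign variants.

    Positions with both classes are excluded from PM2 training.
    """
    seen: dict[tuple[str, int], set[str]] = {}
    for v in variants:
        seen.setdefault((v.protein_id, v.pos), set()).add(v.label)
    del_pos = {k for k, s in seen.items() if s == {"deleterious"}}
    ben_pos = {k for k, s in seen.items() if s == {"benign"}}
    return del_pos, ben_pos


def train_pm2_profiles(
    deleterious_lstps: np.ndarray, benign_lstps: np.ndarray
) -> Pm2Profiles:
    """Center/span profiles from per-position LSTP vectors of the two classes."""
    d = np.atleast_2d(np.asarray(deleterious_lstps, dtype=float))
    b = np.atleast_2d(np.asarray(benign_lstps, dtype=float))
    if d.size == 0 or b.size == 0:
        raise CalibrationError("both variant classes are required to train PM2")
    if d.shape[1] != N_ST or b.shape[1] != N_ST:
        raise CalibrationError(f"LSTP vectors must have {N_ST} elements")
    mean_del = d.mean(axis=0)
    mean_ben = b.mean(axis=0)
    return Pm2Profiles(
        center=(mean_del + mean_ben) / 2.0, span=mean_del - mean_ben
    )


# ---------------------------------------------------------------------------
# AM matrix
# ---------------------------------------------------------------------------

def train_am(variants: list[LabeledVariant], smoothing: bool = True) -> AmMatrix:
    """Swap-ability matrix from labeled substitution counts.

    Deleterious variants populate the rare-class counts CR, benign the
    common-class counts CC (with real allele-frequency data the rare class is
    0.015%-0.03% and the common class >= 0.5%; the trainer accepts any two
    labeled sets).  ``smoothing`` adds +1 Laplace pseudocounts to every
    off-diagonal cell before normalizing.
    """
    cr = np.zeros((20, 20))
    cc = np.zeros((20, 20))
    n_del = n_ben = 0
    for v in variants:
        if v.ref_aa not in AA_INDEX or v.alt_aa not in AA_INDEX:
            continue
        r, x = AA_INDEX[v.ref_aa], AA_INDEX[v.alt_aa]
        if v.label == "deleterious":
            cr[r, x] += 1
            n_del += 1
        else:
            cc[r, x] += 1
            n_ben += 1
    if n_del == 0 or n_ben == 0:
        raise CalibrationError("both variant classes are required to train AM")
    return am_from_counts(cr, cc, smoothing=smoothing)


def am_from_counts(cr: np.ndarray, cc: np.ndarray, smoothing: bool = True) -> AmMatrix:
    """Row-normalize rare/common counts and form the swap-ability ratio."""
    off_diag = ~np.eye(20, dtype=bool)
    cr = np.where(off_diag, np.asarray(cr, dtype=float), 0.0)
    cc = np.where(off_diag, np.asarray(cc, dtype=float), 0.0)
    if smoothing:
        cr = cr + off_diag
        cc = cc + off_diag

    def normalize(m):
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(sums > 0, m / np.where(sums > 0, sums, 1.0), 0.0)
        return p

    pr, pc = normalize(cr), normalize(cc)
    denom = pr + pc
    with np.errstate(invalid="ignore", divide="ignore"):
        am = np.where(denom > 0, pr / np.where(denom > 0, denom, 1.0), 0.5)
    am = np.where(off_diag, am, np.nan)
    pr = np.where(off_diag, pr, np.nan)
    pc = np.where(off_diag, pc, np.nan)
    return AmMatrix(pr=pr, pc=pc, am=am)


# ---------------------------------------------------------------------------
# Depth compensation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthTables:
    """Per-depth-bin PM2 ranges and deleterious probabilities.

    ``bin_edges`` are the lower edges of every bin, starting with the
    fallback bin at 0; bin i spans ``[bin_edges[i], bin_edges[i+1])`` with the
    last bin open-ended.
    """

    bin_edges: tuple[int, ...]
    pm2_range_by_bin: tuple[tuple[float, float], ...]
    global_pm2_range: tuple[float, float]
    p_deleterious_by_bin: tuple[float, ...]
    module_medians: dict[str, float]
    depth_fallback: int = DEPTH_FALLBACK

    def bin_of(self, depth: int) -> int:
        edges = np.asarray(self.bin_edges)
        return int(np.searchsorted(edges, depth, side="right") - 1)


def fit_depth_tables(
    scored: pd.DataFrame,
    range_mode: str = "robust",
    depth_edges=DEFAULT_DEPTH_EDGES,
    min_occupancy: int = MIN_BIN_OCCUPANCY,
    depth_fallback: int = DEPTH_FALLBACK,
    smoothing: bool = True,
) -> DepthTables:
    """Fit compensation tables from raw calibration scores.

    ``scored`` needs columns ``pvm, pm1, pm2, depth, label``.  "Range" is the
    5th-95th percentile band (``range_mode='robust'``) or the literal min-max
    (``range_mode='minmax'``).  Bins with fewer than ``min_occupancy`` points
    are merged rightward; the fallback bin ``[0, depth_fallback)`` is always
    kept.
    """
    if scored.empty:
        raise CalibrationError("empty calibration set")
    medians = {m: float(scored[m].median()) for m in ("pvm", "pm1", "pm2")}

    depth = scored["depth"].to_numpy()
    is_del = (scored["label"] == "deleterious").to_numpy()
    # depth < fallback positions are scored with median modules, so their PM2
    # enters the range statistics as the median too
    pm2 = np.where(depth < depth_fallback, medians["pm2"], scored["pm2"].to_numpy())

    edges = [0] + [e for e in depth_edges if e >= depth_fallback]
    if edges[1] != depth_fallback:
        edges.insert(1, depth_fallback)
    # merge sparse bins rightward (fallback bin excluded)
    while len(edges) > 2:
        counts = _bin_counts(depth, edges)
        sparse = [
            i for i in range(1, len(counts)) if counts[i] < min_occupancy
        ]
        if not sparse:
            break
        i = sparse[0]
        # drop the edge to the right of bin i (or to its left for the last bin)
        drop = i + 1 if i + 1 < len(edges) else i
        if drop == 1:  # never remove the fallback edge
            break
        edges.pop(drop)

    def band(values):
        if values.size == 0:
            return (medians["pm2"], medians["pm2"])
        if range_mode == "minmax":
            return (float(values.min()), float(values.max()))
        if range_mode == "robust":
            lo, hi = np.percentile(values, [5.0, 95.0])
            return (float(lo), float(hi))
        raise CalibrationError(f"unknown range mode {range_mode!r}")

    ranges, probs = [], []
    bounds = edges + [np.inf]
    for i in range(len(edges)):
        in_bin = (depth >= bounds[i]) & (depth < bounds[i + 1])
        ranges.append(band(pm2[in_bin]))
        k, n = int(is_del[in_bin].sum()), int(in_bin.sum())
        if smoothing:
            probs.append((k + 1.0) / (n + 2.0))  # Laplace (k+1)/(n+2)
        else:
            probs.append(k / n if n else 0.5)

    return DepthTables(
        bin_edges=tuple(edges),
        pm2_range_by_bin=tuple(ranges),
        global_pm2_range=band(pm2),
        p_deleterious_by_bin=tuple(probs),
        module_medians=medians,
        depth_fallback=depth_fallback,
    )


def _bin_counts(depth: np.ndarray, edges: list[int]) -> list[int]:
    bounds = edges + [np.inf]
    return [
        int(((depth >= bounds[i]) & (depth < bounds[i + 1])).sum())
        for i in range(len(edges))
    ]


def compensate(scores: ModuleScores, tables: DepthTables) -> ModuleScores:
    """Depth-compensate raw module scores.

    Positions with depth below the fallback first take the stored global
    median PVM/PM1/PM2; then PM2 is shifted from its depth-bin range onto the
    global range, and PVM/PM1/PM2 are multiplied by the bin's deleterious
    probability.  AM is never depth-compensated.
    """
    if tables is None:
        raise CalibrationError("depth tables not fitted")
    fallback = scores.depth < tables.depth_fallback
    pvm, pm1, pm2 = scores.pvm, scores.pm1, scores.pm2
    if fallback:
        pvm = tables.module_medians["pvm"]
        pm1 = tables.module_medians["pm1"]
        pm2 = tables.module_medians["pm2"]
    b = tables.bin_of(scores.depth)
    lo, hi = tables.pm2_range_by_bin[b]
    glo, ghi = tables.global_pm2_range
    if hi - lo > 1e-12:
        pm2 = glo + (ghi - glo) * (pm2 - lo) / (hi - lo)
    else:
        pm2 = (glo + ghi) / 2.0
    p = tables.p_deleterious_by_bin[b]
    return ModuleScores(
        pvm=pvm * p, pm1=pm1 * p, pm2=pm2 * p, am=scores.am,
        depth=scores.depth, low_depth_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class LISTModel:
    """All trained parameters plus the constants of the method."""

    pm2_profiles: Pm2Profiles
    am: AmMatrix
    depth_tables: DepthTables
    rescale_minmax: dict[str, tuple[float, float]]
    omega: dict[str, float]
    maps: dict[str, MonotoneMap]
    topology: tuple = DEFAULT_TOPOLOGY
    window: int = 9
    alpha: int = ALPHA
    C: float = C_DEFAULT
    depth_fallback: int = DEPTH_FALLBACK
    max_st: int = MAX_ST
    include_max_st: bool = False

    def to_json(self) -> str:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "pm2_profiles": {
                "center": self.pm2_profiles.center.tolist(),
                "span": self.pm2_profiles.span.tolist(),
            },
            "am": {
                "pr": _nan_to_none(self.am.pr),
                "pc": _nan_to_none(self.am.pc),
                "am": _nan_to_none(self.am.am),
            },
            "depth_tables": {
                "bin_edges": list(self.depth_tables.bin_edges),
                "pm2_range_by_bin": [list(r) for r in self.depth_tables.pm2_range_by_bin],
                "global_pm2_range": list(self.depth_tables.global_pm2_range),
                "p_deleterious_by_bin": list(self.depth_tables.p_deleterious_by_bin),
                "module_medians": self.depth_tables.module_medians,
                "depth_fallback": self.depth_tables.depth_fallback,
            },
            "rescale_minmax": {k: list(v) for k, v in self.rescale_minmax.items()},
            "omega": self.omega,
            "maps": {k: m.to_dict() for k, m in self.maps.items()},
            "topology": [
                {"name": n["name"], "children": list(n["children"]),
                 "target": n["target"]}
                for n in self.topology
            ],
            "constants": {
                "window": self.window, "alpha": self.alpha, "C": self.C,
                "depth_fallback": self.depth_fallback, "max_st": self.max_st,
                "include_max_st": self.include_max_st,
            },
        }
        return json.dumps(doc)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "LISTModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise CalibrationError(
                f"unsupported model schema {doc.get('schema_version')!r}"
            )
        consts = doc["constants"]
        return cls(
            pm2_profiles=Pm2Profiles(
                center=np.asarray(doc["pm2_profiles"]["center"]),
                span=np.asarray(doc["pm2_profiles"]["span"]),
            ),
            am=AmMatrix(
                pr=_none_to_nan(doc["am"]["pr"]),
                pc=_none_to_nan(doc["am"]["pc"]),
                am=_none_to_nan(doc["am"]["am"]),
            ),
            depth_tables=DepthTables(
                bin_edges=tuple(doc["depth_tables"]["bin_edges"]),
                pm2_range_by_bin=tuple(
                    tuple(r) for r in doc["depth_tables"]["pm2_range_by_bin"]
                ),
                global_pm2_range=tuple(doc["depth_tables"]["global_pm2_range"]),
                p_deleterious_by_bin=tuple(
                    doc["depth_tables"]["p_deleterious_by_bin"]
                ),
                module_medians=doc["depth_tables"]["module_medians"],
                depth_fallback=doc["depth_tables"]["depth_fallback"],
            ),
            rescale_minmax={
                k: tuple(v) for k, v in doc["rescale_minmax"].items()
            },
            omega=doc["omega"],
            maps={k: MonotoneMap.from_dict(m) for k, m in doc["maps"].items()},
            topology=tuple(
                {"name": n["name"], "children": tuple(n["children"]),
                 "target": n["target"]}
                for n in doc["topology"]
            ),
            window=consts["window"], alpha=consts["alpha"], C=consts["C"],
            depth_fallback=consts["depth_fallback"], max_st=consts["max_st"],
            include_max_st=consts["include_max_st"],
        )

    @classmethod
    def load(cls, path) -> "LISTModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _nan_to_none(arr: np.ndarray):
    return [[None if np.isnan(x) else x for x in row] for row in arr]


def _none_to_nan(rows) -> np.ndarray:
    return np.asarray(
        [[np.nan if x is None else x for x in row] for row in rows], dtype=float
    )


# ---------------------------------------------------------------------------
# Weights and redistribution maps
# ---------------------------------------------------------------------------

OMEGA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))


def fit_weights_and_maps(
    comp_df: pd.DataFrame,
    C: float = C_DEFAULT,
    topology=DEFAULT_TOPOLOGY,
    omega_grid=OMEGA_GRID,
    sweeps: int = 2,
    full_grid: bool = False,
    fixed_omega: dict[str, float] | None = None,
):
    """Learn rescale ranges, module weights and redistribution maps.

    ``comp_df`` holds depth-compensated module scores plus ``label``.  Weights
    are searched on the 0.1-step grid by coordinate ascent (two sweeps;
    ``full_grid`` enumerates the whole grid instead), maximizing the AUC of
    the fused root score with the per-node maps refit for every candidate.
    Ties prefer the smaller weight, so an uninformative module sinks to the
    0.1 floor.  Returns ``(rescale_minmax, omega, maps)``.
    """
    from .evaluate import roc_auc

    labels = comp_df["label"].to_numpy()
    if len(set(labels)) < 2:
        raise CalibrationError("calibration set needs both classes")
    y = (labels == "deleterious").astype(int)

    minmax: dict[str, tuple[float, float]] = {}
    rescaled: dict[str, np.ndarray] = {}
    for m in MODULES:
        v = comp_df[m].to_numpy(dtype=float)
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-12:
            hi = lo + 1e-12
        minmax[m] = (lo, hi)
        rescaled[m] = rescale(v, lo, hi, C)

    def auc_for(omega: dict[str, float]) -> float:
        weighted = {m: weight(rescaled[m], omega[m]) for m in MODULES}
        root, _ = fuse(weighted, topology=topology, fit_maps=True, C=C)
        return roc_auc(root, y)

    if fixed_omega is not None:
        omega = dict(fixed_omega)
    elif full_grid:
        import itertools

        best, omega = -np.inf, None
        for combo in itertools.product(omega_grid, repeat=len(MODULES)):
            cand = dict(zip(MODULES, combo))
            a = auc_for(cand)
            if a > best:
                best, omega = a, cand
    else:
        omega = {m: 1.0 for m in MODULES}
        for _ in range(sweeps):
            for m in MODULES:
                best_w, best_a = None, -np.inf
                for w in omega_grid:  # ascending: ties keep the smaller omega
                    a = auc_for({**omega, m: w})
                    if a > best_a + 1e-12:
                        best_a, best_w = a, w
                omega[m] = best_w

    weighted = {m: weight(rescaled[m], omega[m]) for m in MODULES}
    _, maps = fuse(weighted, topology=topology, fit_maps=True, C=C)
    return minmax, omega, maps


# ---------------------------------------------------------------------------
# End-to-end training
# ---------------------------------------------------------------------------

def raw_scores_table(
    msas: dict[str, MSA],
    st_index: SharedTaxaIndex,
    variants: list[LabeledVariant],
    pm2_profiles: Pm2Profiles,
    am: AmMatrix,
    alpha: int = ALPHA,
    include_max_st: bool = False,
) -> pd.DataFrame:
    """Raw module scores + depth for a labeled variant list."""
    from .scoring import raw_module_scores

    rows = []
    for v in variants:
        msa = msas[v.protein_id]
        s = raw_module_scores(
            msa, v.pos, v.alt_aa, st_index, pm2_profiles, am,
            alpha=alpha, include_max_st=include_max_st,
        )
        rows.append(
            {"protein_id": v.protein_id, "pos": v.pos, "ref": v.ref_aa,
             "alt": v.alt_aa, "label": v.label, "pvm": s.pvm, "pm1": s.pm1,
             "pm2": s.pm2, "am": s.am, "depth": s.depth}
        )
    return pd.DataFrame(rows)


def train_model(
    msas: dict[str, MSA],
    st_index: SharedTaxaIndex,
    module_variants: list[LabeledVariant],
    structure_variants: list[LabeledVariant] | None = None,
    *,
    alpha: int = ALPHA,
    C: float = C_DEFAULT,
    range_mode: str = "robust",
    include_max_st: bool = False,
    smoothing: bool = True,
    full_grid: bool = False,
    fixed_omega: dict[str, float] | None = None,
    topology=DEFAULT_TOPOLOGY,
) -> LISTModel:
    """Train a full model.

    ``module_variants`` train the PM2 profiles and the AM matrix;
    ``structure_variants`` (defaulting to the same set) calibrate depth
    compensation, rescale ranges, weights, and redistribution maps —
    mirroring the two-stage optimization of the original method.
    """
    from .measures import shared_taxa_profile

    if structure_variants is None:
        structure_variants = module_variants

    del_pos, ben_pos = partition_positions(module_variants)
    if not del_pos or not ben_pos:
        raise CalibrationError(
            "PM2 training needs single-class positions of both classes"
        )

    def lstps(positions):
        out = []
        for pid, pos in sorted(positions):
            stp = shared_taxa_profile(
                msas[pid], pos, st_index, include_max_st=include_max_st
            )
            out.append(lstp_transform(stp))
        return np.asarray(out)

    pm2_profiles = train_pm2_profiles(lstps(del_pos), lstps(ben_pos))
    am = train_am(module_variants, smoothing=smoothing)

    raw = raw_scores_table(
        msas, st_index, structure_variants, pm2_profiles, am,
        alpha=alpha, include_max_st=include_max_st,
    )
    tables = fit_depth_tables(raw, range_mode=range_mode)

    comp_rows = []
    for row in raw.itertuples(index=False):
        s = ModuleScores(
            pvm=row.pvm, pm1=row.pm1, pm2=row.pm2, am=row.am, depth=row.depth
        )
        c = compensate(s, tables)
        comp_rows.append(
            {"pvm": c.pvm, "pm1": c.pm1, "pm2": c.pm2, "am": c.am,
             "label": row.label}
        )
    comp_df = pd.DataFrame(comp_rows)

    minmax, omega, maps = fit_weights_and_maps(
        comp_df, C=C, topology=topology, full_grid=full_grid,
        fixed_omega=fixed_omega,
    )
    return LISTModel(
        pm2_profiles=pm2_profiles, am=am, depth_tables=tables,
        rescale_minmax=minmax, omega=omega, maps=maps, topology=topology,
        alpha=alpha, C=C, include_max_st=include_max_st,
    )
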