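"""Hierarchical fusion of module scores into the final rank score.

Each depth-compensated module score is affinely rescaled into [C, 1-C]
(C = 0.2 keeps any single module from dominating), shrunk toward the Bayes
identity element 0.5 by a learned weight, and fused bottom-up through a small
tree of naive-Bayes odds products.  Because fused scores of correlated inputs
drift away from 0.5, every internal node's output is redistributed onto a
normal N(0.5, 0.01) truncated to [C, 1-C] before feeding the next level; the
root output is redistributed onto the uniform distribution, so the final
score is a rank score on [0, 1] with higher = more deleterious.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: clip margin keeping pseudo-probabilities away from 0 and 1
C_DEFAULT = 0.2
#: std-dev of the per-node target normal (variance 0.01)
NODE_SIGMA = 0.1
MODULES = ("pvm", "pm1", "pm2", "am")

#: fusion tree: PM1+PM2 (position signal), then PVM, then AM at the root
DEFAULT_TOPOLOGY = (
    {"name": "node1", "children": ("pm1", "pm2"), "target": "truncnorm"},
    {"name": "node2", "children": ("node1", "pvm"), "target": "truncnorm"},
    {"name": "root", "children": ("node2", "am"), "target": "uniform"},
)


class FusionError(ValueError):
    """Invalid fusion inputs or unfitted maps."""


def rescale(score, min_: float, max_: float, C: float = C_DEFAULT):
    """Affine map of ``[min_, max_]`` onto ``[C, 1-C]``, clamped outside."""
    if max_ <= min_:
        raise FusionError(f"degenerate rescale range [{min_}, {max_}]")
    out = C + (1.0 - 2.0 * C) * (np.asarray(score, dtype=float) - min_) / (max_ - min_)
    return np.clip(out, C, 1.0 - C)


def weight(rescaled, omega: float):
    """Shrink toward the Bayes identity 0.5 by module weight ``omega``."""
    if not 0.1 <= omega <= 1.0:
        raise FusionError(f"omega {omega} outside [0.1, 1]")
    return 0.5 + (np.asarray(rescaled, dtype=float) - 0.5) * omega


def bayes_combine(probs):
    """Naive-Bayes odds product: ``prod(p) / (prod(p) + prod(1-p))``.

    Commutative; 0.5 is the identity element.  Inputs must lie strictly
    inside (0, 1) — guaranteed upstream by C-clipping.
    """
    arr = np.atleast_2d(np.asarray(probs, dtype=float))
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise FusionError("bayes_combine inputs must be strictly inside (0, 1)")
    num = np.prod(arr, axis=-1)
    den = num + np.prod(1.0 - arr, axis=-1)
    out = num / den
    return out if out.size > 1 else float(out[0])


@dataclass(frozen=True)
class MonotoneMap:
    """Monotone piecewise-linear map on 1,001 knots; out-of-range clamped."""

    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        if self.xs.shape != self.ys.shape or self.xs.ndim != 1:
            raise FusionError("knot arrays must be 1-D and of equal length")
        if np.any(np.diff(self.xs) < 0) or np.any(np.diff(self.ys) < 0):
            raise FusionError("knots must be non-decreasing")

    def __call__(self, v):
        arr = np.asarray(v, dtype=float)
        out = np.interp(arr, self.xs, self.ys)
        return float(out) if arr.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"xs": self.xs.tolist(), "ys": self.ys.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MonotoneMap":
        return cls(xs=np.asarray(d["xs"]), ys=np.asarray(d["ys"]))


def fit_redistribution(
    sample,
    target: str = "truncnorm",
    C: float = C_DEFAULT,
    sigma: float = NODE_SIGMA,
    n_knots: int = 1001,
) -> MonotoneMap:
    """Quantile map taking ``sample``'s distribution onto the target.

    ``target`` is the truncated normal N(0.5, sigma^2) on [C, 1-C] for
    internal nodes, or the uniform on [0, 1] (an empirical-CDF rank map) for
    the root.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise FusionError("need at least 2 calibration scores to fit a map")
    p = np.linspace(0.0, 1.0, n_knots)
    xs = np.quantile(sample, p)
    xs = np.maximum.accumulate(xs)
    # break exact ties so interpolation is well defined
    span = max(xs[-1] - xs[0], 1.0)
    xs = xs + np.arange(n_knots) * (1e-12 * span)
    if target == "truncnorm":
        a = (C - 0.5) / sigma
        b = (1.0 - C - 0.5) / sigma
        ys = stats.truncnorm.ppf(p, a, b, loc=0.5, scale=sigma)
    elif target == "uniform":
        ys = p
    else:
        raise FusionError(f"unknown redistribution target {target!r}")
    return MonotoneMap(xs=xs, ys=np.asarray(ys))


def redistribute(scores, map_: MonotoneMap):
    """Apply a fitted monotone redistribution map."""
    if map_ is None:
        raise FusionError("redistribution map not fitted")
    return map_(scores)


# ---------------------------------------------------------------------------
# Fusion tree evaluation
# ---------------------------------------------------------------------------

def fuse(
    weighted: dict[str, np.ndarray],
    topology=DEFAULT_TOPOLOGY,
    maps: dict[str, MonotoneMap] | None = None,
    fit_maps: bool = False,
    C: float = C_DEFAULT,
):
    """Evaluate the fusion tree bottom-up.

    ``weighted`` maps module names to (arrays of) weighted scores.  With
    ``fit_maps`` the per-node redistribution maps are fitted on the given
    sample and returned alongside the root scores; otherwise ``maps`` must
    hold a fitted map per node.
    """
    values = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in weighted.items()}
    fitted: dict[str, MonotoneMap] = {}
    out = None
    for node in topology:
        children = [values[c] for c in node["children"]]
        combined = np.atleast_1d(bayes_combine(np.stack(children, axis=-1)))
        if fit_maps:
            m = fit_redistribution(combined, target=node["target"], C=C)
            fitted[node["name"]] = m
        else:
            m = (maps or {}).get(node["name"])
            if m is None:
                raise FusionError(f"no fitted map for fusion node {node['name']!r}")
        values[node["name"]] = np.atleast_1d(np.asarray(m(combined), dtype=float))
        out = values[node["name"]]
    if fit_maps:
        return out, fitted
    return out


def pipeline_scores(comp_df, model) -> np.ndarray:
    """Final scores for a table of depth-compensated module scores."""
    weighted = {}
    for m in MODULES:
        lo, hi = model.rescale_minmax[m]
        weighted[m] = weight(
            rescale(np.asarray(comp_df[m], dtype=float), lo, hi, model.C),
            model.omega[m],
        )
    return np.atleast_1d(
        fuse(weighted, topology=model.topology, maps=model.maps, C=model.C)
    )


def list_score(variant, msa, model, st_index) -> float:
    """End-to-end score for one variant: measures -> modules -> fusion.

    ``variant`` needs ``pos``, ``ref_aa`` and ``alt_aa`` attributes.  Every
    variant is scored regardless of alignment depth (depth < 3 positions fall
    back to stored median module scores).  Higher = more deleterious.
    """
    import pandas as pd

    from .calibration import compensate
    from .msa import MsaError
    from .scoring import raw_module_scores

    pos = variant.pos
    if not 1 <= pos <= len(msa.query):
        raise MsaError(
            f"{msa.query.protein_id}: variant position {pos} outside query of "
            f"length {len(msa.query)}"
        )
    ref = msa.query.residue(pos)
    if variant.ref_aa != ref:
        raise MsaError(
            f"{msa.query.protein_id} position {pos}: variant reference "
            f"{variant.ref_aa!r} does not match query residue {ref!r}"
        )
    raw = raw_module_scores(
        msa, pos, variant.alt_aa, st_index, model.pm2_profiles, model.am,
        alpha=model.alpha, include_max_st=model.include_max_st,
    )
    comp = compensate(raw, model.depth_tables)
    df = pd.DataFrame(
        [{m: getattr(comp, m) for m in MODULES}]
    )
    return float(pipeline_scores(df, model)[0])
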