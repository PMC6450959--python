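"""Raw module scores: PVM, PM1, PM2 and AM.

All four scores are oriented so that higher means more deleterious-like.

* **PVM** maps the variant's VST onto [0, 1]: ``1 - VST/31`` when a matching
  segment with LI_max >= alpha exists, else 1 (no match in any close homolog
  is the strongest deleteriousness signal this measure can give).
* **PM1** is the mean PVM over the 19 possible substitutions at the position.
* **PM2** is a linear contrast of the position's log shared-taxa profile
  against trained center/span profiles: positions whose non-reference
  residues concentrate at taxonomically close species score benign-like.
* **AM** is a learned swap-ability ratio between rare-variant and
  common-variant substitution probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import AA_INDEX, AMINO_ACIDS, MSA, MsaError
from .measures import N_ST, STProfile, VSTResult, variant_shared_taxa
from .taxonomy import SharedTaxaIndex

#: minimum LI_max for a VST match to be trusted as homologous
ALPHA = 4


def pvm_score(v: VSTResult, alpha: int = ALPHA) -> float:
    """Position-variant module score in [0, 1].

    VST is clamped to 31 so a same-species match (ST 32) scores 0 rather
    than going negative.
    """
    if v.matched and v.li_max >= alpha:
        return 1.0 - min(v.vst, N_ST) / N_ST
    return 1.0


def pm1_score(
    msa: MSA, pos: int, st_index: SharedTaxaIndex, alpha: int = ALPHA
) -> float:
    """Mean PVM over all 19 non-reference amino acids at ``pos``."""
    ref = msa.query.residue(pos)
    total = 0.0
    for aa in AMINO_ACIDS:
        if aa == ref:
            continue
        total += pvm_score(variant_shared_taxa(msa, pos, aa, st_index), alpha)
    return total / (len(AMINO_ACIDS) - 1)


def lstp_transform(stp: STProfile | np.ndarray) -> np.ndarray:
    """Element-wise ``log10(1 + STP)``."""
    values = stp.values if isinstance(stp, STProfile) else np.asarray(stp)
    return np.log10(1.0 + values.astype(float))


@dataclass(frozen=True)
class Pm2Profiles:
    """Trained LSTP center and span profiles (one value per ST in 1..31)."""

    center: np.ndarray
    span: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("center", self.center), ("span", self.span)):
            if arr.shape != (N_ST,):
                raise ValueError(f"{name} profile must have shape ({N_ST},)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} profile has non-finite entries")


def pm2_score(lstp: np.ndarray, profiles: Pm2Profiles) -> float:
    """Linear profile contrast: mean of ``(LSTP - center) * span`` over ST."""
    lstp = np.asarray(lstp, dtype=float)
    if lstp.shape != (N_ST,):
        raise ValueError(f"LSTP vector must have shape ({N_ST},)")
    return float(np.sum((lstp - profiles.center) * profiles.span) / N_ST)


@dataclass(frozen=True)
class AmMatrix:
    """Learned amino-acid swap-ability.

    ``pr`` (``pc``) holds per-reference-row substitution probabilities among
    rare (common) variants; ``am = pr / (pr + pc)`` cell-wise, with 0.5 where
    both are zero.  Diagonals are undefined and held at NaN.
    """

    pr: np.ndarray
    pc: np.ndarray
    am: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("pr", self.pr), ("pc", self.pc), ("am", self.am)):
            if arr.shape != (20, 20):
                raise ValueError(f"{name} must be a 20x20 matrix")


def am_score(ref_aa: str, alt_aa: str, m: AmMatrix) -> float:
    """Swap-ability score for a reference -> alternate substitution."""
    if ref_aa == alt_aa:
        raise MsaError(f"reference and alternate both {ref_aa!r}")
    try:
        r, x = AA_INDEX[ref_aa], AA_INDEX[alt_aa]
    except KeyError as exc:
        raise MsaError(f"non-standard amino acid {exc}") from exc
    return float(m.am[r, x])


@dataclass(frozen=True)
class ModuleScores:
    """Raw (or depth-compensated) module scores for one variant."""

    pvm: float
    pm1: float
    pm2: float
    am: float
    depth: int
    low_depth_fallback: bool = False


def raw_module_scores(
    msa: MSA,
    pos: int,
    alt_aa: str,
    st_index: SharedTaxaIndex,
    pm2_profiles: Pm2Profiles,
    am: AmMatrix,
    alpha: int = ALPHA,
    include_max_st: bool = False,
) -> ModuleScores:
    """All four raw scores for one variant (no depth compensation yet)."""
    from .msa import alignment_depth
    from .measures import shared_taxa_profile

    ref = msa.query.residue(pos)
    v = variant_shared_taxa(msa, pos, alt_aa, st_index)
    stp = shared_taxa_profile(msa, pos, st_index, include_max_st=include_max_st)
    return ModuleScores(
        pvm=pvm_score(v, alpha),
        pm1=pm1_score(msa, pos, st_index, alpha),
        pm2=pm2_score(lstp_transform(stp), pm2_profiles),
        am=am_score(ref, alt_aa, am),
        depth=alignment_depth(msa, pos),
    )
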