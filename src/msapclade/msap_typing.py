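"""MSAP methylation typing from paired HpaII/MspI digests.

MSAP replaces the AFLP MseI digest with two isoschizomers, HpaII and MspI,
which both cut 5'-CCGG but differ in sensitivity to cytosine methylation.
The presence pattern of a fragment across the two digests therefore encodes
the methylation state of its CCGG site:

========  =======  =======  ================================
type      HpaII    MspI     interpretation
========  =======  =======  ================================
I         1        1        non-methylated
II        0        1        fully methylated internal cytosine
III       1        0        hemimethylated
IV        0        0        fully methylated (both strands)
========  =======  =======  ================================

Type IV is only interpretable against a locus panel: a band absent from both
digests in *every* sample is indistinguishable from a locus that does not
exist, so the panel is the union of loci amplified in at least one
sample/digest, and "absent in both" counts as IV only inside that panel.

From per-sample type counts the module derives the two standard methylation
indices: overall methylation (MSAP%) and the fully-methylated ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .band_matrix import MISSING, BandMatrix, BandMatrixError


class MsapType(Enum):
    """Methylation class of one (sample, locus) site."""

    I = "I"  # noqa: E741 - field-standard roman numeral
    II = "II"
    III = "III"
    IV = "IV"


#: integer codes used in type matrices; UNTYPED marks missing digest states
TYPE_CODES = {MsapType.I: 1, MsapType.II: 2, MsapType.III: 3, MsapType.IV: 4}
UNTYPED: int = 0


def classify_site(hpa: int, msp: int) -> MsapType:
    """Methylation type of one site from its two digest presence states."""
    if hpa not in (0, 1) or msp not in (0, 1):
        raise ValueError(f"digest states must be 0/1, got ({hpa!r}, {msp!r})")
    return {(1, 1): MsapType.I, (0, 1): MsapType.II,
            (1, 0): MsapType.III, (0, 0): MsapType.IV}[hpa, msp]


def _check_paired(hpa: BandMatrix, msp: BandMatrix) -> None:
    if hpa.sample_ids != msp.sample_ids:
        raise BandMatrixError("HpaII and MspI matrices list different samples")
    if hpa.locus_ids != msp.locus_ids:
        raise BandMatrixError("HpaII and MspI matrices list different loci")


def amplified_panel(hpa: BandMatrix, msp: BandMatrix) -> np.ndarray:
    """Boolean mask of loci amplified in >=1 sample in either digest."""
    _check_paired(hpa, msp)
    return ((hpa.values == 1) | (msp.values == 1)).any(axis=0)


def type_matrix(hpa: BandMatrix, msp: BandMatrix) -> tuple[np.ndarray, list[str]]:
    """Per-cell type codes over the amplified panel.

    Returns ``(codes, panel_locus_ids)`` where ``codes`` is samples x panel
    loci with values in {1..4} (:data:`TYPE_CODES`) or :data:`UNTYPED` where
    either digest state is missing.
    """
    panel = amplified_panel(hpa, msp)
    h = hpa.values[:, panel]
    m = msp.values[:, panel]
    codes = np.zeros(h.shape, dtype=np.int8)
    ok = (h != MISSING) & (m != MISSING)
    codes[ok & (h == 1) & (m == 1)] = TYPE_CODES[MsapType.I]
    codes[ok & (h == 0) & (m == 1)] = TYPE_CODES[MsapType.II]
    codes[ok & (h == 1) & (m == 0)] = TYPE_CODES[MsapType.III]
    codes[ok & (h == 0) & (m == 0)] = TYPE_CODES[MsapType.IV]
    return codes, [l for l, keep in zip(hpa.locus_ids, panel) if keep]


@dataclass
class MsapProfile:
    """Per-sample MSAP type counts and methylation indices."""

    sample_id: str
    type_i_total: int
    type_i_ms: int  # methylation-sensitive subset of type I
    type_ii: int
    type_iii: int
    type_iv: int
    total_amplified: int
    msap_pct: float = float("nan")
    fully_methylated_pct: float = float("nan")

    @property
    def total_methylated(self) -> int:
        return self.type_i_ms + self.type_ii + self.type_iii + self.type_iv


#: predicate(sample_idx, locus_idx, codes) -> is this type-I site
#: "methylation-sensitive"?  Default: the locus is type-polymorphic, i.e.
#: some other sample carries a different (observed) type there.
MsPredicate = Callable[[int, int, np.ndarray], bool]


def _default_ms_predicate(i: int, j: int, codes: np.ndarray) -> bool:
    others = np.delete(codes[:, j], i)
    others = others[others != UNTYPED]
    return bool((others != codes[i, j]).any())


def methylation_indices(
    p: MsapProfile, full_methylation_mode: str = "II+IV"
) -> tuple[float, float]:
    """Overall-methylation and fully-methylated percentages for a profile.

    MSAP% counts every methylation-affected class: the methylation-sensitive
    subset of type I plus types II, III and IV, over total amplified bands.
    The fully-methylated ratio defaults to (II + IV)/total, the definition
    that matches published per-cultivar tables; ``full_methylation_mode="IV"``
    selects the narrower IV-only variant.  Both are rounded half-up to two
    decimals, matching report conventions.
    """
    if p.total_amplified <= 0:
        raise ValueError("total_amplified must be positive")
    msap = 100.0 * p.total_methylated / p.total_amplified
    if full_methylation_mode == "II+IV":
        full = 100.0 * (p.type_ii + p.type_iv) / p.total_amplified
    elif full_methylation_mode == "IV":
        full = 100.0 * p.type_iv / p.total_amplified
    else:
        raise ValueError(f"unknown full_methylation_mode {full_methylation_mode!r}")
    return round_half_up(msap, 2), round_half_up(full, 2)


def profile_sample(
    hpa: BandMatrix,
    msp: BandMatrix,
    sample_id: str,
    ms_predicate: MsPredicate = _default_ms_predicate,
) -> MsapProfile:
    """Type counts and indices for one sample over the amplified panel.

    ``ms_predicate`` decides which type-I sites count as methylation
    sensitive; the default flags sites whose locus is non-type-I in at least
    one other sample.  Sites with a missing digest state are skipped (not
    classified), so counts may sum to less than the panel size for samples
    with missing data.
    """
    codes, _ = type_matrix(hpa, msp)
    i = hpa.sample_index(sample_id)
    row = codes[i]
    counts = {t: int((row == c).sum()) for t, c in TYPE_CODES.items()}
    ms = sum(
        1
        for j in np.flatnonzero(row == TYPE_CODES[MsapType.I])
        if ms_predicate(i, int(j), codes)
    )
    prof = MsapProfile(
        sample_id=sample_id,
        type_i_total=counts[MsapType.I],
        type_i_ms=ms,
        type_ii=counts[MsapType.II],
        type_iii=counts[MsapType.III],
        type_iv=counts[MsapType.IV],
        total_amplified=int((row != UNTYPED).sum()),
    )
    prof.msap_pct, prof.fully_methylated_pct = methylation_indices(prof)
    return prof


def profile_all(hpa: BandMatrix, msp: BandMatrix) -> pd.DataFrame:
    """Per-cultivar type-count/index table for the whole panel."""
    rows = [profile_sample(hpa, msp, s) for s in hpa.sample_ids]
    return pd.DataFrame(
        {
            "sample": [p.sample_id for p in rows],
            "type_I": [p.type_i_total for p in rows],
            "type_I_ms": [p.type_i_ms for p in rows],
            "type_II": [p.type_ii for p in rows],
            "type_III": [p.type_iii for p in rows],
            "type_IV": [p.type_iv for p in rows],
            "total_amplified": [p.total_amplified for p in rows],
            "total_methylated": [p.total_methylated for p in rows],
            "msap_pct": [p.msap_pct for p in rows],
            "fully_methylated_pct": [p.fully_methylated_pct for p in rows],
        }
    )


@dataclass
class CladeFragmentTally:
    """Shared and clade-private locus counts per methylation type.

    ``shared_all[t]`` counts loci uniformly of type ``t`` in every sample;
    ``private_a[t]`` (resp. ``private_b``) counts loci of type ``t`` in every
    member of side A (resp. B) and in no member of the other side.
    """

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    shared_all: dict[MsapType, int]
    private_a: dict[MsapType, int]
    private_b: dict[MsapType, int]


def clade_fragment_tally(
    hpa: BandMatrix,
    msp: BandMatrix,
    partition: tuple[Sequence[str], Sequence[str]],
) -> CladeFragmentTally:
    """Count type-wise shared and clade-private fragments for a 2-way split.

    The partition must cover the full sample set with disjoint, non-empty
    sides.  Untyped (missing) cells block a locus from counting as uniformly
    typed on a side but do count as "absent from the other side" only when
    observed non-``t``.
    """
    side_a, side_b = (tuple(partition[0]), tuple(partition[1]))
    if not side_a or not side_b:
        raise ValueError("both partition sides must be non-empty")
    if set(side_a) & set(side_b):
        raise ValueError("partition sides overlap")
    if set(side_a) | set(side_b) != set(hpa.sample_ids):
        raise ValueError("partition does not cover the sample set")
    codes, _ = type_matrix(hpa, msp)
    ia = [hpa.sample_index(s) for s in side_a]
    ib = [hpa.sample_index(s) for s in side_b]
    shared, priv_a, priv_b = {}, {}, {}
    for t, c in TYPE_CODES.items():
        is_t = codes == c
        observed = codes != UNTYPED
        all_t = is_t.all(axis=0)
        a_all_t = is_t[ia].all(axis=0)
        b_all_t = is_t[ib].all(axis=0)
        a_none_t = (~is_t[ia] & observed[ia]).all(axis=0)
        b_none_t = (~is_t[ib] & observed[ib]).all(axis=0)
        shared[t] = int(all_t.sum())
        priv_a[t] = int((a_all_t & b_none_t).sum())
        priv_b[t] = int((b_all_t & a_none_t).sum())
    return CladeFragmentTally(side_a, side_b, shared, priv_a, priv_b)
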