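"""Binary band matrices for dominant markers (AFLP/MSAP) and their I/O.

Dominant marker systems score each locus per sample as band present (1) or
absent (0) on a gel.  This module holds the core :class:`BandMatrix`
container, delimited-text readers/writers, the monomorphic-locus filter
applied before distance analysis, matrix combination across marker systems,
and per-primer-combination polymorphism summaries.

The canonical file orientation is gel-like: rows are loci, columns are
samples.  Missing scores are written as ``?`` and excluded pairwise in
downstream distance computations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for an unscored cell in ``BandMatrix.values``
MISSING: int = -1

#: recognised marker systems
MARKER_SYSTEMS = ("AFLP", "MSAP_HPAII", "MSAP_MSPI", "MORPHOLOGY", "COMBINED")

_ROWS_ARE_LOCI = "rows-are-loci"
_ROWS_ARE_SAMPLES = "rows-are-samples"


class BandMatrixError(ValueError):
    """Malformed band matrix or band-matrix file."""


@dataclass
class BandMatrix:
    """Samples x loci presence/absence matrix for a dominant marker system.

    Parameters
    ----------
    sample_ids : sequence of str
        Ordered, unique sample labels (rows of ``values``).
    locus_ids : sequence of str
        Ordered, unique locus labels (columns of ``values``).
    values : ndarray of int8
        Entries in {0, 1, MISSING}.
    marker_system : str
        One of :data:`MARKER_SYSTEMS`.
    primer_combo : sequence of str, optional
        Per-locus primer-combination label (needed for
        :func:`polymorphism_summary`).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    marker_system: str = "AFLP"
    primer_combo: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.locus_ids = [str(l).strip() for l in self.locus_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise BandMatrixError("duplicate sample labels")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise BandMatrixError("duplicate locus labels")
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise BandMatrixError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            raise BandMatrixError("entries must be 0, 1 or missing")
        if self.marker_system not in MARKER_SYSTEMS:
            raise BandMatrixError(f"unknown marker system {self.marker_system!r}")
        if self.primer_combo is not None:
            self.primer_combo = [str(c).strip() for c in self.primer_combo]
            if len(self.primer_combo) != len(self.locus_ids):
                raise BandMatrixError("primer_combo length does not match loci")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def row(self, sample_id: str) -> np.ndarray:
        """Band vector (with MISSING sentinels) for one sample."""
        return self.values[self.sample_index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        """Samples x loci DataFrame with NaN for missing cells."""
        vals = self.values.astype(float)
        vals[vals == MISSING] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.locus_ids)

    def reorder_samples(self, order: Sequence[str]) -> "BandMatrix":
        if sorted(order) != sorted(self.sample_ids):
            raise BandMatrixError("reorder must use the same sample set")
        idx = [self.sample_index(s) for s in order]
        return replace(self, sample_ids=list(order), values=self.values[idx])


# -- I/O -------------------------------------------------------------------


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_token(tok: str, path: str | os.PathLike) -> int:
    tok = str(tok).strip()
    if tok == "?":
        return MISSING
    if tok in ("0", "1"):
        return int(tok)
    raise BandMatrixError(f"{path}: entry {tok!r} is not 0, 1 or '?'")


def read_band_matrix(
    path: str | os.PathLike,
    orientation: str = _ROWS_ARE_LOCI,
    marker_system: str = "AFLP",
    primer_combo: Sequence[str] | None = None,
) -> BandMatrix:
    """Read a delimited 0/1/? matrix with a header row and a label column.

    ``orientation`` is ``"rows-are-loci"`` (canonical, gel-like: header row
    holds sample labels) or ``"rows-are-samples"`` (header row holds locus
    labels).  CSV vs TSV is chosen by file extension.
    """
    if orientation not in (_ROWS_ARE_LOCI, _ROWS_ARE_SAMPLES):
        raise BandMatrixError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, header=0)
    if df.isna().any().any():
        raise BandMatrixError(f"{path}: ragged rows or empty cells")
    parsed = df.map(lambda t: _parse_token(t, path))
    values = parsed.to_numpy(dtype=np.int8)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if orientation == _ROWS_ARE_LOCI:
        sample_ids, locus_ids, values = col_labels, row_labels, values.T
    else:
        sample_ids, locus_ids = row_labels, col_labels
    return BandMatrix(
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        values=values,
        marker_system=marker_system,
        primer_combo=list(primer_combo) if primer_combo is not None else None,
    )


def write_band_matrix(
    m: BandMatrix, path: str | os.PathLike, orientation: str = _ROWS_ARE_LOCI
) -> None:
    """Write ``m`` as delimited text; inverse of :func:`read_band_matrix`."""
    if orientation not in (_ROWS_ARE_LOCI, _ROWS_ARE_SAMPLES):
        raise BandMatrixError(f"unknown orientation {orientation!r}")
    tokens = np.where(m.values == MISSING, "?", m.values.astype(str))
    df = pd.DataFrame(tokens, index=m.sample_ids, columns=m.locus_ids)
    if orientation == _ROWS_ARE_LOCI:
        df = df.T
    df.to_csv(path, sep=_sep_for(path))


# -- filtering and combination --------------------------------------------


def is_polymorphic(column: np.ndarray) -> bool:
    """True if a locus column shows >=2 distinct observed (non-missing) states."""
    observed = column[column != MISSING]
    return observed.size > 0 and np.unique(observed).size >= 2


def filter_monomorphic(m: BandMatrix) -> BandMatrix:
    """Drop invariant loci; the standard pre-clustering step for band data.

    A locus is retained iff at least two distinct non-missing states occur
    across samples.  Loci with missing cells still count as variable when
    two observed states remain.  Idempotent; may return a 0-locus matrix.
    """
    keep = [j for j in range(m.n_loci) if is_polymorphic(m.values[:, j])]
    return replace(
        m,
        locus_ids=[m.locus_ids[j] for j in keep],
        values=m.values[:, keep],
        primer_combo=[m.primer_combo[j] for j in keep] if m.primer_combo else None,
    )


def merge_matrices(ms: Sequence[BandMatrix]) -> BandMatrix:
    """Column-concatenate marker matrices over one sample panel.

    Inputs must share the same sample *set* (order may differ; rows are
    aligned by label to the first input's order).  Locus labels are prefixed
    with each input's marker system so the combined labels stay unique.
    """
    if not ms:
        raise BandMatrixError("no matrices to merge")
    ref = ms[0]
    ref_set = set(ref.sample_ids)
    blocks, locus_ids, combos = [], [], []
    any_combo = any(m.primer_combo is not None for m in ms)
    for m in ms:
        if set(m.sample_ids) != ref_set:
            raise BandMatrixError("sample sets differ between matrices")
        aligned = m.reorder_samples(ref.sample_ids)
        blocks.append(aligned.values)
        locus_ids.extend(f"{m.marker_system}:{l}" for l in m.locus_ids)
        if any_combo:
            combos.extend(
                m.primer_combo if m.primer_combo is not None else [""] * m.n_loci
            )
    return BandMatrix(
        sample_ids=list(ref.sample_ids),
        locus_ids=locus_ids,
        values=np.hstack(blocks),
        marker_system="COMBINED",
        primer_combo=combos if any_combo else None,
    )


# -- polymorphism summaries ------------------------------------------------


@dataclass(frozen=True)
class PolymorphismSummary:
    """Fragment and variable-fragment counts per primer combination."""

    per_combo: dict[str, tuple[int, int]]  # combo -> (n_fragments, n_variable)

    @property
    def total_fragments(self) -> int:
        return sum(n for n, _ in self.per_combo.values())

    @property
    def total_variable(self) -> int:
        return sum(v for _, v in self.per_combo.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [(c, n, v) for c, (n, v) in self.per_combo.items()],
            columns=["primer_combo", "n_fragments", "n_variable"],
        )
        df.loc[len(df)] = ["Total", self.total_fragments, self.total_variable]
        return df


def polymorphism_summary(m: BandMatrix) -> PolymorphismSummary:
    """Count fragments and variable fragments per primer combination.

    "Variable" uses the same rule as :func:`filter_monomorphic`.  Requires
    ``primer_combo``; combinations appear in first-occurrence order.
    """
    if m.primer_combo is None:
        raise BandMatrixError("primer_combo labels required for summary")
    per: dict[str, list[int]] = {}
    for j, combo in enumerate(m.primer_combo):
        n, v = per.setdefault(combo, [0, 0])
        per[combo][0] = n + 1
        per[combo][1] = v + int(is_polymorphic(m.values[:, j]))
    return PolymorphismSummary({c: (n, v) for c, (n, v) in per.items()})
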