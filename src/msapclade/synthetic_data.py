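"""Synthetic marker panels, character matrices and fluorescence histograms.

The analysis stages in this package were designed around a 14-cultivar,
two-clade ornamental panel (a 2-cultivar clade and a 12-cultivar clade plus
a distant outgroup) typed at ~549 AFLP and ~667 MSAP loci.  The raw gel
matrices behind such studies are rarely published, so this module generates
panels with the same statistical structure, together with a
:class:`PanelTruth` record of everything that was planted, making every
pipeline stage testable end to end:

* AFLP loci fall into three classes — shared-monomorphic, clade-diagnostic
  (fixed presence in one clade, absent in the other) and within-clade
  polymorphic (independent per-sample presence);
* MSAP loci are generated as methylation *types* per (sample, locus) and
  then split into the paired HpaII/MspI digest matrices through the inverse
  of the type-classification map, guaranteeing round-trip consistency;
* binary characters are planted on a given tree with known minimal step
  counts (synapomorphic = 1, autapomorphic = 1, homoplastic = 2);
* fluorescence histograms are two-Gaussian mixtures with Poisson-like
  counting noise around a known 2C value and internal standard.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .band_matrix import BandMatrix
from .character_mapping import CharacterMatrix
from .cytometry import FluorHistogram
from .msap_typing import TYPE_CODES, MsapType


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class PanelConfig:
    """Study-condition parameters for the two-clade marker panel.

    Defaults mirror the panel this package was designed around: clades of
    2 and 12 samples plus one outgroup; 549 AFLP loci of which 292 are
    polymorphic; 667 MSAP loci with per-sample type proportions inside the
    observed per-cultivar ranges; planted shared-type and clade-private
    fragment counts matching the published tallies (116/84/77 shared type
    I/II/III; 39 vs 51 type-I, 20 vs 22 type-II and 21 vs 25 type-III
    private fragments).
    """

    n_clade_a: int = 2
    n_clade_b: int = 12
    include_outgroup: bool = True
    outgroup_label: str = "Outgroup"

    # AFLP
    n_aflp_loci: int = 549
    aflp_fraction_polymorphic: float = 292 / 549
    aflp_diagnostic_a: int = 30  # fixed-present in clade A only
    aflp_diagnostic_b: int = 37  # fixed-present in clade B only
    aflp_within_presence_p: float = 0.5
    outgroup_presence_p: float = 0.35

    # MSAP: target per-sample type proportions (I, II, III, IV)
    n_msap_loci: int = 667
    msap_type_props: tuple[float, float, float, float] = (0.31, 0.31, 0.23, 0.15)
    msap_shared_counts: Mapping[MsapType, int] = field(
        default_factory=lambda: {MsapType.I: 116, MsapType.II: 84, MsapType.III: 77}
    )
    msap_private_a: Mapping[MsapType, int] = field(
        default_factory=lambda: {MsapType.I: 39, MsapType.II: 20, MsapType.III: 21}
    )
    msap_private_b: Mapping[MsapType, int] = field(
        default_factory=lambda: {MsapType.I: 51, MsapType.II: 22, MsapType.III: 25}
    )

    seed: int = 0

    # -- derived -----------------------------------------------------------

    @property
    def clade_a(self) -> list[str]:
        return [f"cladeA_{i + 1}" for i in range(self.n_clade_a)]

    @property
    def clade_b(self) -> list[str]:
        return [f"cladeB_{i + 1}" for i in range(self.n_clade_b)]

    @property
    def sample_ids(self) -> list[str]:
        out = self.clade_a + self.clade_b
        if self.include_outgroup:
            out.append(self.outgroup_label)
        return out

    @property
    def n_aflp_polymorphic(self) -> int:
        return int(round(self.n_aflp_loci * self.aflp_fraction_polymorphic))

    def validate(self) -> None:
        if self.n_clade_a < 1 or self.n_clade_b < 1:
            raise ConfigError("both clades need at least one sample")
        if not 0.0 <= self.aflp_fraction_polymorphic <= 1.0:
            raise ConfigError("polymorphic fraction must be in [0, 1]")
        if self.aflp_diagnostic_a + self.aflp_diagnostic_b > self.n_aflp_polymorphic:
            raise ConfigError("diagnostic loci exceed the polymorphic budget")
        props = np.asarray(self.msap_type_props, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("type proportions must be >=0 and sum to 1")
        planted = (
            sum(self.msap_shared_counts.values())
            + sum(self.msap_private_a.values())
            + sum(self.msap_private_b.values())
        )
        if planted > self.n_msap_loci:
            raise ConfigError("planted MSAP loci exceed the locus budget")


@dataclass
class PanelTruth:
    """Ground truth planted by a generator; every field is verifiable by
    brute force against the emitted data."""

    clade_a: tuple[str, ...] = ()
    clade_b: tuple[str, ...] = ()
    aflp_diagnostic_a: int = 0
    aflp_diagnostic_b: int = 0
    aflp_n_polymorphic: int = 0
    msap_shared_counts: dict[MsapType, int] = field(default_factory=dict)
    msap_private_a: dict[MsapType, int] = field(default_factory=dict)
    msap_private_b: dict[MsapType, int] = field(default_factory=dict)
    msap_type_props: tuple[float, ...] = ()
    n_msap_background: int = 0
    character_steps: dict[str, int] = field(default_factory=dict)
    true_2c: float | None = None


# -- marker panel ----------------------------------------------------------


_CODE_HPA = {1: 1, 2: 0, 3: 1, 4: 0}  # type code -> HpaII presence
_CODE_MSP = {1: 1, 2: 1, 3: 0, 4: 0}  # type code -> MspI presence


def _draw_nonconstant(
    rng: np.random.Generator, n: int, p: float, max_tries: int = 1000
) -> np.ndarray:
    """Bernoulli vector that is guaranteed polymorphic (not all equal)."""
    for _ in range(max_tries):
        v = (rng.random(n) < p).astype(np.int8)
        if 0 < v.sum() < n:
            return v
    # p extreme enough that rejection failed: force one flip
    v = np.full(n, int(p >= 0.5), dtype=np.int8)
    v[rng.integers(0, n)] = 1 - v[0]
    return v


def simulate_marker_panel(
    cfg: PanelConfig | None = None,
) -> tuple[BandMatrix, BandMatrix, BandMatrix, PanelTruth]:
    """Generate the AFLP matrix, the paired MSAP digest matrices and truth.

    AFLP columns are shuffled so locus class is not encoded in locus order;
    the truth record carries planted counts, not positions.  Deterministic
    for a given ``cfg.seed``.
    """
    cfg = cfg or PanelConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids
    a_idx = [samples.index(s) for s in cfg.clade_a]
    b_idx = [samples.index(s) for s in cfg.clade_b]
    ingroup = a_idx + b_idx
    n_samples = len(samples)

    # ---- AFLP ----
    n_poly = cfg.n_aflp_polymorphic
    n_mono = cfg.n_aflp_loci - n_poly
    n_within = n_poly - cfg.aflp_diagnostic_a - cfg.aflp_diagnostic_b
    cols: list[np.ndarray] = []
    for _ in range(n_mono):  # present in every sample, outgroup included
        cols.append(np.ones(n_samples, dtype=np.int8))
    for side_idx, n_diag in ((a_idx, cfg.aflp_diagnostic_a),
                             (b_idx, cfg.aflp_diagnostic_b)):
        for _ in range(n_diag):
            col = np.zeros(n_samples, dtype=np.int8)
            col[side_idx] = 1
            if cfg.include_outgroup:
                col[-1] = int(rng.random() < cfg.outgroup_presence_p)
            cols.append(col)
    for _ in range(n_within):
        col = np.zeros(n_samples, dtype=np.int8)
        col[ingroup] = _draw_nonconstant(
            rng, len(ingroup), cfg.aflp_within_presence_p
        )
        if cfg.include_outgroup:
            col[-1] = int(rng.random() < cfg.outgroup_presence_p)
        cols.append(col)
    order = rng.permutation(cfg.n_aflp_loci)
    aflp_values = np.column_stack(cols)[:, order]
    aflp = BandMatrix(
        sample_ids=list(samples),
        locus_ids=[f"AFLP_{j + 1:04d}" for j in range(cfg.n_aflp_loci)],
        values=aflp_values,
        marker_system="AFLP",
    )

    # ---- MSAP ----
    codes = list(TYPE_CODES.values())  # 1..4 for types I..IV
    props = np.asarray(cfg.msap_type_props, dtype=float)
    type_cols: list[np.ndarray] = []

    def draw_types(n: int) -> np.ndarray:
        return rng.choice(codes, size=n, p=props).astype(np.int8)

    def draw_types_excluding(n: int, excluded: int) -> np.ndarray:
        # The non-carrier side of a planted private locus must not itself be
        # uniform in some other type, or it would register as a spurious
        # private fragment of the opposite clade; redraw uniform vectors.
        keep = [c for c in codes if c != excluded]
        p = np.array([props[c - 1] for c in keep])
        p = p / p.sum()
        for _ in range(1000):
            v = rng.choice(keep, size=n, p=p).astype(np.int8)
            if n == 1 or np.unique(v).size > 1:
                return v
        v[0] = keep[0] if v[0] != keep[0] else keep[1]
        return v

    for t, k in cfg.msap_shared_counts.items():
        for _ in range(k):  # uniformly this type in every sample
            type_cols.append(np.full(n_samples, TYPE_CODES[t], dtype=np.int8))
    for own_idx, other_idx, planted in (
        (a_idx, b_idx, cfg.msap_private_a),
        (b_idx, a_idx, cfg.msap_private_b),
    ):
        for t, k in planted.items():
            code = TYPE_CODES[t]
            for _ in range(k):
                col = np.empty(n_samples, dtype=np.int8)
                col[own_idx] = code
                col[other_idx] = draw_types_excluding(len(other_idx), code)
                if cfg.include_outgroup:
                    col[-1] = draw_types(1)[0]
                type_cols.append(col)
    n_background = cfg.n_msap_loci - len(type_cols)
    for _ in range(n_background):
        type_cols.append(draw_types(n_samples))
    order = rng.permutation(cfg.n_msap_loci)
    type_values = np.column_stack(type_cols)[:, order]

    locus_ids = [f"MSAP_{j + 1:04d}" for j in range(cfg.n_msap_loci)]
    hpa = BandMatrix(
        sample_ids=list(samples),
        locus_ids=list(locus_ids),
        values=np.vectorize(_CODE_HPA.get)(type_values).astype(np.int8),
        marker_system="MSAP_HPAII",
    )
    msp = BandMatrix(
        sample_ids=list(samples),
        locus_ids=list(locus_ids),
        values=np.vectorize(_CODE_MSP.get)(type_values).astype(np.int8),
        marker_system="MSAP_MSPI",
    )

    truth = PanelTruth(
        clade_a=tuple(cfg.clade_a),
        clade_b=tuple(cfg.clade_b),
        aflp_diagnostic_a=cfg.aflp_diagnostic_a,
        aflp_diagnostic_b=cfg.aflp_diagnostic_b,
        aflp_n_polymorphic=n_poly,
        msap_shared_counts=dict(cfg.msap_shared_counts),
        msap_private_a=dict(cfg.msap_private_a),
        msap_private_b=dict(cfg.msap_private_b),
        msap_type_props=tuple(cfg.msap_type_props),
        n_msap_background=n_background,
    )
    return aflp, hpa, msp, truth


# -- characters ------------------------------------------------------------


def simulate_characters(
    t: TreeNode,
    n_synapomorphic: int,
    n_autapomorphic: int,
    n_homoplastic: int,
    seed: int = 0,
    outgroup: str | None = None,
) -> tuple[CharacterMatrix, PanelTruth]:
    """Plant binary characters with known minimal step counts on a tree.

    Synapomorphic characters place the derived state (1) on one internal
    clade (1 step); autapomorphic characters on one tip (1 step);
    homoplastic characters on two tips that do not form a cherry (2 steps).
    If ``outgroup`` is given it always keeps the ancestral state 0 and never
    belongs to a planted clade.
    """
    rng = np.random.default_rng(seed)
    tips = [tip.name for tip in t.tips()]
    if len(tips) < 4:
        raise ConfigError("tree must have at least 4 leaves")
    ingroup = [n for n in tips if n != outgroup]

    # candidate clades: internal-node tip sets excluding the outgroup and
    # not spanning the whole ingroup-or-more
    clades = []
    for node in t.non_tips(include_self=False):
        members = {tip.name for tip in node.tips()}
        if outgroup is not None and outgroup in members:
            continue
        if 2 <= len(members) < len(tips) - 1:
            clades.append(sorted(members))
    cherries = {frozenset(c) for c in clades if len(c) == 2}
    if n_synapomorphic > 0 and not clades:
        raise ConfigError("no internal clade available for synapomorphies")

    # homoplastic pairs: two ingroup tips not forming an exclusive cherry
    pairs = [
        (x, y)
        for i, x in enumerate(ingroup)
        for y in ingroup[i + 1 :]
        if frozenset((x, y)) not in cherries
    ]
    if n_homoplastic > 0 and not pairs:
        raise ConfigError("no non-sister tip pair available for homoplasy")

    labels: list[str] = []
    columns: list[np.ndarray] = []
    steps: dict[str, int] = {}
    tip_index = {n: i for i, n in enumerate(tips)}

    def add(label: str, derived: Sequence[str], true_steps: int) -> None:
        col = np.zeros(len(tips), dtype=np.int8)
        for n in derived:
            col[tip_index[n]] = 1
        labels.append(label)
        columns.append(col)
        steps[label] = true_steps

    for k in range(n_synapomorphic):
        members = clades[rng.integers(0, len(clades))]
        add(f"syn_{k + 1}", members, 1)
    for k in range(n_autapomorphic):
        add(f"aut_{k + 1}", [ingroup[rng.integers(0, len(ingroup))]], 1)
    for k in range(n_homoplastic):
        x, y = pairs[rng.integers(0, len(pairs))]
        add(f"hom_{k + 1}", [x, y], 2)

    cm = CharacterMatrix(
        taxa=list(tips),
        characters=labels,
        values=np.column_stack(columns) if columns else np.zeros((len(tips), 0)),
        outgroup=outgroup,
    )
    return cm, PanelTruth(character_steps=steps)


# -- histograms ------------------------------------------------------------


def simulate_histogram(
    true_2c: float,
    standard_2c: float,
    cv: float,
    n_events: int,
    seed: int = 0,
    standard_channel: float = 300.0,
    n_channels: int = 512,
) -> FluorHistogram:
    """Two-peak fluorescence histogram around a known 2C value.

    The standard peak is centered at ``standard_channel``; the sample peak
    at ``standard_channel * true_2c / standard_2c`` (fluorescence is
    proportional to DNA content).  Each peak is Gaussian with relative width
    ``cv``; events split evenly between the peaks and land in unit-width
    channels, giving Poisson-like count noise.  Peaks closer than 4 combined
    SDs set the ``"overlapping_peaks"`` metadata flag.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    if n_events < 100:
        raise ValueError("need at least 100 events")
    rng = np.random.default_rng(seed)
    sample_center = standard_channel * true_2c / standard_2c
    sd_sample = cv * sample_center
    sd_standard = cv * standard_channel
    overlap = abs(standard_channel - sample_center) < 4.0 * (sd_sample + sd_standard)
    n_sample = n_events // 2
    events = np.concatenate(
        [
            rng.normal(sample_center, sd_sample, size=n_sample),
            rng.normal(standard_channel, sd_standard, size=n_events - n_sample),
        ]
    )
    counts, edges = np.histogram(
        events, bins=n_channels, range=(0.5, n_channels + 0.5)
    )
    channels = 0.5 * (edges[:-1] + edges[1:])
    return FluorHistogram(
        channels=channels,
        counts=counts,
        metadata={
            "synthetic": True,
            "true_2c": true_2c,
            "standard_2c": standard_2c,
            "cv": cv,
            "n_events": n_events,
            "overlapping_peaks": bool(overlap),
        },
    )
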