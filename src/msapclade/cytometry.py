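"""Flow-cytometry genome-size and ploidy estimation with an internal standard.

Propidium-iodide flow cytometry measures relative nuclear DNA content: nuclei
of the sample and of an internal reference standard of known genome size
(here Pisum sativum 'Ctirad', 2C = 9.09 pg by default) are co-chopped,
co-stained and run together, producing a fluorescence histogram with one G1
peak per species.  The DNA index (sample peak mean / standard peak mean)
times the standard's 2C value gives the sample's 2C value in picograms;
1 pg = 978 Mbp converts to genome size, and the ratio to a known-diploid
reference 2C calls the ploidy.

Peaks are located non-parametrically: after light smoothing, the most
prominent local maxima are taken and each peak statistic is the
count-weighted mean/SD of channels within +-20% of the peak mode.
"""

from __future__ import annotations

import os
import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from ._utils import round_half_up

#: 2C DNA content of Pisum sativum 'Ctirad', the usual internal standard (pg)
PISUM_CTIRAD_2C_PG: float = 9.09

#: mean base-pair mass conversion: 1 pg of DNA ~ 978 Mbp
MBP_PER_PG: float = 978.0


class PeakDetectionError(RuntimeError):
    """Fewer detectable fluorescence peaks than expected."""


@dataclass
class FluorHistogram:
    """Fluorescence histogram: event counts per channel.

    ``channels`` must be strictly increasing; ``counts`` are non-negative
    with a positive total.  ``metadata`` carries free-form labels (sample,
    standard, simulation flags).
    """

    channels: np.ndarray
    counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.channels.ndim != 1 or self.channels.shape != self.counts.shape:
            raise ValueError("channels and counts must be matching 1-D arrays")
        if not (np.diff(self.channels) > 0).all():
            raise ValueError("channels must be strictly increasing")
        if (self.counts < 0).any() or self.counts.sum() <= 0:
            raise ValueError("counts must be non-negative with >0 total events")


def read_histogram(path: str | os.PathLike, **metadata) -> FluorHistogram:
    """Read a two-column (channel, count) delimited text file."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=0)
    return FluorHistogram(
        channels=df.iloc[:, 0].to_numpy(float),
        counts=df.iloc[:, 1].to_numpy(float),
        metadata=dict(metadata),
    )


def find_peaks(
    h: FluorHistogram, n_expected: int, smooth_window: int = 5
) -> list[tuple[float, float]]:
    """Locate the ``n_expected`` most prominent peaks of a histogram.

    Counts are smoothed with a centered moving average of ``smooth_window``
    channels before local-maximum detection; each reported peak mean is the
    count-weighted average of raw counts over channels within +-20% of the
    peak mode, and CV is the weighted SD over that window divided by the
    mean.  Peaks are returned in ascending order of mean.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    counts = h.counts.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts
    idx, props = _scipy_find_peaks(smoothed, prominence=1e-12)
    if len(idx) < n_expected:
        raise PeakDetectionError(
            f"expected {n_expected} peaks, found {len(idx)}"
        )
    top = idx[np.argsort(props["prominences"])[::-1][:n_expected]]
    peaks = []
    for i in top:
        mode = h.channels[i]
        window = (h.channels >= 0.8 * mode) & (h.channels <= 1.2 * mode)
        w = counts[window]
        x = h.channels[window]
        if w.sum() <= 0:
            raise PeakDetectionError("empty peak window")
        mean = float(np.average(x, weights=w))
        var = float(np.average((x - mean) ** 2, weights=w))
        peaks.append((mean, float(np.sqrt(var) / mean) if mean > 0 else 0.0))
    return sorted(peaks, key=lambda p: p[0])


def dna_index(sample_peak: float, standard_peak: float) -> float:
    """Ratio of sample to internal-standard peak fluorescence."""
    if sample_peak <= 0 or standard_peak <= 0:
        raise ValueError("peak means must be positive")
    return sample_peak / standard_peak


def estimate_2c(index: float, standard_2c: float = PISUM_CTIRAD_2C_PG) -> float:
    """2C DNA content (pg) from a DNA index and the standard's 2C value."""
    if standard_2c <= 0:
        raise ValueError("standard 2C value must be positive")
    return index * standard_2c


def genome_size_mbp(two_c: float) -> int:
    """1C genome size in Mbp from a 2C value in pg (half-up to integer)."""
    if two_c <= 0:
        raise ValueError("2C value must be positive")
    return int(round_half_up(two_c / 2.0 * MBP_PER_PG, 0))


def ploidy_call(
    two_c: float, diploid_reference_2c: float, rel_tol: float = 0.15
) -> tuple[int, bool]:
    """Ploidy as the nearest integer multiple of the haploid reference.

    ``diploid_reference_2c`` is the 2C value of a known diploid (in practice
    the panel median).  Returns ``(ploidy, inconclusive)`` where the call is
    flagged inconclusive when ``2 * two_c / reference`` is farther than
    ``rel_tol`` from the nearest integer; the call itself is still returned
    rather than raised.
    """
    if diploid_reference_2c <= 0:
        raise ValueError("diploid reference 2C must be positive")
    ratio = 2.0 * two_c / diploid_reference_2c
    p = max(int(round_half_up(ratio, 0)), 1)
    return p, abs(ratio - p) > rel_tol


def replicate_summary(values: list[float]) -> tuple[float, float]:
    """Mean +- sample SD over replicate 2C measurements (2 decimals)."""
    if len(values) < 2:
        raise ValueError("need at least 2 replicates")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values)
    return round_half_up(mean, 2), round_half_up(sd, 2)


@dataclass
class PloidyEstimate:
    """Aggregated flow-cytometry result for one sample."""

    sample_id: str
    dna_index: float
    two_c_pg: float
    two_c_sd: float
    one_c_mbp: int
    ploidy: int
    inconclusive: bool
    n_replicates: int


def estimate_from_histograms(
    sample_id: str,
    histograms: list[FluorHistogram],
    standard_2c: float = PISUM_CTIRAD_2C_PG,
    diploid_reference_2c: float | None = None,
) -> PloidyEstimate:
    """Full pipeline over replicate histograms for one sample.

    Each histogram must contain the sample G1 peak and the (higher) standard
    peak; the sample is assumed to fluoresce below the standard, as holds
    for species with genomes smaller than the Pisum standard.  The ploidy is
    referenced to ``diploid_reference_2c`` (defaults to the estimated mean
    itself, i.e. "assume diploid").
    """
    indices, two_cs = [], []
    for h in histograms:
        (sample_mean, _), (standard_mean, _) = find_peaks(h, 2)
        di = dna_index(sample_mean, standard_mean)
        indices.append(di)
        two_cs.append(estimate_2c(di, standard_2c))
    if len(two_cs) >= 2:
        mean_2c, sd_2c = replicate_summary(two_cs)
    else:
        mean_2c, sd_2c = round_half_up(two_cs[0], 2), 0.0
    ref = diploid_reference_2c if diploid_reference_2c is not None else mean_2c
    ploidy, inconclusive = ploidy_call(mean_2c, ref)
    return PloidyEstimate(
        sample_id=sample_id,
        dna_index=round_half_up(statistics.fmean(indices), 2),
        two_c_pg=mean_2c,
        two_c_sd=sd_2c,
        one_c_mbp=genome_size_mbp(mean_2c),
        ploidy=ploidy,
        inconclusive=inconclusive,
        n_replicates=len(histograms),
    )
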