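"""Frequency-domain periodicity analysis of expression time series.

Transcript trajectories sampled over several phenotypic cycles (e.g. the
dissolved-O2 cycles of a respiratory oscillation) are decomposed with the
discrete Fourier transform.  The component index ``k_osc`` equal to the
number of phenotypic cycles spanned by the series carries the oscillatory
signal; its amplitude, phase angle and a normalization-free *scaled
amplitude* statistic are the per-gene features used downstream.

DFT convention
--------------
The unnormalized, negative-exponent forward transform::

    X_k = sum_{n=0}^{N-1} x_n * exp(-2*pi*i*k*n/N)

so for ``x_n = A*cos(2*pi*k0*n/N + phi0)`` the coefficient at ``k0`` has
amplitude ``N*A/2`` and phase ``phi0`` (atan2 convention).  Phase angles
therefore proxy peak time: ``t_peak = (-phi_k mod 2*pi) * P / (2*pi)``
from cycle start.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cap substituted for an infinite scaled amplitude before clustering.
#: Keeps EM numerically safe while preserving the ordering of finite values.
INF_CAP = 100.0


@dataclass
class ExpressionTimeSeries:
    """One gene's raw intensity trajectory.

    Parameters
    ----------
    gene_id : str
    values : array of raw (unnormalized) intensities, one per timepoint.
    sample_times : equally spaced sampling times; spacing checked to 1%.
    k_osc : number of full phenotypic cycles spanned by the series.
    """

    gene_id: str
    values: np.ndarray
    sample_times: np.ndarray
    k_osc: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite intensities for {self.gene_id}")
        n = self.values.size
        if n < 2 * self.k_osc + 2:
            raise ValueError(
                f"{self.gene_id}: need N >= 2*k_osc+2 points, got {n} for k_osc={self.k_osc}"
            )
        dt = np.diff(self.sample_times)
        if dt.size and (dt.max() - dt.min()) > 0.01 * abs(dt.mean()):
            raise ValueError(f"{self.gene_id}: sampling not equally spaced within 1%")


@dataclass
class FourierFeatures:
    """DFT coefficients and derived periodicity statistics for one series."""

    gene_id: str
    coefficients: np.ndarray          # complex X_k, k = 0..N-1
    k_osc: int
    p_perm: float | None = None
    _scaled: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.coefficients.size

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phases(self) -> np.ndarray:
        x = self.coefficients
        return np.arctan2(x.imag, x.real)


def dft(series: ExpressionTimeSeries) -> FourierFeatures:
    """Forward DFT of one expression series (coefficients only)."""
    return FourierFeatures(
        gene_id=series.gene_id,
        coefficients=np.fft.fft(series.values),
        k_osc=series.k_osc,
    )


def _admissible_range(n: int) -> np.ndarray:
    """Component indices entering the scaled-amplitude denominator pool.

    Non-DC components up to (but excluding) the Nyquist/"half-sampling"
    index: 1 .. ceil(N/2)-1.
    """
    return np.arange(1, int(np.ceil(n / 2)))


def scaled_amplitude_spectrum(amplitudes: np.ndarray) -> np.ndarray:
    """Scaled amplitude S_k for every admissible k (vector form).

    S_k is the amplitude at cycle number k divided by the mean of the
    amplitudes at all other non-zero cycle numbers, the Nyquist component
    excluded.  A zero denominator with a positive numerator yields ``inf``;
    0/0 yields 0.  S_k is invariant under x -> a*x, a > 0.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    ks = _admissible_range(amplitudes.size)
    if ks.size < 2:
        raise ValueError("series too short for a scaled amplitude")
    pool = amplitudes[ks]
    total = pool.sum()
    out = np.empty(ks.size)
    for i, a in enumerate(pool):
        denom = (total - a) / (ks.size - 1)
        if denom > 0:
            out[i] = a / denom
        else:
            out[i] = np.inf if a > 0 else 0.0
    return out


def scaled_amplitude(features: FourierFeatures, k: int) -> float:
    """Scaled amplitude S_k = A_k / mean{A_j : j admissible, j != k}."""
    ks = _admissible_range(features.n)
    if k not in ks:
        raise ValueError(f"component k={k} out of admissible range {ks.min()}..{ks.max()}")
    if k not in features._scaled:
        spectrum = scaled_amplitude_spectrum(features.amplitudes)
        features._scaled.update(dict(zip(ks.tolist(), spectrum.tolist())))
    return features._scaled[k]


def periodicity_pvalue(
    series: ExpressionTimeSeries,
    k_osc: int | None = None,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the scaled amplitude at ``k_osc``.

    The time order of the measurements is permuted uniformly at random
    ``n_permutations`` times; the add-one estimate
    ``p = (1 + #{S_perm >= S_obs}) / (B + 1)`` keeps p in (0, 1].
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    k = series.k_osc if k_osc is None else k_osc
    rng = np.random.default_rng(seed)
    x = series.values
    ks = _admissible_range(x.size)
    kpos = int(np.flatnonzero(ks == k)[0])
    obs = scaled_amplitude_spectrum(np.abs(np.fft.fft(x)))[kpos]
    idx = np.argsort(rng.random((n_permutations, x.size)), axis=1)
    pool = np.abs(np.fft.fft(x[idx], axis=1))[:, ks]
    denom = (pool.sum(axis=1, keepdims=True) - pool) / (ks.size - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, pool / denom, np.where(pool > 0, np.inf, 0.0))
    count = int(np.sum(s[:, kpos] >= obs - 1e-12))
    return (1 + count) / (n_permutations + 1)


def feature_vector(
    scaled: np.ndarray | list[float],
    phases: np.ndarray | list[float],
    inf_cap: float = INF_CAP,
) -> np.ndarray:
    """Scaled real/imaginary clustering features.

    Per selected component: ``(S_k*cos(phi_k), S_k*sin(phi_k))``, i.e. the
    real and imaginary parts of ``S_k*exp(i*phi_k)``.  Infinite scaled
    amplitudes are capped at ``inf_cap`` first.
    """
    s = np.minimum(np.asarray(scaled, dtype=float), inf_cap)
    phi = np.asarray(phases, dtype=float)
    out = np.empty(2 * s.size)
    out[0::2] = s * np.cos(phi)
    out[1::2] = s * np.sin(phi)
    return out


def peak_time(phi: float, period: float) -> float:
    """Peak time within the cycle implied by a phase angle (cosine convention)."""
    return (-phi % (2 * np.pi)) * period / (2 * np.pi)


def fourier_features(
    matrix: pd.DataFrame,
    k_osc: int,
    components: list[int] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene DFT feature table for a genes x timepoints matrix.

    Returns a DataFrame indexed by gene with, for each selected component k
    (default ``{k_osc, 2*k_osc}``), columns ``A_k``, ``phi_k`` (radians),
    ``S_k``, plus ``p_perm`` at ``k_osc``.
    """
    if components is None:
        components = [k_osc, 2 * k_osc]
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    n = values.shape[1]
    coefs = np.fft.fft(values, axis=1)
    amps = np.abs(coefs)
    ks = _admissible_range(n)
    for k in components:
        if k not in ks:
            raise ValueError(f"component {k} outside admissible range for N={n}")

    # scaled amplitudes for all admissible components at once
    pool = amps[:, ks]
    denom = (pool.sum(axis=1, keepdims=True) - pool) / (ks.size - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        spectrum = np.where(denom > 0, pool / denom,
                            np.where(pool > 0, np.inf, 0.0))

    out = pd.DataFrame(index=matrix.index)
    for k in components:
        kpos = int(np.flatnonzero(ks == k)[0])
        out[f"A_{k}"] = amps[:, k]
        out[f"phi_{k}"] = np.arctan2(coefs[:, k].imag, coefs[:, k].real)
        out[f"S_{k}"] = spectrum[:, kpos]

    rng = np.random.default_rng(seed)
    kpos = int(np.flatnonzero(ks == k_osc)[0])
    # one shared permutation set across genes: valid under the null and
    # O(B) full-matrix FFTs instead of O(genes*B)
    pvals = np.ones(values.shape[0])
    obs = spectrum[:, kpos]
    counts = np.zeros(values.shape[0])
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pa = np.abs(np.fft.fft(values[:, perm], axis=1))[:, ks]
        pdenom = (pa.sum(axis=1, keepdims=True) - pa) / (ks.size - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ps = np.where(pdenom > 0, pa / pdenom, np.where(pa > 0, np.inf, 0.0))
        counts += ps[:, kpos] >= obs - 1e-12
    pvals = (1 + counts) / (n_permutations + 1)
    out["p_perm"] = pvals
    out.attrs["k_osc"] = k_osc
    out.attrs["components"] = list(components)
    return out


def clustering_features(features: pd.DataFrame, components: list[int] | None = None,
                        inf_cap: float = INF_CAP) -> pd.DataFrame:
    """Genes x (2 per component) matrix of scaled real/imaginary parts."""
    if components is None:
        components = features.attrs.get("components")
    cols = {}
    for k in components:
        s = np.minimum(features[f"S_{k}"].to_numpy(dtype=float), inf_cap)
        phi = features[f"phi_{k}"].to_numpy(dtype=float)
        cols[f"re_{k}"] = s * np.cos(phi)
        cols[f"im_{k}"] = s * np.sin(phi)
    return pd.DataFrame(cols, index=features.index)


def select_reference_set(
    features: pd.DataFrame,
    k_osc: int | None = None,
    quantile: float = 0.1,
    p_min: float = 0.5,
) -> pd.Index:
    """"Least-oscillating" gene set used as a display-normalization reference.

    Genes in the bottom ``quantile`` of the scaled amplitude at ``k_osc``
    AND with permutation p-value >= ``p_min``.  If the intersection is
    empty, falls back (with a warning) to the bottom quantile alone.
    """
    if len(features) < 100:
        raise ValueError("reference selection needs features for >= 100 genes")
    if k_osc is None:
        k_osc = features.attrs.get("k_osc")
    s = features[f"S_{k_osc}"]
    cutoff = s.quantile(quantile)
    low = features.index[s <= cutoff]
    sel = features.index[(s <= cutoff) & (features["p_perm"] >= p_min)]
    if len(sel) == 0:
        warnings.warn("no gene satisfies both reference criteria; "
                      "falling back to the bottom scaled-amplitude quantile")
        sel = low
    logger.info("reference set: %d of %d genes", len(sel), len(features))
    return sel


def normalize_display(matrix: pd.DataFrame, reference: pd.Index) -> pd.DataFrame:
    """Display-only normalization against a least-oscillating reference set.

    Each sample (column) is divided by the median over reference genes of
    the gene-mean ratio x_gn / mean_n(x_g); the normalized matrix is then
    returned per gene as log2 of the mean-ratio.  Intended purely for
    plotting average cluster time courses; all statistics upstream operate
    on raw intensities.
    """
    if len(reference) == 0:
        raise ValueError("empty reference set")
    gene_means = matrix.mean(axis=1)
    keep = gene_means > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} genes with zero mean intensity")
    m = matrix.loc[keep]
    ratios = m.div(m.mean(axis=1), axis=0)
    scale = ratios.loc[ratios.index.intersection(reference)].median(axis=0)
    corrected = m.div(scale, axis=1)
    return np.log2(corrected.div(corrected.mean(axis=1), axis=0))
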