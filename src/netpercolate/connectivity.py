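"""Narrowband functional connectivity via the weighted phase lag index.

Trial-wise Fourier coefficients are computed with Slepian (discrete
prolate spheroidal) multitapers, giving spectral smoothing of
+/- ``half_bandwidth`` Hz around each bin centre.  The weighted phase lag
index (wPLI) for a node pair at one bin is

    wPLI_ij(f) = | E[ Im S_ij(f) ] | / E[ | Im S_ij(f) | ],

with the expectation taken over trial x taper observations and the 0/0
case mapped to 0 (zero-lag coupling is exactly what wPLI is built to
discount).  Per-bin values are aggregated across the spectrum in the L2
norm to yield a single weighted connectome per subject.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import windows
from scipy.spatial.distance import pdist

from .types import (
    ConfigurationError,
    Connectome,
    CrossSpectra,
    NodeTimeseries,
    SpectralConnectivity,
)

__all__ = [
    "multitaper_cross_spectra",
    "wpli",
    "aggregate_l2",
    "mean_node_distance",
    "MultitaperWPLI",
]


def multitaper_cross_spectra(
    ts: NodeTimeseries,
    fmin: float = 0.5,
    fmax: float = 100.0,
    fstep: float = 0.5,
    half_bandwidth: float = 2.0,
) -> CrossSpectra:
    """Slepian-multitaper Fourier coefficients on a fixed frequency grid.

    The time-half-bandwidth product is ``NW = duration_s * half_bandwidth``
    and ``2 NW - 1`` tapers are kept (the standard concentration rule; the
    defaults, 2 s trials with +/-2 Hz smoothing, give NW = 4 and 7 tapers).
    Each trial is demeaned before tapering.  Bin centres are aligned to the
    requested grid by zero-padding the FFT when ``duration * fstep`` is not
    an integer.
    """
    trials, n_nodes, n_samples = ts.data.shape
    if trials < 2:
        raise ConfigurationError("need at least 2 trials (expectation undefined)")
    nyquist = ts.fs / 2.0
    if fmax >= nyquist:
        raise ConfigurationError(f"fmax={fmax} Hz is at or above Nyquist ({nyquist} Hz)")
    if fstep <= 0:
        raise ConfigurationError("fstep must be > 0")
    duration = n_samples / ts.fs
    nw = duration * half_bandwidth
    if nw < 1:
        raise ConfigurationError("half_bandwidth * duration must be >= 1")
    n_tapers = max(1, int(round(2 * nw - 1)))
    tapers = windows.dpss(n_samples, nw, Kmax=n_tapers)  # (K, samples)

    # FFT length that puts the requested bin centres on exact DFT bins
    base = ts.fs / fstep
    nfft = int(round(base))
    if abs(base - nfft) > 1e-9:
        raise ConfigurationError("fs must be an integer multiple of fstep")
    if nfft < n_samples:
        nfft *= int(np.ceil(n_samples / nfft))

    freqs = np.arange(fmin, fmax + fstep / 2, fstep)
    bin_idx = np.round(freqs * nfft / ts.fs).astype(int)

    coeffs = np.empty((trials * n_tapers, n_nodes, len(freqs)), dtype=complex)
    for tr in range(trials):  # trial loop keeps the tapered FFT memory bounded
        x = ts.data[tr] - ts.data[tr].mean(axis=1, keepdims=True)
        tapered = x[None, :, :] * tapers[:, None, :]  # (K, nodes, samples)
        spec = np.fft.rfft(tapered, n=nfft, axis=-1)[..., bin_idx]
        coeffs[tr * n_tapers : (tr + 1) * n_tapers] = spec
    return CrossSpectra(coeffs=coeffs, freqs=freqs, half_bandwidth=half_bandwidth, fs=ts.fs)


def wpli(cs: CrossSpectra) -> SpectralConnectivity:
    """Weighted phase lag index per frequency bin, pooling trials and tapers."""
    if cs.n_observations < 2:
        raise ConfigurationError("need at least 2 observations per bin")
    n = cs.n_nodes
    out = np.zeros((cs.n_bins, n, n))
    for b in range(cs.n_bins):
        im = np.imag(cs.cross_spectrum(b))  # (obs, nodes, nodes)
        num = np.abs(im.mean(axis=0))
        den = np.abs(im).mean(axis=0)
        # 0/0 convention: a denominator at rounding-noise level relative to
        # the cross-spectral amplitude is an exactly-zero-lag pair
        amp = np.abs(cs.coeffs[:, :, b])
        floor = 1e-10 * (amp[:, :, None] * amp[:, None, :]).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > floor, num / den, 0.0)
        np.fill_diagonal(w, 0.0)
        out[b] = np.clip(0.5 * (w + w.T), 0.0, 1.0)
    return SpectralConnectivity(freqs=cs.freqs.copy(), wpli=out)


def aggregate_l2(
    sc: SpectralConnectivity,
    node_coords: np.ndarray | None = None,
    subject_id: str = "",
) -> Connectome:
    """Collapse per-bin wPLI into one adjacency: ``W_ij = sqrt(sum_f wPLI_ij^2)``."""
    if sc.n_bins < 1:
        raise ConfigurationError("need at least one frequency bin")
    w = np.sqrt((sc.wpli**2).sum(axis=0))
    np.fill_diagonal(w, 0.0)
    dist = mean_node_distance(node_coords) if node_coords is not None else float("nan")
    return Connectome(
        W=w,
        node_coords=node_coords,
        mean_distance=dist,
        n_bins_aggregated=sc.n_bins,
        subject_id=subject_id,
    )


def mean_node_distance(coords: np.ndarray) -> float:
    """Mean Euclidean distance (mm) over all unordered node pairs."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ConfigurationError("need at least 2 nodes with coordinates")
    if not np.all(np.isfinite(coords)):
        raise ConfigurationError("coordinates must be finite")
    return float(pdist(coords).mean())


class MultitaperWPLI:
    """Transformer from node time series to a weighted wPLI connectome.

    Thin scikit-learn-style composition of :func:`multitaper_cross_spectra`,
    :func:`wpli` and :func:`aggregate_l2`; stateless, so ``fit`` is a no-op.
    """

    def __init__(
        self,
        fmin: float = 0.5,
        fmax: float = 100.0,
        fstep: float = 0.5,
        half_bandwidth: float = 2.0,
    ):
        self.fmin = fmin
        self.fmax = fmax
        self.fstep = fstep
        self.half_bandwidth = half_bandwidth

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fmin": self.fmin,
            "fmax": self.fmax,
            "fstep": self.fstep,
            "half_bandwidth": self.half_bandwidth,
        }

    def set_params(self, **params) -> "MultitaperWPLI":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "MultitaperWPLI":
        return self

    def transform(self, ts: NodeTimeseries) -> Connectome:
        cs = multitaper_cross_spectra(
            ts, fmin=self.fmin, fmax=self.fmax, fstep=self.fstep,
            half_bandwidth=self.half_bandwidth,
        )
        return aggregate_l2(wpli(cs), node_coords=ts.node_coords, subject_id=ts.subject_id)

    def fit_transform(self, ts: NodeTimeseries, y=None) -> Connectome:
        return self.transform(ts)
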