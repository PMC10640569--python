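"""Core containers shared across the pipeline.

The analysis passes through a fixed chain of representations:
multichannel oscillatory recordings (:class:`NodeTimeseries`) are reduced
to trial/taper Fourier coefficients (:class:`CrossSpectra`), to per-bin
phase-coupling matrices (:class:`SpectralConnectivity`), and finally to a
single weighted adjacency per subject (:class:`Connectome`).  Attack
simulations convert connectomes into per-density percolation points
(:class:`PercolationFunction`), which are assembled across subjects into a
:class:`FunctionalSample` for the functional-regression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """A configuration or specification object violates one of its invariants."""


class DensityTooLowError(ValueError):
    """Proportional threshold would retain zero edges at this density."""


@dataclass
class SubjectRecord:
    """Covariates for one subject entering the design matrix."""

    id: str
    age_years: float
    sex: str  # "male" | "female"
    handedness: str  # "left" | "right" | "no_preference"
    mean_node_distance: float  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.handedness not in ("left", "right", "no_preference"):
            raise ConfigurationError(f"invalid handedness {self.handedness!r}")
        if not self.mean_node_distance > 0:
            raise ConfigurationError("mean_node_distance must be > 0")


@dataclass
class NodeTimeseries:
    """Node-level recordings: ``data`` has shape (trials, nodes, samples)."""

    subject_id: str
    data: np.ndarray
    fs: float  # Hz
    node_coords: np.ndarray  # (nodes, 3), mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be (trials, nodes, samples)")
        if not self.fs > 0:
            raise ConfigurationError("fs must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("all samples must be finite")
        if self.node_coords.shape != (self.data.shape[1], 3):
            raise ConfigurationError("node_coords must be (nodes, 3)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[2] / self.fs


@dataclass
class CrossSpectra:
    """Multitaper Fourier coefficients, one per trial x taper observation.

    ``coeffs`` has shape (observations, nodes, bins); the cross-spectrum for
    bin ``b`` is ``S[o, i, j] = coeffs[o, i, b] * conj(coeffs[o, j, b])``,
    materialised on demand by :meth:`cross_spectrum` so that the full
    nodes x nodes x bins array never needs to be held at once.
    """

    coeffs: np.ndarray
    freqs: np.ndarray  # bin centres, Hz
    half_bandwidth: float  # Hz
    fs: float

    @property
    def n_observations(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[2]

    def cross_spectrum(self, bin_index: int) -> np.ndarray:
        """Per-observation cross-spectral matrix for one frequency bin."""
        x = self.coeffs[:, :, bin_index]
        return x[:, :, None] * np.conj(x[:, None, :])


@dataclass
class SpectralConnectivity:
    """Per-bin wPLI matrices, shape (bins, nodes, nodes)."""

    freqs: np.ndarray
    wpli: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.wpli.shape[0]


@dataclass
class Connectome:
    """Symmetric weighted adjacency with node coordinates; the object attacked."""

    W: np.ndarray
    node_coords: np.ndarray | None = None
    mean_distance: float = float("nan")
    n_bins_aggregated: int = 1
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ConfigurationError("W must be square")
        if not np.allclose(self.W, self.W.T):
            raise ConfigurationError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ConfigurationError("W must have a zero diagonal")
        if np.any(self.W < 0):
            raise ConfigurationError("W must be nonnegative")
        if self.node_coords is not None:
            self.node_coords = np.asarray(self.node_coords, dtype=float)
            if self.node_coords.shape != (self.W.shape[0], 3):
                raise ConfigurationError("node_coords must be (nodes, 3)")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class ComponentTrace:
    """Largest and second-largest component sizes after each removal step."""

    s1: np.ndarray  # size of largest component after removing k nodes, k=1..N
    s2: np.ndarray  # second largest; 0 when fewer than two components

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=int)
        self.s2 = np.asarray(self.s2, dtype=int)

    @property
    def n_steps(self) -> int:
        return len(self.s1)


@dataclass
class PercolationFunction:
    """Mean percolation point (fraction of nodes removed) per initial density."""

    subject_id: str
    densities: np.ndarray
    p: np.ndarray  # NaN where the density retained no edges


@dataclass
class RemovalFrequencyMap:
    """Per-node fraction of subjects for which the node fell before failure."""

    density: float
    strategy: str
    frequencies: np.ndarray  # (nodes,), values in [0, 1]


@dataclass
class FunctionalSample:
    """Per-subject functions on a common ascending density grid.

    ``values`` is (subjects, densities).  The grid ascends in density; the
    attack sweep's terminal (lowest-density) value is therefore column 0.
    """

    densities: np.ndarray
    values: np.ndarray
    subject_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.densities):
            raise ConfigurationError("values must be (subjects, len(densities))")
        if np.any(np.diff(self.densities) <= 0):
            raise ConfigurationError("densities must be strictly increasing")
        if not list(self.subject_ids):
            self.subject_ids = [f"s{i:03d}" for i in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise ConfigurationError("subject_ids length must match values rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_densities(self) -> int:
        return len(self.densities)

    def select(self, mask: np.ndarray) -> "FunctionalSample":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.subject_ids, mask) if m]
        return FunctionalSample(self.densities.copy(), self.values[mask], ids)


@dataclass
class SmoothedFunction:
    """Penalized B-spline representation of one subject's function."""

    knots: np.ndarray
    coefficients: np.ndarray
    order: int  # spline order (4 = cubic)
    lam: float  # roughness penalty weight on the second derivative
    gcv: float
    ssr: float

    @property
    def n_basis(self) -> int:
        return len(self.coefficients)
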