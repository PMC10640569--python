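"""Synthetic cohorts with a known age-by-topology gradient.

The graph generator emulates the developmental contrast the pipeline is
built to detect: young subjects carry many redundant inter-module bridges
(a distributed, robust topology), while older subjects concentrate
inter-module traffic on a single high-betweenness bridge node per module
(a hub-concentrated, vulnerable topology).  The shift is continuous in an
``age`` covariate, controlled by ``hub_concentration_slope``.

Two auxiliary generators support validation of the other stages: a
phase-coupled oscillator simulator with known wPLI structure, and a
function-level cohort simulator that draws percolation-point-like
functions with known covariate effects (used for calibrating the
function-on-scalar regression without re-running graph attacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    Connectome,
    FunctionalSample,
    NodeTimeseries,
    SubjectRecord,
)

__all__ = [
    "SyntheticCohortSpec",
    "generate_cohort",
    "simulate_coupled_oscillators",
    "simulate_functional_cohort",
]

# Demographic frequencies of the reference developmental cohort (see
# datasets.reference_cohort_demographics): 54.9% female, 87.8% right-handed.
_P_FEMALE = 0.549
_P_HAND = {"right": 0.878, "no_preference": 0.085, "left": 0.037}


def _ensure_factor_levels(sex: np.ndarray, hand: np.ndarray, rng) -> None:
    """Force every sex/handedness level to appear at least once (in place).

    Rare levels (left-handed: 3.7%) are otherwise frequently absent from
    small cohorts, which would make the downstream design matrix rank
    deficient by sampling accident rather than by design.
    """
    if len(sex) < 6:
        return
    for level in ("male", "female"):
        if level not in sex:
            sex[rng.integers(len(sex))] = level
    missing = [lv for lv in _P_HAND if lv not in hand]
    if missing:
        slots = rng.choice(len(hand), size=len(missing), replace=False)
        for lv, i in zip(missing, slots):
            hand[i] = lv


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic developmental cohort.

    ``hub_concentration_slope`` (per year) sets how fast inter-module
    connectivity collapses onto a single bridge node per module as age
    increases; the default reaches full concentration at the top of the
    default 4-19 y age range.  ``edge_noise_sd`` perturbs every edge weight.
    """

    n_subjects: int = 60
    n_nodes: int = 64
    n_modules: int = 4
    age_range: tuple[float, float] = (4.0, 19.0)
    hub_concentration_slope: float = 1.0 / 15.0
    edge_noise_sd: float = 0.02
    master_seed: int = 0
    sphere_radius_mm: float = 70.0
    n_bridges_max: int = 3  # redundant inter-module channels at the youngest age

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_nodes < 8:
            raise ConfigurationError("n_nodes must be >= 8")
        if self.n_modules < 2:
            raise ConfigurationError("n_modules must be >= 2")
        if self.edge_noise_sd < 0:
            raise ConfigurationError("edge_noise_sd must be >= 0")
        if not self.age_range[1] > self.age_range[0]:
            raise ConfigurationError("age_range must be a nonempty interval")
        if self.n_nodes // self.n_modules < 2:
            raise ConfigurationError("each module needs at least 2 nodes")
        if self.n_bridges_max < 1:
            raise ConfigurationError("n_bridges_max must be >= 1")


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    return np.arange(n_nodes) % n_modules


def _subject_adjacency(
    spec: SyntheticCohortSpec,
    modules: np.ndarray,
    bridge_nodes: np.ndarray,  # (n_modules, n_bridges_max), cohort-fixed
    age: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = spec.n_nodes
    amin = spec.age_range[0]
    # concentration in [0, 1]: 0 = fully redundant bridges, 1 = single hub
    c = float(np.clip(spec.hub_concentration_slope * (age - amin), 0.0, 1.0))

    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    same = modules[iu] == modules[ju]

    # weak background coupling everywhere (a wPLI connectome has no true
    # zeros) and a mid-tier of intra-module chords
    vals = rng.uniform(0.0, 0.3, size=iu.size)
    vals[same] = rng.uniform(0.3, 0.6, size=int(same.sum()))
    w[iu, ju] = vals

    # strong intra-module backbone: a ring over the module's members keeps
    # each module internally connected at sparse thresholds
    for m in range(spec.n_modules):
        members = np.flatnonzero(modules == m)
        for a, b in zip(members, np.roll(members, -1)):
            w[min(a, b), max(a, b)] = rng.uniform(0.92, 1.0)

    # inter-module channels: each active channel `ch` fully connects the
    # ch-th bridge node of every module.  The number of redundant channels
    # decreases with concentration: young networks keep several parallel
    # channels (losing the top hubs is tolerated), old networks route all
    # inter-module traffic through the single channel-0 hub per module.
    n_channels = max(1, int(round(spec.n_bridges_max - c * (spec.n_bridges_max - 1))))
    for a in range(spec.n_modules):
        for b in range(a + 1, spec.n_modules):
            for ch in range(n_channels):
                u, v = bridge_nodes[a, ch], bridge_nodes[b, ch]
                boost = 0.3 * c if ch == 0 else 0.0
                w[min(u, v), max(u, v)] = rng.uniform(0.8, 0.9) + boost

    # channel-0 hubs are also their module's internal centre: strong spokes
    # to members spread around the ring give them clearly-top betweenness
    # at every age
    for m in range(spec.n_modules):
        members = np.flatnonzero(modules == m)
        size = len(members)
        hub = bridge_nodes[m, 0]
        pos = int(np.flatnonzero(members == hub)[0])
        n_spokes = max(2, size // 4)
        for s in range(1, n_spokes + 1):
            target = members[(pos + s * size // (n_spokes + 1)) % size]
            if target != hub:
                w[min(hub, target), max(hub, target)] = rng.uniform(0.92, 1.0)

    if spec.edge_noise_sd > 0:
        noise = rng.normal(0.0, spec.edge_noise_sd, size=iu.size)
        w[iu, ju] = np.clip(w[iu, ju] + noise, 0.0, None)
    w = w + w.T
    return w


def generate_cohort(spec: SyntheticCohortSpec) -> list[tuple[SubjectRecord, Connectome]]:
    """Generate a cohort of (covariates, weighted connectome) pairs.

    Deterministic given ``spec.master_seed``; each subject draws from an
    independent child seed so cohorts are reproducible subject-by-subject.
    """
    spec.validate()
    master = np.random.SeedSequence(spec.master_seed)
    cohort_ss, *subject_ss = master.spawn(1 + spec.n_subjects)
    cohort_rng = np.random.default_rng(cohort_ss)

    modules = _module_assignment(spec.n_nodes, spec.n_modules)
    # cohort-fixed bridge nodes, one candidate set per module
    bridge_nodes = np.empty((spec.n_modules, spec.n_bridges_max), dtype=int)
    for m in range(spec.n_modules):
        members = np.flatnonzero(modules == m)
        bridge_nodes[m] = cohort_rng.choice(members, size=spec.n_bridges_max, replace=False)

    # node directions drawn once per cohort on the unit sphere
    dirs = cohort_rng.normal(size=(spec.n_nodes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    amin, amax = spec.age_range
    ages = cohort_rng.uniform(amin, amax, size=spec.n_subjects)
    sexes = np.where(
        cohort_rng.random(spec.n_subjects) < _P_FEMALE, "female", "male"
    ).astype(object)
    hands = cohort_rng.choice(
        list(_P_HAND), p=list(_P_HAND.values()), size=spec.n_subjects
    ).astype(object)
    _ensure_factor_levels(sexes, hands, cohort_rng)

    out: list[tuple[SubjectRecord, Connectome]] = []
    for i, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        age = float(ages[i])
        # head radius grows mildly (~10%) over the age range, with
        # individual variation so distance is not collinear with age
        scale = (1.0 + 0.1 * (age - amin) / (amax - amin)) * rng.normal(1.0, 0.03)
        coords = dirs * spec.sphere_radius_mm * scale
        from .connectivity import mean_node_distance

        w = _subject_adjacency(spec, modules, bridge_nodes, age, rng)
        seed = int(ss.generate_state(1)[0] % (2**31))
        rec = SubjectRecord(
            id=f"sub-{i:03d}",
            age_years=age,
            sex=str(sexes[i]),
            handedness=str(hands[i]),
            mean_node_distance=mean_node_distance(coords),
            seed=seed,
        )
        conn = Connectome(
            W=w,
            node_coords=coords,
            mean_distance=rec.mean_node_distance,
            subject_id=rec.id,
        )
        out.append((rec, conn))
    return out


def simulate_coupled_oscillators(
    n_nodes: int,
    coupling: list[tuple[int, int, float, float, float]],
    n_trials: int = 50,
    fs: float = 600.0,
    duration_s: float = 2.0,
    seed: int = 0,
    subject_id: str = "sim",
) -> NodeTimeseries:
    """Oscillatory recordings with known pairwise phase-lag structure.

    ``coupling`` entries are ``(i, j, freq_Hz, phase_lag_rad, snr)``: nodes
    ``i`` and ``j`` share a sinusoid at ``freq_Hz`` with the stated phase
    lag between them, plus independent Gaussian noise with standard
    deviation ``signal_sd / snr`` (``snr = inf`` gives a noiseless pair).
    Uncoupled nodes receive independent unit-variance noise.  The shared
    sinusoid's phase is re-drawn per trial.
    """
    if not duration_s > 0:
        raise ConfigurationError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration_s))
    t = np.arange(n_samples) / fs
    data = np.zeros((n_trials, n_nodes, n_samples))
    noisy = np.ones(n_nodes, dtype=bool)
    signal_sd = np.sqrt(0.5)  # sd of a unit-amplitude sinusoid

    for i, j, freq, lag, snr in coupling:
        if not 0 < freq < fs / 2:
            raise ConfigurationError(
                f"coupling frequency {freq} Hz not in (0, Nyquist={fs / 2} Hz)"
            )
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ConfigurationError("coupling node index out of range")
        phases = rng.uniform(0, 2 * np.pi, size=n_trials)
        for tr in range(n_trials):
            data[tr, i] += np.sin(2 * np.pi * freq * t + phases[tr])
            data[tr, j] += np.sin(2 * np.pi * freq * t + phases[tr] + lag)
        noise_sd = 0.0 if np.isinf(snr) else signal_sd / snr
        if noise_sd > 0:
            data[:, i] += rng.normal(0, noise_sd, size=(n_trials, n_samples))
            data[:, j] += rng.normal(0, noise_sd, size=(n_trials, n_samples))
        noisy[i] = noisy[j] = False

    for k in np.flatnonzero(noisy):
        data[:, k] = rng.normal(0, 1.0, size=(n_trials, n_samples))

    coords = rng.normal(size=(n_nodes, 3)) * 50.0
    return NodeTimeseries(subject_id=subject_id, data=data, fs=fs, node_coords=coords)


def _rising_mean(d: np.ndarray) -> np.ndarray:
    # saturating rise typical of percolation point vs initial density
    return 0.1 + 0.85 * (1.0 - np.exp(-6.0 * d))


def simulate_functional_cohort(
    n_subjects: int = 80,
    densities: np.ndarray | None = None,
    age_effect: float = 0.0,
    mean_function: str = "rising",
    noise_sd: float = 0.05,
    age_range: tuple[float, float] = (4.0, 19.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, FunctionalSample]:
    """Draw percolation-point-like functions with known covariate effects.

    ``y_i(d) = mu(d) + age_effect * (age_i - mean age) + eps_i(d)`` with
    ``eps`` i.i.d. N(0, noise_sd^2) across grid points and subjects; sex,
    handedness and mean node distance are drawn but carry no effect.
    ``mean_function='constant'`` gives a flat mu (all coefficient
    functions truly constant over density, the null of the overall
    constancy test); ``'rising'`` gives a saturating rise.
    """
    rng = np.random.default_rng(seed)
    if densities is None:
        densities = np.arange(1, 31) / 100.0
    densities = np.asarray(densities, dtype=float)
    ages = rng.uniform(*age_range, size=n_subjects)
    sex = np.where(rng.random(n_subjects) < _P_FEMALE, "female", "male")
    hand = rng.choice(list(_P_HAND), p=list(_P_HAND.values()), size=n_subjects)
    _ensure_factor_levels(sex, hand, rng)
    dist = rng.normal(80.0, 5.0, size=n_subjects)

    if mean_function == "constant":
        mu = np.full_like(densities, 0.5)
    elif mean_function == "rising":
        mu = _rising_mean(densities)
    else:
        raise ConfigurationError("mean_function must be 'rising' or 'constant'")

    y = (
        mu[None, :]
        + age_effect * (ages - ages.mean())[:, None]
        + rng.normal(0, noise_sd, size=(n_subjects, len(densities)))
    )
    ids = [f"sub-{i:03d}" for i in range(n_subjects)]
    cov = pd.DataFrame(
        {
            "id": ids,
            "age_years": ages,
            "sex": sex,
            "handedness": hand,
            "mean_node_distance": dist,
        }
    )
    return cov, FunctionalSample(densities=densities, values=y, subject_ids=ids)
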