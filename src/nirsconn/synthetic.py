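"""Synthetic fNIRS experiments with known condition-driven VAR dynamics.

The generator emulates the structure of a block-design walking experiment:
M spatially separated cortical regions whose signals follow a stable VAR(p)
with condition-dependent coefficients; a block paradigm (17 s initial and
final rests, 22 s task blocks, 10 s inter-block rests, 4 trials, 10.2 Hz);
regional signals expanded into several co-located measurement channels with
independent noise and optional outlier channels; and a forward Beer-Lambert
model producing two-wavelength raw intensities so the full pipeline --
SNIRF I/O, optical density, MBLL inversion, filtering, clustering,
projection, fitting -- can be exercised end to end with a known answer.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cdvar import companion_spectral_radius
from .errors import NumericalError, ValidationError
from .io import Channel, EventMarker, IntensityRecording, ProbeGeometry
from .preprocess import HbSeries, mbll_forward
from .projection import ClusterAssignment

__all__ = [
    "GroundTruth",
    "ParadigmSpec",
    "SimulatedRun",
    "SimulatedExperiment",
    "make_ground_truth",
    "simulate_condition_run",
    "sphere_anchors",
    "expand_to_channels",
    "simulate_experiment",
    "match_clusters",
]

_STABILITY_BOUND = 0.95


@dataclass
class GroundTruth:
    """Known coefficients of the condition-driven VAR generative model."""

    M: int
    K: int
    p: int
    phi0: np.ndarray                  # (p, M, M)
    deltas: np.ndarray                # (K, p, M, M)
    resid_cov: np.ndarray             # (M, M)
    seed: int
    sparsity: float
    effect_size: float

    def phi_total(self, k: int) -> np.ndarray:
        """Coefficients in force under condition k (0 = baseline)."""
        if k == 0:
            return self.phi0
        return self.phi0 + self.deltas[k - 1]

    def max_companion_radius(self) -> float:
        return max(
            companion_spectral_radius(self.phi_total(k))
            for k in range(self.K + 1)
        )


@dataclass(frozen=True)
class ParadigmSpec:
    """Block-design timing: initial/final standing rests, task blocks (one
    figure-eight walking round each), inter-block rests, trial count."""

    initial_rest_s: float = 17.0
    task_s: float = 22.0
    inter_rest_s: float = 10.0
    trials: int = 4
    fs: float = 10.2
    final_rest_s: float | None = None  # defaults to initial_rest_s

    def __post_init__(self) -> None:
        for name in ("initial_rest_s", "task_s", "inter_rest_s", "fs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.trials < 1:
            raise ValidationError("trials must be >= 1")

    @property
    def final_rest(self) -> float:
        return self.initial_rest_s if self.final_rest_s is None else self.final_rest_s

    @property
    def total_s(self) -> float:
        return (
            self.initial_rest_s
            + self.trials * self.task_s
            + (self.trials - 1) * self.inter_rest_s
            + self.final_rest
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.fs))

    def task_onsets_s(self) -> list[float]:
        return [
            self.initial_rest_s + i * (self.task_s + self.inter_rest_s)
            for i in range(self.trials)
        ]


def make_ground_truth(
    M: int,
    K: int,
    p: int = 1,
    sparsity: float = 0.2,
    effect_size: float = 0.4,
    seed: int = 0,
    diag: float = 0.3,
    resid_cov: np.ndarray | None = None,
) -> GroundTruth:
    """Random sparse, stable coefficient set.

    The baseline gets self-dependence ``diag`` on every region plus a
    ``sparsity`` fraction of the off-diagonal entries at +/- ``effect_size``
    (random signs), all on lag 1.  Each condition delta places the same
    number of off-diagonal entries, preferring positions left free by the
    baseline so baseline and condition effects are distinguishable.  The
    whole coefficient set is rescaled (if needed) until every condition's
    companion spectral radius is below 0.95, guaranteeing weak stationarity
    with margin.
    """
    if M < 1 or K < 0 or p < 1:
        raise ValidationError("need M >= 1, K >= 0, p >= 1")
    if not (0 <= sparsity <= 1):
        raise ValidationError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    off_diag = [(i, j) for i in range(M) for j in range(M) if i != j]
    n_off = int(round(sparsity * len(off_diag)))

    phi0 = np.zeros((p, M, M))
    phi0[0][np.diag_indices(M)] = diag
    support: set[tuple[int, int]] = set()
    if n_off:
        picks = rng.choice(len(off_diag), size=n_off, replace=False)
        for c in picks:
            i, j = off_diag[c]
            phi0[0, i, j] = effect_size * rng.choice([-1.0, 1.0])
            support.add((i, j))

    deltas = np.zeros((K, p, M, M))
    for k in range(K):
        free = [ij for ij in off_diag if ij not in support]
        pool = free if len(free) >= n_off else off_diag
        if n_off:
            picks = rng.choice(len(pool), size=n_off, replace=False)
            for c in picks:
                i, j = pool[c]
                deltas[k, 0, i, j] = effect_size * rng.choice([-1.0, 1.0])

    if resid_cov is None:
        resid_cov = np.eye(M)
    resid_cov = np.asarray(resid_cov, dtype=float)

    truth = GroundTruth(
        M=M, K=K, p=p, phi0=phi0, deltas=deltas, resid_cov=resid_cov,
        seed=seed, sparsity=sparsity, effect_size=effect_size,
    )
    for _ in range(50):
        r = truth.max_companion_radius()
        if r < _STABILITY_BOUND:
            return truth
        c = 0.9 * _STABILITY_BOUND / r
        truth = replace(truth, phi0=truth.phi0 * c, deltas=truth.deltas * c)
    raise NumericalError(
        "could not rescale coefficients to a stable regime; "
        "reduce sparsity or effect_size"
    )


def _innovations(rng, cov, n, law="gaussian", df=4.0):
    Lc = np.linalg.cholesky(cov)
    if law == "gaussian":
        w = rng.standard_normal((cov.shape[0], n))
    elif law == "student_t":
        if df <= 2:
            raise ValidationError("student_t innovations need df > 2")
        w = rng.standard_t(df, size=(cov.shape[0], n))
        w /= np.sqrt(df / (df - 2.0))  # unit variance
    else:
        raise ValidationError(f"unknown innovation law {law!r}")
    return Lc @ w


def simulate_condition_run(
    truth: GroundTruth,
    k: int,
    T: int,
    seed: int,
    burn_in: int = 200,
    innovation: str = "gaussian",
    df: float = 4.0,
) -> np.ndarray:
    """Simulate T post-burn-in samples of the region-level VAR under
    condition k (0 = baseline, k >= 1 adds that condition's delta)."""
    if not (0 <= k <= truth.K):
        raise ValidationError(f"condition index {k} outside 0..{truth.K}")
    phi = truth.phi_total(k)
    if companion_spectral_radius(phi) >= 1.0:
        raise NumericalError(
            f"condition {k} dynamics are unstable; refusing to simulate"
        )
    rng = np.random.default_rng(seed)
    M, p = truth.M, truth.p
    n = T + burn_in
    eps = _innovations(rng, truth.resid_cov, n, innovation, df)
    x = np.zeros((M, n))
    for t in range(n):
        acc = eps[:, t].copy()
        for l in range(1, p + 1):
            if t - l >= 0:
                acc += phi[l - 1] @ x[:, t - l]
        x[:, t] = acc
    return x[:, burn_in:]


def sphere_anchors(M: int, radius: float = 10.0) -> np.ndarray:
    """M well-separated anchor points on a sphere (Fibonacci lattice),
    standing in for regional centroids on an idealised spherical head of
    the given radius (cm)."""
    i = np.arange(M, dtype=float) + 0.5
    phi_angle = np.arccos(1 - 2 * i / M)
    theta = np.pi * (1 + 5**0.5) * i
    return radius * np.column_stack(
        [
            np.sin(phi_angle) * np.cos(theta),
            np.sin(phi_angle) * np.sin(theta),
            np.cos(phi_angle),
        ]
    )


def expand_to_channels(
    cluster_series: np.ndarray,
    *,
    fs: float = 10.2,
    channels_per_cluster: int = 5,
    channel_noise_sd: float = 0.1,
    outlier_channels: int = 0,
    outlier_offset: float = 0.0,
    seed: int = 0,
    noise_seed: int | None = None,
    anchors: np.ndarray | None = None,
    sd_separation: float = 3.0,
    hbr_ratio: float = -0.3,
    run_condition: str | None = None,
    event_markers=(),
) -> tuple[HbSeries, ProbeGeometry, ClusterAssignment]:
    """Expand M regional signals into co-located noisy channels.

    Cluster c spawns ``channels_per_cluster`` channels jittered tightly
    around its anchor (jitter SD = min inter-anchor distance / 20, so the
    spawning partition is recoverable by clustering).  Each channel carries
    the regional HbO signal plus independent Gaussian noise; HbR is a scaled
    mirror (ratio ``hbr_ratio``) with its own noise.  ``outlier_channels``
    channels (assigned round-robin across clusters) additionally receive a
    constant offset ``outlier_offset`` -- the failure mode the median
    projection is meant to absorb.  Also returns the generating partition as
    a :class:`ClusterAssignment` ground truth.

    ``seed`` drives the montage jitter (fix it to share one montage across
    runs); ``noise_seed`` drives the channel noise and defaults to ``seed``
    + 1, so a different noise draw on the same montage needs only a new
    ``noise_seed``.
    """
    import warnings

    g = np.asarray(cluster_series, dtype=float)
    if g.ndim != 2:
        raise ValidationError("cluster_series must be M x T")
    M, T = g.shape
    if channels_per_cluster < 1:
        raise ValidationError("channels_per_cluster must be >= 1")
    if anchors is None:
        anchors = sphere_anchors(M)
    anchors = np.asarray(anchors, dtype=float)
    if anchors.shape != (M, 3):
        raise ValidationError("anchors must be (M, 3)")

    if M > 1:
        d = np.linalg.norm(anchors[:, None] - anchors[None, :], axis=-1)
        min_dist = d[~np.eye(M, dtype=bool)].min()
    else:
        min_dist = 2.0
    jitter_sd = min_dist / 20.0

    per_cluster_outliers = np.zeros(M, dtype=int)
    outlier_flags = np.zeros(M * channels_per_cluster, dtype=bool)
    for o in range(outlier_channels):
        c = o % M
        slot = o // M
        if slot >= channels_per_cluster:
            raise ValidationError("more outliers requested than channels exist")
        outlier_flags[c * channels_per_cluster + slot] = True
        per_cluster_outliers[c] += 1
    if np.any(per_cluster_outliers >= (channels_per_cluster + 1) // 2) and \
            outlier_channels > 0 and channels_per_cluster > 1:
        if np.any(per_cluster_outliers * 2 >= channels_per_cluster):
            warnings.warn(
                "outliers reach half of a cluster's channels; the median's "
                "robustness guarantee no longer holds",
                stacklevel=2,
            )

    geom_rng = np.random.default_rng(seed)
    rng = np.random.default_rng(seed + 1 if noise_seed is None else noise_seed)
    L = M * channels_per_cluster
    labels = np.repeat(np.arange(M), channels_per_cluster)
    coords = anchors[labels] + geom_rng.normal(0.0, jitter_sd, size=(L, 3))

    u = geom_rng.standard_normal((L, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    sources = coords + (sd_separation / 2.0) * u
    detectors = coords - (sd_separation / 2.0) * u
    channels = []
    for pair in range(L):
        channels.append(Channel(pair, pair, 760.0))
        channels.append(Channel(pair, pair, 850.0))
    geometry = ProbeGeometry(sources, detectors, channels)

    hbo = g[labels] + rng.normal(0.0, channel_noise_sd, size=(L, T))
    hbo[outlier_flags] += outlier_offset
    hbr = hbr_ratio * hbo + rng.normal(0.0, channel_noise_sd / 2.0, size=(L, T))

    hb = HbSeries(
        hbo=hbo,
        hbr=hbr,
        fs=fs,
        channel_coords=coords,
        run_condition=run_condition,
        event_markers=list(event_markers),
    )
    assignment = ClusterAssignment(
        labels=labels, n_clusters=M, centroids=anchors, seed=seed
    )
    return hb, geometry, assignment


def _canonical_hrf(fs: float, duration_s: float = 30.0) -> np.ndarray:
    """Double-gamma hemodynamic response, peak normalised to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration_s, 1.0 / fs)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.max()


def block_envelope(paradigm: ParadigmSpec, kind: str = "boxcar") -> np.ndarray:
    """Task gating signal over the run: 1 inside task blocks, 0 in rests;
    optionally convolved with a canonical HRF (peak-normalised)."""
    n = paradigm.n_samples
    env = np.zeros(n)
    for onset in paradigm.task_onsets_s():
        a = int(round(onset * paradigm.fs))
        b = min(int(round((onset + paradigm.task_s) * paradigm.fs)), n)
        env[a:b] = 1.0
    if kind == "boxcar":
        return env
    if kind == "hrf":
        h = _canonical_hrf(paradigm.fs)
        out = np.convolve(env, h)[:n]
        peak = out.max()
        return out / peak if peak > 0 else out
    raise ValidationError(f"unknown envelope kind {kind!r}")


@dataclass
class SimulatedRun:
    """One condition's run: region-level truth plus channel-level data."""

    condition: str
    condition_index: int
    recording: IntensityRecording
    hb: HbSeries
    cluster_series: np.ndarray
    envelope: np.ndarray


@dataclass
class SimulatedExperiment:
    """A full synthetic experiment: shared montage, per-condition runs and
    the generating coefficients."""

    truth: GroundTruth
    paradigm: ParadigmSpec
    conditions: list[str]
    geometry: ProbeGeometry
    anchors: np.ndarray
    true_assignment: ClusterAssignment
    runs: list[SimulatedRun] = field(default_factory=list)


def simulate_experiment(
    truth: GroundTruth,
    paradigm: ParadigmSpec | None = None,
    conditions: list[str] | None = None,
    seed: int = 0,
    channels_per_cluster: int = 5,
    channel_noise_sd: float = 0.1,
    outlier_channels: int = 0,
    outlier_offset: float = 0.0,
    amplitude_uM: float = 1.0,
    rest_noise_sd: float = 0.2,
    envelope: str = "boxcar",
    innovation: str = "gaussian",
    baseline_intensity: float = 1.0,
) -> SimulatedExperiment:
    """Generate one run per condition, SNIRF-ready.

    Task blocks carry the condition's VAR dynamics gated by a block
    envelope; rests carry baseline noise.  Region signals are scaled to
    ``amplitude_uM`` micromolar, expanded to channels on a shared montage
    (same seed-derived geometry for every run), and pushed through the
    forward Beer-Lambert model to two-wavelength intensities
    I = I0 * exp(-dOD), so MBLL inversion recovers the hemoglobin series
    exactly up to a per-channel constant (optical density is referenced to
    the run-mean intensity, which absorbs any DC component).
    """
    if paradigm is None:
        paradigm = ParadigmSpec()
    if conditions is None:
        from .cdvar import DEFAULT_CONDITIONS

        conditions = list(DEFAULT_CONDITIONS[: truth.K + 1])
    if len(conditions) != truth.K + 1:
        raise ValidationError(
            f"{len(conditions)} condition names for K+1={truth.K + 1} conditions"
        )

    ss = np.random.SeedSequence(seed)
    geom_seed, *run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                             ss.spawn(1 + 3 * len(conditions))]

    anchors = sphere_anchors(truth.M)
    env = block_envelope(paradigm, envelope)
    T = paradigm.n_samples
    markers_proto = [
        EventMarker(onset, paradigm.task_s, "") for onset in paradigm.task_onsets_s()
    ]

    experiment = None
    runs = []
    for k, cond in enumerate(conditions):
        sim_seed = run_seeds[3 * k]
        rest_seed = run_seeds[3 * k + 1]
        noise_seed = run_seeds[3 * k + 2]
        ch_seed = geom_seed  # same montage jitter for every run

        x = simulate_condition_run(truth, k, T, sim_seed, innovation=innovation)
        rest_rng = np.random.default_rng(rest_seed)
        g = amplitude_uM * (
            env * x + (1.0 - env) * rest_noise_sd
            * rest_rng.standard_normal((truth.M, T))
        )
        markers = [EventMarker(m.onset, m.duration, cond) for m in markers_proto]
        hb, geometry, true_assignment = expand_to_channels(
            g,
            fs=paradigm.fs,
            channels_per_cluster=channels_per_cluster,
            channel_noise_sd=channel_noise_sd * amplitude_uM,
            outlier_channels=outlier_channels,
            outlier_offset=outlier_offset,
            seed=ch_seed,
            noise_seed=noise_seed,
            anchors=anchors,
            run_condition=cond,
            event_markers=markers,
        )
        distances = geometry.sd_distances()
        pairs = list(geometry.pairs().items())
        intens = np.empty((geometry.n_channels, T))
        for row, ((s, d), idx) in enumerate(pairs):
            od = mbll_forward(hb.hbo[row], hb.hbr[row], distances[idx[0]])
            intens[idx[0]] = baseline_intensity * np.exp(-od[0])
            intens[idx[1]] = baseline_intensity * np.exp(-od[1])
        recording = IntensityRecording(
            intensities=intens,
            fs=paradigm.fs,
            wavelengths=np.array([c.wavelength for c in geometry.channels]),
            run_condition=cond,
            event_markers=markers,
        )
        runs.append(
            SimulatedRun(
                condition=cond,
                condition_index=k,
                recording=recording,
                hb=hb,
                cluster_series=g,
                envelope=env,
            )
        )
        if experiment is None:
            experiment = SimulatedExperiment(
                truth=truth,
                paradigm=paradigm,
                conditions=list(conditions),
                geometry=geometry,
                anchors=anchors,
                true_assignment=true_assignment,
            )
    experiment.runs = runs
    return experiment


def match_clusters(assignment: ClusterAssignment, anchors: np.ndarray) -> np.ndarray:
    """Permutation mapping estimated cluster labels to generating anchors:
    entry m is the anchor index nearest centroid m.  Raises if the mapping
    is not one-to-one (clustering failed to recover the partition)."""
    anchors = np.asarray(anchors, dtype=float)
    d = np.linalg.norm(
        assignment.centroids[:, None, :] - anchors[None, :, :], axis=-1
    )
    perm = np.argmin(d, axis=1)
    if len(set(perm.tolist())) != len(perm):
        raise NumericalError("cluster-to-anchor matching is not one-to-one")
    return perm
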