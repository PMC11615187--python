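"""Seeded ground-truth generators for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes: nonlinear MVAR systems with known linear coefficient matrices
and known nonlinear couplings (for the connectivity estimator),
two-condition oscillatory sensor epochs with planted band-power effects
(for the sensor cluster test), source activity projected through a known
leadfield (for the beamformer), behavioral scores with a stated
correlation (for brain-behavior statistics), and a full multi-subject
two-condition study with a planted coupling contrast (for the
end-to-end group analysis).

All generators are deterministic given their spec and seed; one global
seed expands into per-subject / per-trial substreams via counter-based
SeedSequence spawning, so results do not depend on evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EpochedData, SourceModel, seed_streams

__all__ = [
    "NMVARSpec", "BandEffectSpec", "simulate_nmvar", "simulate_band_trials",
    "simulate_source_projection", "simulate_behavior", "simulate_condition_study",
    "companion_spectral_radius", "oscillator_var_spec", "make_grid_source_model",
]

NONLINEAR_KINDS = ("square", "tanh", "cross")


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix of coefficient stack A (p, M, M)."""
    A = np.asarray(A, dtype=float)
    p, M, _ = A.shape
    comp = np.zeros((M * p, M * p))
    comp[:M] = A.transpose(1, 0, 2).reshape(M, M * p)
    if p > 1:
        comp[M:, :-M] = np.eye(M * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class NMVARSpec:
    """Specification of a nonlinear MVAR system.

    ``A`` is the stack of p linear coefficient matrices A_d (A[d-1][i, j]
    is the linear contribution of node j at lag d to node i).
    ``nonlinear_terms`` is a list of (target, source, lag, kind, gain)
    tuples with kind in {"square", "tanh", "cross"}: square adds
    gain*x_src(n-d)^2, tanh adds gain*tanh(x_src(n-d)), cross adds
    gain*x_src(n-d)*x_src(n-d-1) (product of two consecutive lagged
    values of the source).
    """

    M: int
    p: int
    A: np.ndarray
    nonlinear_terms: list = field(default_factory=list)
    noise_sd: float | np.ndarray = 1.0
    n_samples: int = 1000
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.p, self.M, self.M):
            raise ValueError(f"A must have shape (p, M, M) = "
                             f"({self.p}, {self.M}, {self.M}), got {self.A.shape}")
        if self.p < 1:
            raise ValueError("lag order p must be >= 1")
        rho = companion_spectral_radius(self.A)
        if rho >= 1.0:
            raise ValueError(
                f"linear part is non-stationary: companion spectral radius "
                f"{rho:.4f} >= 1; shrink the coefficient matrices")
        for t in self.nonlinear_terms:
            tgt, src, lag, kind, gain = t
            if kind not in NONLINEAR_KINDS:
                raise ValueError(f"unknown nonlinear kind {kind!r}")
            if not (0 <= tgt < self.M and 0 <= src < self.M):
                raise ValueError(f"nonlinear term node out of range: {t}")
            if not 1 <= lag <= self.p:
                raise ValueError(f"nonlinear term lag out of range: {t}")
            if not np.isfinite(gain):
                raise ValueError(f"non-finite nonlinear gain: {t}")

    @property
    def burn_in(self) -> int:
        return max(10 * self.p, 100)

    def edges(self) -> list[tuple[int, int, str]]:
        """Ground-truth directed edges as (source, target, kind) tuples."""
        out = []
        for i in range(self.M):
            for j in range(self.M):
                if i != j and np.any(self.A[:, i, j] != 0):
                    out.append((j, i, "linear"))
        for tgt, src, _lag, _kind, gain in self.nonlinear_terms:
            if gain != 0 and (src, tgt, "nonlinear") not in out:
                out.append((src, tgt, "nonlinear"))
        return out


def simulate_nmvar(spec: NMVARSpec) -> tuple[np.ndarray, list]:
    """Simulate an nMVAR system.

    Returns
    -------
    data : ndarray, shape (n_trials, M, n_samples)
        Each trial generated independently; the first
        ``max(10*p, 100)`` samples of each trial are burn-in and are
        discarded before returning.
    edges : list of (source, target, kind)
        Ground-truth directed couplings.
    """
    M, p = spec.M, spec.p
    noise_sd = np.broadcast_to(np.asarray(spec.noise_sd, dtype=float), (M,))
    hist_len = p + 1  # "cross" needs lag d and d+1 of the source
    total = spec.burn_in + spec.n_samples
    rngs = seed_streams(spec.seed, spec.n_trials)
    data = np.empty((spec.n_trials, M, spec.n_samples))
    for tr, rng in enumerate(rngs):
        x = np.zeros((total + hist_len, M))
        x[:hist_len] = rng.normal(0.0, noise_sd, size=(hist_len, M))
        eps = rng.normal(0.0, noise_sd, size=(total, M))
        for n in range(hist_len, total + hist_len):
            xn = eps[n - hist_len].copy()
            for d in range(1, p + 1):
                xn += spec.A[d - 1] @ x[n - d]
            for tgt, src, lag, kind, gain in spec.nonlinear_terms:
                v = x[n - lag, src]
                if kind == "square":
                    xn[tgt] += gain * v * v
                elif kind == "tanh":
                    xn[tgt] += gain * np.tanh(v)
                else:  # cross
                    xn[tgt] += gain * v * x[n - lag - 1, src]
            x[n] = xn
        out = x[hist_len + spec.burn_in:].T
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(
                "nMVAR simulation diverged (non-finite samples); "
                "reduce nonlinear gains or coefficient magnitudes")
        data[tr] = out
    return data, spec.edges()


def oscillator_var_spec(M: int, p: int = 2, freqs_hz=None, srate: float = 256.0,
                        damping: float = 0.98, coupling=None,
                        noise_sd: float = 1.0, **kw) -> NMVARSpec:
    """Convenience constructor: coupled damped-oscillator VAR nodes.

    Each node is an AR(2) resonator with pole radius ``damping`` at its
    own frequency; ``coupling`` is a list of (source, target, lag,
    strength) linear cross-couplings.  With damping close to 1 the
    process variance is dominated by the autoregression, giving the
    high signal-to-residual regime (R^2 near 1) band-limited cortical
    sources live in.
    """
    if p < 2:
        raise ValueError("oscillator nodes need p >= 2")
    if freqs_hz is None:
        freqs_hz = 4.0 + 3.0 * np.arange(M)
    A = np.zeros((p, M, M))
    for i, f in enumerate(np.broadcast_to(freqs_hz, (M,))):
        w = 2 * np.pi * f / srate
        A[0, i, i] = 2 * damping * np.cos(w)
        A[1, i, i] = -damping ** 2
    for (src, tgt, lag, strength) in (coupling or []):
        A[lag - 1, tgt, src] += strength
    return NMVARSpec(M=M, p=p, A=A, noise_sd=noise_sd, **kw)


# ---------------------------------------------------------------------------
# Two-condition band-effect sensor data
# ---------------------------------------------------------------------------

@dataclass
class BandEffectSpec:
    """Two-condition oscillatory sensor study with planted band effects.

    ``effect_size_d`` plants, per band, a deterministic relative
    amplitude contrast between conditions: the oscillation amplitude on
    that band's effect channels is multiplied by ``1 + 0.4*d`` in
    condition A relative to condition B.  Per-subject amplitude jitter
    multiplies both conditions equally, so d=0 is an exact null and the
    sign of the per-subject measured power difference follows the sign
    of d for essentially every subject.
    """

    bands: dict
    channel_groups: dict
    effect_size_d: dict
    srate: float = 256.0
    n_subjects: int = 20
    n_trials_per_condition: int = 30
    trial_window: tuple = (-2.0, 2.0)
    n_channels: int = 32
    osc_amplitude: float = 1.0
    background_sd: float = 1.0
    subject_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.srate) or self.srate <= 0:
            raise ValueError("sampling rate must be finite and positive")
        nyq = self.srate / 2
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi < nyq):
                raise ValueError(f"band {name}: need 0 < f_lo < f_hi < Nyquist")
        for name, chans in self.channel_groups.items():
            if name not in self.bands:
                raise ValueError(f"channel group for unknown band {name!r}")
            if np.max(chans) >= self.n_channels or np.min(chans) < 0:
                raise ValueError(f"effect channels for {name} outside channel set")


def _pink_noise(rng, n_channels, n_samples, srate, sd):
    """1/f-power background noise via spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, 1 / srate)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    x *= sd / x.std(axis=-1, keepdims=True)
    return x


def _narrowband_noise(rng, n_samples, srate, lo, hi):
    """Unit-variance band-limited Gaussian noise (oscillatory burst carrier)."""
    pad = n_samples  # generate longer and trim to dodge filter edge transients
    white = rng.standard_normal(n_samples + 2 * pad)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=srate, output="sos")
    x = sps.sosfiltfilt(sos, white)[pad:pad + n_samples]
    s = x.std()
    return x / s if s > 0 else x


def simulate_band_trials(spec: BandEffectSpec, channel_positions: np.ndarray
                         ) -> list[tuple[EpochedData, EpochedData]]:
    """Generate per-subject (condition A, condition B) epoched sensor data.

    Every channel carries 1/f background noise; each band's effect
    channels additionally carry narrowband oscillatory activity whose
    amplitude differs between conditions by the planted contrast.
    Returns one (EpochedData_A, EpochedData_B) pair per subject.
    """
    channel_positions = np.asarray(channel_positions, dtype=float)
    if channel_positions.shape[0] != spec.n_channels:
        raise ValueError("channel_positions must match spec.n_channels")
    t0, t1 = spec.trial_window
    n_samples = int(round((t1 - t0) * spec.srate))
    ch_names = [f"ch{c:02d}" for c in range(spec.n_channels)]
    rngs = seed_streams(spec.seed, spec.n_subjects)
    out = []
    for rng in rngs:
        jitter = np.exp(rng.normal(0.0, spec.subject_jitter_sd))
        conds = {}
        for cond in ("A", "B"):
            trials = np.empty((spec.n_trials_per_condition, spec.n_channels, n_samples))
            for tr in range(spec.n_trials_per_condition):
                x = _pink_noise(rng, spec.n_channels, n_samples,
                                spec.srate, spec.background_sd)
                for name, (lo, hi) in spec.bands.items():
                    chans = spec.channel_groups.get(name)
                    if chans is None:
                        continue
                    d = spec.effect_size_d.get(name, 0.0)
                    amp = spec.osc_amplitude * jitter
                    if cond == "A":
                        amp *= max(0.0, 1.0 + 0.4 * d)
                    for c in chans:
                        x[c] += amp * _narrowband_noise(rng, n_samples,
                                                        spec.srate, lo, hi)
                trials[tr] = x
            conds[cond] = EpochedData(
                trials, spec.srate, ch_names, channel_positions, tmin=t0,
                condition=np.array([cond] * spec.n_trials_per_condition))
        out.append((conds["A"], conds["B"]))
    return out


# ---------------------------------------------------------------------------
# Source projection fixture
# ---------------------------------------------------------------------------

def make_grid_source_model(shape=(10, 10, 10), edge_mm: float = 5.0,
                           n_channels: int = 32, n_labels: int = 8,
                           seed: int = 0) -> SourceModel:
    """Small synthetic lattice source model with integer atlas labels.

    A stand-in for a template-grid leadfield: random smooth gain
    columns on a regular voxel lattice.  Synthetic by construction —
    it encodes no head geometry.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    grid = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                indexing="ij"), axis=-1).reshape(-1, 3)
    coords = grid * edge_mm
    n_vox = coords.shape[0]
    # channels on a sphere above the grid; gains fall off with distance
    ch_dir = rng.standard_normal((n_channels, 3))
    ch_dir /= np.linalg.norm(ch_dir, axis=1, keepdims=True)
    radius = 1.5 * np.max(coords)
    center = coords.mean(axis=0)
    ch_pos = center + radius * ch_dir
    lf = np.empty((n_channels, n_vox, 3))
    for v in range(n_vox):
        dvec = ch_pos - coords[v]
        dist = np.linalg.norm(dvec, axis=1)
        # dipole gain ~ projection of orientation on the channel direction / r^2
        for o in range(3):
            e = np.zeros(3)
            e[o] = 1.0
            lf[:, v, o] = (dvec @ e) / dist ** 3
    lf /= np.abs(lf).max()
    labels = 1 + (np.arange(n_vox) * n_labels) // n_vox
    return SourceModel(lf, coords, edge_mm, labels)


def simulate_source_projection(source_tcs: np.ndarray, source_voxel_indices,
                               model: SourceModel, sensor_noise_sd: float,
                               orientations=None, n_trials: int = 1,
                               srate: float = 256.0, seed: int = 0
                               ) -> tuple[EpochedData, dict]:
    """Project K planted sources through the leadfield and add white noise.

    source_tcs : (K, n_samples) source time courses (shared across trials).
    Returns the sensor epochs and a ground-truth dict (voxel indices,
    orientations, source time courses).
    """
    source_tcs = np.atleast_2d(np.asarray(source_tcs, dtype=float))
    K, n_samples = source_tcs.shape
    idx = np.asarray(source_voxel_indices, dtype=int)
    if idx.shape[0] != K:
        raise ValueError("one voxel index per source required")
    if np.any(idx < 0) or np.any(idx >= model.n_voxels):
        raise ValueError("source voxel index outside the grid")
    rng = np.random.default_rng(seed)
    if orientations is None:
        orientations = rng.standard_normal((K, 3))
    orientations = np.asarray(orientations, dtype=float)
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)
    clean = np.zeros((model.n_channels, n_samples))
    for k in range(K):
        gain = model.leadfield[:, idx[k], :] @ orientations[k]
        clean += np.outer(gain, source_tcs[k])
    trials = clean[None] + rng.normal(0.0, sensor_noise_sd,
                                      size=(n_trials, model.n_channels, n_samples))
    ch_names = [f"ch{c:02d}" for c in range(model.n_channels)]
    ch_pos = np.zeros((model.n_channels, 3))
    epochs = EpochedData(trials, srate, ch_names, ch_pos, tmin=0.0)
    truth = {"voxel_indices": idx, "orientations": orientations,
             "source_tcs": source_tcs}
    return epochs, truth


# ---------------------------------------------------------------------------
# Behavioral scores
# ---------------------------------------------------------------------------

def simulate_behavior(connectivity_summary: np.ndarray, r_target: float,
                      seed: int = 0, mean: float = 0.0, sd: float = 1.0
                      ) -> np.ndarray:
    """Behavioral scores with population correlation ``r_target`` to the summary."""
    x = np.asarray(connectivity_summary, dtype=float)
    if abs(r_target) >= 1:
        raise ValueError("|r_target| must be < 1")
    sx = x.std()
    if sx == 0:
        raise ValueError("connectivity summary has zero variance")
    z = (x - x.mean()) / sx
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(x.shape[0])
    scores = r_target * z + np.sqrt(1 - r_target ** 2) * noise
    return mean + sd * scores


# ---------------------------------------------------------------------------
# End-to-end multi-subject study with a planted coupling contrast
# ---------------------------------------------------------------------------

def simulate_condition_study(n_subjects: int = 40, M: int = 3, p: int = 2,
                             base_coupling: float = 0.4,
                             effect_size_d: float = 0.5,
                             edge_sd_frac: float = 0.3,
                             noise_sd: float = 1.0,
                             n_trials: int = 20, n_samples: int = 128,
                             seed: int = 0) -> dict:
    """Two-condition multi-subject nMVAR study with a per-edge coupling effect.

    A fixed set of directed cross-couplings (a ring j -> j+1 at lag 1)
    carries strength ``base_coupling`` jittered per subject and edge.
    Condition B subtracts a per-subject, per-edge difference drawn as
    N(mu, sigma) with mu/sigma = ``effect_size_d``: each edge's coupling
    contrast across subjects has standardized effect effect_size_d, and
    differences are independent across edges, so a network-mean
    contrast aggregates them.

    Returns a dict with per-subject condition data arrays
    (``data[s]["A"]`` of shape (n_trials, M, n_samples)), the planted
    edge list and the per-subject coupling matrices.
    """
    ring = [((j + 1) % M, j) for j in range(M)]  # (target, source), lag 1
    sigma = edge_sd_frac * base_coupling
    mu = effect_size_d * sigma
    rngs = seed_streams(seed, n_subjects)
    data, couplings = [], []
    for rng in rngs:
        entry, coup = {}, {}
        jitter = rng.normal(0.0, sigma, size=len(ring))
        diff = rng.normal(mu, sigma, size=len(ring))
        for cond in ("A", "B"):
            A = np.zeros((p, M, M))
            for i in range(M):
                A[0, i, i] = 0.5
                if p > 1:
                    A[1, i, i] = 0.2
            for e, (tgt, src) in enumerate(ring):
                c = base_coupling + jitter[e]
                if cond == "B":
                    c -= diff[e]
                A[0, tgt, src] = c
                coup[(src, tgt, cond)] = c
            # shrink toward stability if a jitter draw crossed the boundary
            while companion_spectral_radius(A) >= 0.995:
                A *= 0.95
            spec = NMVARSpec(M=M, p=p, A=A, noise_sd=noise_sd,
                             n_samples=n_samples, n_trials=n_trials,
                             seed=int(rng.integers(2 ** 31)))
            entry[cond], _ = simulate_nmvar(spec)
        data.append(entry)
        couplings.append(coup)
    return {"data": data, "edges": [(s, t) for (t, s) in ring],
            "couplings": couplings, "M": M, "p": p}
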