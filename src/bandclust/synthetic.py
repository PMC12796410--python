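"""Synthetic EEG-like cohorts with planted band-specific phase-lagged coupling.

The generator emulates the study design the downstream pipeline expects:
a cohort of children, each recorded at rest before and after a short play
session, with connectivity structure planted in the delta and beta bands and
two latent subgroups that differ in network *topology* (segregated
community structure vs. density-matched uniform wiring) but not in edge
density.  A behavioral table mirrors the questionnaire/working-memory schema
of such studies, with configurable subgroup effects (zero by default for
device-use variables, so null results hold by construction).

The oscillatory sources are narrowband Gaussian processes built directly in
the frequency domain (complex Gaussian spectrum restricted to the band),
i.e. ideal bandpass-filtered white noise.  A coupled channel pair shares a
source, with the second channel receiving a phase-rotated copy — this is
what the weighted Phase Lag Index detects.  Confounds available: per-channel
1/f (pink) noise and a common zero-lag broadband source that wPLI must
suppress.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import BETA, BROADBAND, DELTA, BandSpec, Recording

__all__ = [
    "CouplingGraph",
    "SubgroupSpec",
    "NoiseConfig",
    "EffectConfig",
    "Cohort",
    "SEGREGATED",
    "INTEGRATED",
    "make_coupling_graph",
    "synthesize_recording",
    "generate_cohort",
    "expected_density",
]


@dataclass(frozen=True)
class CouplingGraph:
    """Ground-truth phase-lagged coupling structure for one band.

    ``edges`` are unordered channel pairs (i < j); ``lag_per_edge`` holds the
    phase lag in radians, strictly inside (0, pi) for every true coupling.
    """

    n_channels: int
    edges: tuple[tuple[int, int], ...]
    lag_per_edge: tuple[float, ...]
    band: BandSpec

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.lag_per_edge):
            raise ValueError("one lag per edge required")
        for (i, j), lag in zip(self.edges, self.lag_per_edge):
            if i == j:
                raise ValueError("self-edges not allowed")
            if not (0 <= i < j < self.n_channels):
                raise ValueError("edges must be ordered pairs within range")
            if not (0.0 < lag < math.pi):
                raise ValueError("lags must lie in (0, pi)")

    @property
    def density(self) -> float:
        m = self.n_channels * (self.n_channels - 1) / 2
        return len(self.edges) / m


@dataclass(frozen=True)
class SubgroupSpec:
    """Topology template for one latent subgroup.

    ``segregated`` uses a stochastic block model (``community_count`` blocks,
    within-block probability ``p_within``, between-block ``p_between``);
    ``integrated`` uses uniform-random wiring matched to the same expected
    density, so the two subgroups differ in topology, not in density.
    """

    label: str
    community_count: int = 4
    p_within: float = 0.8
    p_between: float = 0.04
    coupling_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ("segregated", "integrated"):
            raise ValueError("label must be 'segregated' or 'integrated'")
        for p in (self.p_within, self.p_between):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.label == "segregated" and self.p_within < self.p_between:
            raise ValueError("segregated requires p_within >= p_between")
        if self.community_count < 1:
            raise ValueError("community_count must be >= 1")


#: Default subgroup templates.  The segregated template's expected density at
#: 19 channels is ~0.20, matching the downstream binarization density so the
#: retained edges coincide with the planted structure.
SEGREGATED = SubgroupSpec("segregated", community_count=4, p_within=0.8, p_between=0.04)
INTEGRATED = SubgroupSpec("integrated", community_count=4, p_within=0.8, p_between=0.04)

#: Range of planted phase lags (radians): away from both 0 and pi/2 extremes.
LAG_RANGE = (math.pi / 8, 3 * math.pi / 8)


def _communities(n_channels: int, k: int) -> np.ndarray:
    """Assign channels to k nearly equal contiguous communities."""
    return np.array_split(np.arange(n_channels), k)


def _pair_masks(n_channels: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    comm = np.empty(n_channels, dtype=int)
    for c, members in enumerate(_communities(n_channels, k)):
        comm[members] = c
    iu, ju = np.triu_indices(n_channels, k=1)
    within = comm[iu] == comm[ju]
    return within, ~within


def expected_density(spec: SubgroupSpec, n_channels: int) -> float:
    """Expected edge density of the template graph on ``n_channels``.

    Both labels use the same block-weighted formula, so an integrated spec
    with the same probability fields as a segregated one is density-matched
    by construction — it just spreads that density uniformly.
    """
    within, between = _pair_masks(n_channels, spec.community_count)
    m = within.size
    return (spec.p_within * within.sum() + spec.p_between * between.sum()) / m


def make_coupling_graph(
    spec: SubgroupSpec,
    band: BandSpec,
    n_channels: int,
    seed: int | np.random.Generator,
) -> CouplingGraph:
    """Sample a ground-truth coupling graph for one subgroup and band.

    Segregated subgroups get stochastic-block-model edges; integrated ones
    get uniform-random edges at the segregated template's expected density.
    Each edge receives a lag drawn uniformly from [pi/8, 3pi/8].
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_channels, k=1)
    if spec.label == "segregated":
        within, _ = _pair_masks(n_channels, spec.community_count)
        p = np.where(within, spec.p_within, spec.p_between)
    else:
        p = np.full(iu.size, expected_density(spec, n_channels))
    chosen = rng.random(iu.size) < p
    edges = tuple((int(i), int(j)) for i, j in zip(iu[chosen], ju[chosen]))
    lags = tuple(float(v) for v in rng.uniform(*LAG_RANGE, size=len(edges)))
    return CouplingGraph(
        n_channels=n_channels, edges=edges, lag_per_edge=lags, band=band
    )


def check_density_match(
    a: CouplingGraph, b: CouplingGraph, tol: float = 0.10
) -> None:
    """Error if the two templates' realized densities differ by > ``tol``."""
    hi = max(a.density, b.density)
    if hi > 0 and abs(a.density - b.density) / hi > tol:
        raise ValueError(
            f"template density mismatch: {a.density:.3f} vs {b.density:.3f}"
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Additive confound levels, as RMS amplitudes relative to unit sources."""

    pink_gain: float = 0.7
    zero_lag_mix_gain: float = 0.5


def _narrowband_analytic(
    rng: np.random.Generator, n_samples: int, rate_hz: float, band: BandSpec
) -> np.ndarray:
    """Unit-RMS analytic narrowband Gaussian process (complex, length n)."""
    freqs = np.fft.fftfreq(n_samples, d=1.0 / rate_hz)
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec = np.zeros(n_samples, dtype=complex)
    k = int(mask.sum())
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    z = np.fft.ifft(spec)
    rms = np.sqrt(np.mean(z.real**2))
    return z / rms if rms > 0 else z


def _pink_noise(
    rng: np.random.Generator, n_samples: int, rate_hz: float
) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * scale, n=n_samples)
    return x / np.sqrt(np.mean(x**2))


def synthesize_recording(
    graph_delta: CouplingGraph,
    graph_beta: CouplingGraph,
    duration_s: float = 120.0,
    rate_hz: float = 256.0,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
    coupling_gain: float = 1.0,
    participant_id: str = "P00",
    condition: str = "pre",
) -> Recording:
    """Render one multichannel recording from per-band coupling graphs.

    Every edge contributes a shared narrowband source: channel i receives
    Re(z), channel j receives Re(z * exp(-i*lag)), a genuinely phase-lagged
    dependence.  On top of that every channel gets independent pink noise and
    all channels share one zero-lag broadband source (a volume-conduction
    stand-in that wPLI is designed to reject).
    """
    for g in (graph_delta, graph_beta):
        if g.band.high_hz * 2 >= rate_hz:
            raise ValueError(
                f"rate {rate_hz} Hz violates Nyquist for band {g.band.name!r}"
            )
    if graph_delta.n_channels != graph_beta.n_channels:
        raise ValueError("per-band graphs must share the channel count")
    n_ch = graph_delta.n_channels
    n = int(round(duration_s * rate_hz))
    if n < 1:
        raise ValueError("duration too short")
    rng = np.random.default_rng(seed)
    data = np.zeros((n_ch, n))
    for g in (graph_delta, graph_beta):
        for (i, j), lag in zip(g.edges, g.lag_per_edge):
            z = _narrowband_analytic(rng, n, rate_hz, g.band)
            data[i] += coupling_gain * z.real
            data[j] += coupling_gain * (z * np.exp(-1j * lag)).real
    if noise.zero_lag_mix_gain > 0:
        common = _narrowband_analytic(rng, n, rate_hz, BROADBAND).real
        common /= np.sqrt(np.mean(common**2))
        data += noise.zero_lag_mix_gain * common
    if noise.pink_gain > 0:
        for c in range(n_ch):
            data[c] += noise.pink_gain * _pink_noise(rng, n, rate_hz)
    labels = [f"Ch{c + 1:02d}" for c in range(n_ch)]
    return Recording(
        participant_id=participant_id,
        condition=condition,
        channel_labels=labels,
        rate_hz=rate_hz,
        data=data,
    )


@dataclass(frozen=True)
class EffectConfig:
    """Planted between-subgroup effects in the behavioral table.

    Defaults mirror the magnitude of subgroup contrasts such studies report:
    a ~6-point shift on the second working-memory trial, ~3.6 on the third,
    and a higher proportion of girls in the segregated subgroup.  Device-use
    variables never depend on the subgroup (planted null).
    """

    wm2_shift: float = 5.8
    wm3_shift: float = 3.6
    girl_p: tuple[float, float] = (0.20, 0.64)  # (subgroup 1, subgroup 2)

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(wm2_shift=0.0, wm3_shift=0.0, girl_p=(0.35, 0.35))


# Base behavioral distributions (subgroup-independent components); means/SDs
# chosen at the scale typical for 5-7 year-olds on a span-style WM task.
_WM_BASE = {"wm1": (16.2, 7.7), "wm2": (10.8, 6.5), "wm3": (7.5, 5.4)}
_WM_TIME = {"wm_time1": (3.1, 1.9), "wm_time2": (2.0, 1.3), "wm_time3": (1.3, 0.9)}
_ORDINAL_P = {
    "child_weekday_use": (0.55, 0.33, 0.10, 0.02),
    "child_weekend_use": (0.28, 0.37, 0.23, 0.12),
    "parent_weekday_use": (0.05, 0.20, 0.35, 0.40),
    "parent_weekend_use": (0.10, 0.30, 0.42, 0.18),
}


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, low: float = 0.0
) -> np.ndarray:
    """Normal draws truncated below at ``low`` by redrawing (vectorized)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, low, None)


def make_behavioral_table(
    labels: np.ndarray,
    effect_config: EffectConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Behavioral/questionnaire table with subgroup-dependent WM effects.

    ``labels`` are 1-based subgroup ids; subgroup 2 receives the WM shifts.
    """
    n = labels.size
    is2 = labels == 2
    rows: dict[str, np.ndarray] = {
        "participant_id": np.array([f"P{i + 1:02d}" for i in range(n)])
    }
    girl_p = np.where(is2, effect_config.girl_p[1], effect_config.girl_p[0])
    rows["sex"] = np.where(rng.random(n) < girl_p, "girl", "boy")
    rows["age_years"] = np.round(_trunc_normal(rng, 6.1, 1.35, n, low=3.0), 1)
    rows["errors"] = np.round(_trunc_normal(rng, 3.7, 2.9, n)).astype(int)
    shifts = {"wm1": 0.0, "wm2": effect_config.wm2_shift, "wm3": effect_config.wm3_shift}
    for name, (mean, sd) in _WM_BASE.items():
        mu = mean + np.where(is2, shifts[name], 0.0)
        draws = np.array(
            [rng.normal(m, sd) for m in mu]
        )
        draws = np.clip(draws, 0.0, None)
        rows[name] = np.round(draws).astype(int)
    for name, (mean, sd) in _WM_TIME.items():
        rows[name] = np.round(_trunc_normal(rng, mean, sd, n, low=0.2), 2)
    for name, probs in _ORDINAL_P.items():
        rows[name] = rng.choice(4, size=n, p=probs)
    rows["own_device"] = rng.random(n) < 14 / 31
    rows["played_before"] = rng.random(n) < 15 / 31
    rows["parent_education"] = np.where(
        rng.random(n) < 21 / 31, "higher", "secondary"
    )
    rows["parent_age"] = np.round(_trunc_normal(rng, 36.6, 5.1, n, low=20.0), 1)
    df = pd.DataFrame(rows)
    assert df[list(_ORDINAL_P)].isin([0, 1, 2, 3]).all().all()
    return df


@dataclass
class Cohort:
    """A generated cohort: recordings, behavioral table, ground truth."""

    recordings: list[tuple[Recording, Recording]]  # (pre, post) per participant
    behavioral: pd.DataFrame
    ground_truth: np.ndarray  # 1-based subgroup labels
    manifest: dict = field(default_factory=dict)


def generate_cohort(
    n_participants: int = 31,
    subgroup_fraction: float = 11 / 31,
    effect_config: EffectConfig = EffectConfig(),
    seed: int = 0,
    n_channels: int = 19,
    duration_s: float = 120.0,
    rate_hz: float = 256.0,
    bands: tuple[BandSpec, BandSpec] = (DELTA, BETA),
    subgroup_specs: tuple[SubgroupSpec, SubgroupSpec] = (INTEGRATED, SEGREGATED),
    noise: NoiseConfig = NoiseConfig(),
) -> Cohort:
    """Generate a full pre/post cohort with two latent subgroups.

    ``round(subgroup_fraction * n)`` participants are assigned subgroup 2
    (the segregated template by default).  Each participant samples their own
    coupling graphs from their subgroup's template; the post recording reuses
    the pre coupling graphs with a fresh noise realization, so the pre/post
    connectivity null holds by construction.
    """
    if n_participants < 4:
        raise ValueError("need at least 4 participants")
    n2 = int(round(subgroup_fraction * n_participants))
    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    labels = np.ones(n_participants, dtype=int)
    labels[assign_rng.permutation(n_participants)[:n2]] = 2

    recordings: list[tuple[Recording, Recording]] = []
    child_seeds = ss.spawn(n_participants + 1)
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        spec = subgroup_specs[labels[p] - 1]
        prng = np.random.default_rng(child_seeds[p])
        graphs = [
            make_coupling_graph(spec, band, n_channels, prng) for band in bands
        ]
        pair = []
        for condition in ("pre", "post"):
            pair.append(
                synthesize_recording(
                    graphs[0],
                    graphs[1],
                    duration_s=duration_s,
                    rate_hz=rate_hz,
                    noise=noise,
                    seed=prng,
                    coupling_gain=spec.coupling_gain,
                    participant_id=pid,
                    condition=condition,
                )
            )
        recordings.append((pair[0], pair[1]))

    behav_rng = np.random.default_rng(child_seeds[-1])
    behavioral = make_behavioral_table(labels, effect_config, behav_rng)
    manifest = {
        "seed": seed,
        "n_participants": n_participants,
        "n_subgroup2": int(n2),
        "n_channels": n_channels,
        "duration_s": duration_s,
        "rate_hz": rate_hz,
        "bands": [[b.name, b.low_hz, b.high_hz] for b in bands],
        "subgroups": [s.label for s in subgroup_specs],
        "coupling_gain": [s.coupling_gain for s in subgroup_specs],
        "pink_gain": noise.pink_gain,
        "zero_lag_mix_gain": noise.zero_lag_mix_gain,
        "effects": {
            "wm2_shift": effect_config.wm2_shift,
            "wm3_shift": effect_config.wm3_shift,
            "girl_p": list(effect_config.girl_p),
        },
    }
    return Cohort(
        recordings=recordings,
        behavioral=behavioral,
        ground_truth=labels,
        manifest=manifest,
    )
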