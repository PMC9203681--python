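"""Seeded generators for every input the pipeline consumes.

The surrogate EEG is an AR(2) background plus a sinusoidal rhythm and
white noise; the "ictal-like" class adds intermittent high-amplitude spike
bursts, which raises its variance and kurtosis the way seizure activity
does relative to a healthy baseline.  The construction is stationary and
deliberately simple — it produces class-contrasted descriptor tables
without claiming physiological realism.

Also here: direct draws from the fusion-mixture densities and the
zero-inflated Poisson count model (for parameter-recovery tests), and the
standard benchmark objectives used to exercise the swarm optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fhm import FHMParams
from .signal_features import SignalRecord
from .zipmrm import CountResponse, ZIPMRMParams, component_rates, concomitant_weights


@dataclass
class ClassParams:
    """Per-class signal recipe: AR(2) coefficients, one background
    sinusoid (frequency in Hz, amplitude), white-noise SD, and optional
    ictal-like spike bursts.  Bursts are short rhythmic discharges of
    amplitude ``burst_amp`` x the background SD lasting ``burst_len``
    samples; onsets recur quasi-periodically every ``burst_period`` +/-
    ``burst_jitter`` samples, the way spike-wave complexes recur during a
    seizure, so every ictal window contains several while remaining
    intermittent (heavy-tailed, higher kurtosis and variance)."""

    ar: tuple[float, float] = (0.5, -0.3)
    sine_freq: float = 10.0
    sine_amp: float = 1.0
    noise_sd: float = 1.0
    burst_amp: float = 0.0
    burst_len: int = 16
    burst_period: int = 56
    burst_jitter: int = 16


@dataclass
class SyntheticSpec:
    """Study conditions for the two-class surrogate dataset.

    Defaults give 60 segments per class of 256 samples at a Bonn-like
    173.61 Hz; class 1 differs by quasi-periodic ictal spike bursts
    (6 x background-SD, every ~56 samples).
    """

    n_per_class: int = 60
    signal_length: int = 256
    sampling_rate: float = 173.61
    class_params: tuple[ClassParams, ClassParams] = field(
        default_factory=lambda: (
            ClassParams(),
            ClassParams(burst_amp=6.0),
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cp in self.class_params:
            a1, a2 = cp.ar
            # AR(2) stationarity triangle
            if not (abs(a2) < 1 and a2 + a1 < 1 and a2 - a1 < 1):
                raise ValueError(f"non-stationary AR(2) coefficients {cp.ar}")


def _ar2(n: int, a1: float, a2: float, sd: float,
         rng: np.random.Generator) -> np.ndarray:
    burn = 100
    e = rng.normal(0.0, sd, n + burn)
    x = np.zeros(n + burn)
    for t in range(2, n + burn):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
    return x[burn:]


def gen_two_class_signals(spec: SyntheticSpec) -> list[SignalRecord]:
    """Labelled surrogate segments; a pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    records = []
    t = np.arange(spec.signal_length) / spec.sampling_rate
    for label, cp in zip(("0", "1"), spec.class_params):
        for k in range(spec.n_per_class):
            x = _ar2(spec.signal_length, *cp.ar, cp.noise_sd, rng)
            phase = rng.uniform(0, 2 * np.pi)
            x = x + cp.sine_amp * np.sin(2 * np.pi * cp.sine_freq * t + phase)
            if cp.burst_amp > 0:
                polarity = rng.choice((-1.0, 1.0))  # per-segment montage sign
                start = int(rng.integers(0, cp.burst_period))
                while start < spec.signal_length:
                    stop = min(start + cp.burst_len, spec.signal_length)
                    L = stop - start
                    wave = np.sin(2 * np.pi * np.arange(L) / 8.0)
                    env = np.hanning(cp.burst_len)[:L]
                    scale = cp.burst_amp * cp.noise_sd * rng.uniform(0.7, 1.3)
                    x[start:stop] += polarity * scale * wave * env
                    start += int(
                        cp.burst_period
                        + rng.integers(-cp.burst_jitter, cp.burst_jitter + 1)
                    )
            records.append(
                SignalRecord(
                    samples=x,
                    sampling_rate=spec.sampling_rate,
                    channel_id=f"c{label}s{k}",
                    label=label,
                )
            )
    return records


def gen_mixture_sample(
    params: FHMParams, model_class: str, n: int, seed: int | None = 0
) -> np.ndarray:
    """Draw n observations from the fusion mixture: with probability pi
    from the overdispersion part f1, otherwise from the normal bulk f0."""
    rng = np.random.default_rng(seed)
    from_f1 = rng.random(n) < params.pi
    out = np.empty(n)
    # f0: pick a normal component by gamma, then draw
    n0 = int((~from_f1).sum())
    comp = rng.choice(params.Q, size=n0, p=params.gammas)
    out[~from_f1] = rng.normal(params.means[comp], params.sigmas[comp])
    n1 = int(from_f1.sum())
    if n1:
        if model_class in ("NUDGE", "eNUDGE"):
            i, j = params.uniform_bounds
            out[from_f1] = rng.uniform(i, j, n1)
        elif model_class == "GNG":
            left = rng.random(n1) < params.rho
            draws = np.empty(n1)
            draws[left] = -params.xi1 - rng.exponential(params.beta1, int(left.sum()))
            draws[~left] = params.xi2 + rng.exponential(
                params.beta2, int((~left).sum())
            )
            out[from_f1] = draws
        else:
            raise ValueError(f"unknown model class {model_class!r}")
    return out


def gen_zip_counts(
    params: ZIPMRMParams,
    v1: np.ndarray | None = None,
    v2: np.ndarray | None = None,
    n: int | None = None,
    seed: int | None = 0,
) -> tuple[CountResponse, dict]:
    """Draw counts from the ZIP mixture regression.

    Structural zeros occur with probability psi; otherwise a component is
    drawn from the concomitant weights and the count from its Poisson
    rate.  Returns the data plus the ground-truth latent indicators for
    recovery tests.
    """
    rng = np.random.default_rng(seed)
    if n is None:
        if v1 is None and v2 is None:
            raise ValueError("need n or covariates")
        n = np.atleast_2d(v1 if v1 is not None else v2).shape[0]
    v1m = np.zeros((n, params.beta.shape[1])) if v1 is None else np.atleast_2d(v1)
    v2m = np.zeros((n, params.gamma.shape[1])) if v2 is None else np.atleast_2d(v2)
    lam = component_rates(params, v1m)
    piw = concomitant_weights(v2m, params.gamma0, params.gamma)
    structural = rng.random(n) < params.psi
    comp = np.array(
        [rng.choice(params.K, p=piw[i]) for i in range(n)], dtype=int
    )
    u = rng.poisson(lam[np.arange(n), comp])
    u[structural] = 0
    data = CountResponse(
        u=u,
        v1=None if v1 is None else v1m,
        v2=None if v2 is None else v2m,
    )
    return data, {"structural": structural, "component": comp}


# ---------------------------------------------------------------------------
# Benchmark objectives
# ---------------------------------------------------------------------------

def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x)
    return float(
        np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2)
    )


def benchmark_function(
    name: str, dims: int = 10
) -> tuple[Callable[[np.ndarray], float], np.ndarray, float]:
    """Standard test objective: (callable, optimum location, optimum value)."""
    table = {
        "sphere": (_sphere, np.zeros(dims), 0.0),
        "rastrigin": (_rastrigin, np.zeros(dims), 0.0),
        "rosenbrock": (_rosenbrock, np.ones(dims), 0.0),
    }
    if name not in table:
        raise KeyError(f"unknown benchmark {name!r}; options {sorted(table)}")
    return table[name]
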