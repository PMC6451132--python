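"""Synthetic smFRET trace generation for pre-translocation ribosome titrations.

The generator produces donor/acceptor intensity time series whose hidden-state
dynamics follow a three-state (Classical / Hybrid-1 / Hybrid-2) Markov chain.
The stationary classical/hybrid balance at a given drug concentration is set by
the four-species thermodynamic binding model

    f_c = (1 + [I]/K_I) / (1 + K_0 + ([I]/K_I) * (1 + 1/K_2))

where ``K_I`` is the drug dissociation constant and ``K_0``/``K_2`` are the
classical-to-hybrid equilibrium constants on the drug-free and drug-bound
ribosome.  Drug binding is treated as pre-equilibrated; only the conformational
equilibrium is realised kinetically.

All randomness derives from a single master seed through
``numpy.random.SeedSequence`` spawning (one child stream per dataset, one per
trace), so every dataset is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "ConfigurationError",
    "FretState",
    "ConformationalModel",
    "ThermoParams",
    "PhotophysicsParams",
    "TraceTruth",
    "Trace",
    "TraceDataset",
    "yeast_model",
    "human_model",
    "equilibrium_occupancy",
    "stationary_distribution",
    "transition_matrix",
    "simulate_state_path",
    "render_trace",
    "simulate_titration_dataset",
    "save_dataset_csv",
    "load_dataset_csv",
    "save_dataset_hdf5",
    "load_dataset_hdf5",
]

CLASSICAL, HYBRID1, HYBRID2 = 0, 1, 2
STATE_LABELS = ("Classical", "Hybrid1", "Hybrid2")
BLEACHED = -1  # sentinel state index for post-bleach frames


class ParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


class ConfigurationError(ValueError):
    """A simulation/analysis configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretState:
    """One conformational state with its Gaussian FRET signature."""

    label: str
    fret_mean: float
    fret_sd: float

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise ParameterError(f"unknown state label {self.label!r}")
        if not (0.0 <= self.fret_mean <= 1.0):
            raise ParameterError("fret_mean must lie in [0, 1]")
        if self.fret_sd <= 0:
            raise ParameterError("fret_sd must be positive")
        lo = self.fret_mean - 2 * self.fret_sd
        hi = self.fret_mean + 2 * self.fret_sd
        if lo < -0.2 or hi > 1.2:
            raise ParameterError("mean +/- 2 sd must stay within [-0.2, 1.2]")


@dataclass(frozen=True)
class ConformationalModel:
    """Three-state FRET model of a pre-translocation ribosome species.

    ``hybrid_split`` is the fraction of total hybrid occupancy assigned to the
    Hybrid-2 state; the remainder goes to Hybrid-1.
    """

    species_label: str
    states: tuple[FretState, FretState, FretState]
    hybrid_split: float

    def __post_init__(self) -> None:
        if len(self.states) != 3:
            raise ParameterError("exactly three states required")
        labels = tuple(s.label for s in self.states)
        if labels != STATE_LABELS:
            raise ParameterError(
                f"states must be ordered {STATE_LABELS}, got {labels}")
        means = [s.fret_mean for s in self.states]
        if not (means[0] > means[1] > means[2]):
            raise ParameterError(
                "FRET means must strictly decrease from Classical to Hybrid2")
        if not (0.0 <= self.hybrid_split <= 1.0):
            raise ParameterError("hybrid_split must lie in [0, 1]")

    @property
    def means(self) -> np.ndarray:
        return np.array([s.fret_mean for s in self.states])

    @property
    def sds(self) -> np.ndarray:
        return np.array([s.fret_sd for s in self.states])

    def to_dict(self) -> dict:
        return {
            "species_label": self.species_label,
            "states": [
                {"label": s.label, "fret_mean": s.fret_mean, "fret_sd": s.fret_sd}
                for s in self.states
            ],
            "hybrid_split": self.hybrid_split,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConformationalModel":
        states = tuple(
            FretState(s["label"], s["fret_mean"], s["fret_sd"])
            for s in d["states"]
        )
        return cls(d["species_label"], states, d["hybrid_split"])


def yeast_model() -> ConformationalModel:
    """S. cerevisiae pre-translocation FRET states: 0.65/0.40/0.22.

    The yeast complex favours Hybrid-2 over Hybrid-1, so 60% of hybrid
    occupancy is assigned to Hybrid-2.
    """
    return ConformationalModel(
        species_label="yeast",
        states=(
            FretState("Classical", 0.65, 0.04),
            FretState("Hybrid1", 0.40, 0.06),
            FretState("Hybrid2", 0.22, 0.05),
        ),
        hybrid_split=0.6,
    )


def human_model() -> ConformationalModel:
    """Human pre-translocation FRET states: 0.71/0.44/0.26 (favours Hybrid-1)."""
    return ConformationalModel(
        species_label="human",
        states=(
            FretState("Classical", 0.71, 0.05),
            FretState("Hybrid1", 0.44, 0.06),
            FretState("Hybrid2", 0.26, 0.07),
        ),
        hybrid_split=0.4,
    )


@dataclass(frozen=True)
class ThermoParams:
    """Equilibrium constants of the drug-binding model.

    K0, K2 are dimensionless classical-to-hybrid equilibrium constants on the
    drug-free and drug-bound ribosome; KI is the drug dissociation constant in
    the same concentration units as [I] (uM throughout this package).
    """

    K0: float
    K2: float
    KI: float

    def __post_init__(self) -> None:
        if not (self.K0 > 0 and self.K2 > 0 and self.KI > 0):
            raise ParameterError("K0, K2 and KI must all be strictly positive")


@dataclass(frozen=True)
class PhotophysicsParams:
    """Camera/fluorophore model for rendering intensities.

    Defaults describe a typical single-dye-pair TIRF recording at 40 ms frames:
    ~800 detected photons/frame split between channels, additive per-channel
    shot/read noise, an exponential photobleaching lifetime of 12 s and rare
    short donor blinks.
    """

    total_intensity_mean: float = 800.0
    shot_noise_sd: float = 30.0
    background_sd: float = 15.0
    bleach_mean_lifetime: float = 12.0
    blink_rate: float = 0.05
    blink_mean_duration: float = 0.2
    frame_dt: float = 0.040
    n_frames: int = 750

    def __post_init__(self) -> None:
        for name in ("total_intensity_mean", "shot_noise_sd", "background_sd",
                     "bleach_mean_lifetime", "blink_mean_duration", "frame_dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.blink_rate < 0:
            raise ParameterError("blink_rate must be non-negative")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be at least 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "total_intensity_mean", "shot_noise_sd", "background_sd",
            "bleach_mean_lifetime", "blink_rate", "blink_mean_duration",
            "frame_dt", "n_frames")}


@dataclass(frozen=True)
class TraceTruth:
    """Ground-truth annotation of a simulated trace."""

    states: np.ndarray           # per-frame state index, BLEACHED after bleach
    bleach_frame: int | None     # first background-only frame, None if none
    blink_intervals: tuple[tuple[int, int], ...]  # [start, stop) frame ranges


@dataclass(frozen=True)
class Trace:
    donor: np.ndarray
    acceptor: np.ndarray
    frame_dt: float
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        if len(self.donor) != len(self.acceptor):
            raise ParameterError("donor and acceptor must have equal length")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ParameterError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass(frozen=True)
class TraceDataset:
    traces: tuple[Trace, ...]
    concentration: float
    model: ConformationalModel
    seed: int

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ParameterError("concentration must be non-negative")
        dts = {t.frame_dt for t in self.traces}
        if len(dts) > 1:
            raise ParameterError("all traces must share frame_dt")

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def frame_dt(self) -> float:
        return self.traces[0].frame_dt if self.traces else float("nan")


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

def equilibrium_occupancy(thermo: ThermoParams, concentration: float) -> tuple[float, float]:
    """Classical/hybrid occupancy at equilibrium for drug concentration [I].

    Returns ``(f_c, 1 - f_c)`` with

        f_c = (1 + x) / (1 + K0 + x * (1 + 1/K2)),   x = [I] / K_I.

    Equivalent to the four-species partition function over {Classical, Hybrid,
    Classical.I, Hybrid.I} with Boltzmann weights {1, K0, x, x/K2}.
    """
    if concentration < 0:
        raise ParameterError("concentration must be non-negative")
    x = concentration / thermo.KI
    f_c = (1.0 + x) / (1.0 + thermo.K0 + x * (1.0 + 1.0 / thermo.K2))
    return f_c, 1.0 - f_c


def stationary_distribution(
    model: ConformationalModel, thermo: ThermoParams, concentration: float
) -> np.ndarray:
    """Per-microstate stationary probabilities (Classical, Hybrid1, Hybrid2)."""
    f_c, f_h = equilibrium_occupancy(thermo, concentration)
    return np.array([
        f_c,
        f_h * (1.0 - model.hybrid_split),
        f_h * model.hybrid_split,
    ])


def transition_matrix(pi: np.ndarray, frame_dt: float, mean_dwell: float) -> np.ndarray:
    """Row-stochastic per-frame transition matrix with stationary law ``pi``.

    Uses an independence-sampler construction: with probability
    ``c = frame_dt / mean_dwell`` the chain redraws its state from ``pi``,
    otherwise it stays.  This satisfies detailed balance with respect to
    ``pi`` and gives state dwell times of order ``mean_dwell``.
    """
    if mean_dwell < frame_dt:
        raise ConfigurationError("mean_dwell must be at least one frame long")
    c = frame_dt / mean_dwell
    n = len(pi)
    P = c * np.tile(pi, (n, 1))
    P[np.diag_indices(n)] += 1.0 - c
    return P


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_path(
    model: ConformationalModel,
    thermo: ThermoParams,
    concentration: float,
    photo: PhotophysicsParams,
    seed,
    mean_dwell: float = 0.5,
) -> tuple[np.ndarray, int | None]:
    """Simulate a per-frame hidden-state path truncated by photobleaching.

    Returns ``(states, bleach_frame)`` where ``states`` has length
    ``photo.n_frames`` with the sentinel ``BLEACHED`` (-1) from the bleach
    frame on, and ``bleach_frame`` is None when the fluorophores outlive the
    recording.

    The chain redraws its state from the stationary law with per-frame
    probability ``frame_dt / mean_dwell`` (see :func:`transition_matrix`), so
    the long-run state frequencies equal :func:`equilibrium_occupancy` split
    by ``model.hybrid_split``.
    """
    rng = _as_rng(seed)
    pi = stationary_distribution(model, thermo, concentration)
    if mean_dwell < photo.frame_dt:
        raise ConfigurationError("mean_dwell must be at least one frame long")
    c = photo.frame_dt / mean_dwell
    n = photo.n_frames

    # Redraw construction: candidate states iid from pi at every frame; the
    # path holds its value between redraw events (frame 0 always redraws).
    candidates = rng.choice(3, size=n, p=pi)
    redraw = rng.random(n) < c
    redraw[0] = True
    idx = np.where(redraw, np.arange(n), 0)
    np.maximum.accumulate(idx, out=idx)
    states = candidates[idx].astype(np.int8)

    lifetime = rng.exponential(photo.bleach_mean_lifetime)
    bleach = int(lifetime / photo.frame_dt)
    if bleach >= n:
        return states, None
    if bleach < 0:
        bleach = 0
    states[bleach:] = BLEACHED
    return states, bleach


def _draw_blinks(
    rng: np.random.Generator, photo: PhotophysicsParams, n_live: int
) -> tuple[tuple[int, int], ...]:
    """Poisson-process donor blink intervals within the live segment."""
    if photo.blink_rate == 0 or n_live == 0:
        return ()
    span = n_live * photo.frame_dt
    n_events = rng.poisson(photo.blink_rate * span)
    intervals = []
    for _ in range(n_events):
        start = int(rng.random() * n_live)
        dur = max(1, int(round(rng.exponential(photo.blink_mean_duration)
                               / photo.frame_dt)))
        intervals.append((start, min(start + dur, n_live)))
    return tuple(sorted(intervals))


def render_trace(
    path: tuple[np.ndarray, int | None],
    model: ConformationalModel,
    photo: PhotophysicsParams,
    seed,
) -> Trace:
    """Render donor/acceptor intensities from a hidden-state path.

    Per live frame the FRET efficiency is drawn from the state's Gaussian;
    donor = T*(1-E) + noise and acceptor = T*E + noise with constant expected
    total intensity T.  Post-bleach frames and donor-blink intervals carry
    background noise only in both channels.
    """
    rng = _as_rng(seed)
    states, bleach_frame = path
    n = len(states)
    live = states >= 0
    n_live = int(live.sum())

    E = np.zeros(n)
    if n_live:
        s = states[live]
        E[live] = rng.normal(model.means[s], model.sds[s])

    T = photo.total_intensity_mean
    donor = np.where(live, T * (1.0 - E), 0.0)
    acceptor = np.where(live, T * E, 0.0)

    blink_local = _draw_blinks(rng, photo, n_live)
    # Map blink intervals from live-segment-local to absolute frame indices
    # (live frames are the leading block when a bleach occurred).
    blinks = []
    for start, stop in blink_local:
        donor[start:stop] = 0.0
        acceptor[start:stop] = 0.0
        blinks.append((start, stop))

    noise_sd = np.where(live, photo.shot_noise_sd, photo.background_sd)
    for start, stop in blinks:
        noise_sd[start:stop] = photo.background_sd
    donor = donor + rng.normal(0.0, noise_sd)
    acceptor = acceptor + rng.normal(0.0, noise_sd)

    truth = TraceTruth(states=states.copy(), bleach_frame=bleach_frame,
                       blink_intervals=tuple(blinks))
    return Trace(donor=donor, acceptor=acceptor, frame_dt=photo.frame_dt,
                 truth=truth)


def simulate_trace(
    model: ConformationalModel,
    thermo: ThermoParams,
    concentration: float,
    photo: PhotophysicsParams,
    seed,
    mean_dwell: float = 0.5,
) -> Trace:
    """Simulate a single trace (state path + intensity rendering)."""
    rng = _as_rng(seed)
    path = simulate_state_path(model, thermo, concentration, photo, rng,
                               mean_dwell=mean_dwell)
    return render_trace(path, model, photo, rng)


def simulate_titration_dataset(
    model: ConformationalModel,
    thermo: ThermoParams,
    photo: PhotophysicsParams,
    concentrations: Sequence[float],
    n_traces: int,
    seed: int,
    mean_dwell: float = 0.5,
) -> list[TraceDataset]:
    """Simulate one TraceDataset per drug concentration.

    Seeds are spawned deterministically from the master seed: one child
    SeedSequence per concentration, one grandchild per trace.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise ConfigurationError("concentration list must not be empty")
    if any(c < 0 for c in concentrations):
        raise ParameterError("concentrations must be non-negative")
    if len(set(concentrations)) != len(concentrations):
        raise ConfigurationError("concentrations must be distinct")
    if n_traces < 1:
        raise ConfigurationError("n_traces must be at least 1")

    master = np.random.SeedSequence(seed)
    datasets = []
    for conc, child in zip(concentrations, master.spawn(len(concentrations))):
        trace_seeds = child.spawn(n_traces)
        traces = tuple(
            simulate_trace(model, thermo, conc, photo,
                           np.random.default_rng(ts), mean_dwell=mean_dwell)
            for ts in trace_seeds
        )
        datasets.append(TraceDataset(traces=traces, concentration=conc,
                                     model=model, seed=seed))
    return datasets


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _dataset_frame(dataset: TraceDataset) -> pd.DataFrame:
    recs = []
    for i, tr in enumerate(dataset.traces):
        n = len(tr)
        recs.append(pd.DataFrame({
            "trace_id": np.full(n, i, dtype=int),
            "frame": np.arange(n),
            "donor": tr.donor,
            "acceptor": tr.acceptor,
        }))
    return pd.concat(recs, ignore_index=True)


def save_dataset_csv(dataset: TraceDataset, path: str | Path) -> None:
    """Write one row per frame (trace_id, frame, donor, acceptor) plus a JSON
    sidecar <path>.meta.json holding frame_dt, concentration, model and seed."""
    path = Path(path)
    _dataset_frame(dataset).to_csv(path, index=False)
    meta = {
        "frame_dt": dataset.frame_dt,
        "concentration": dataset.concentration,
        "model": dataset.model.to_dict(),
        "seed": dataset.seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset_csv(path: str | Path) -> TraceDataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    traces = []
    for _, sub in df.groupby("trace_id", sort=True):
        sub = sub.sort_values("frame")
        traces.append(Trace(donor=sub["donor"].to_numpy(),
                            acceptor=sub["acceptor"].to_numpy(),
                            frame_dt=meta["frame_dt"]))
    return TraceDataset(traces=tuple(traces),
                        concentration=meta["concentration"],
                        model=ConformationalModel.from_dict(meta["model"]),
                        seed=meta["seed"])


def save_dataset_hdf5(dataset: TraceDataset, path: str | Path) -> None:
    """Compact binary container for large trace sets (truth included)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["frame_dt"] = dataset.frame_dt
        f.attrs["concentration"] = dataset.concentration
        f.attrs["seed"] = dataset.seed
        f.attrs["model"] = json.dumps(dataset.model.to_dict())
        for i, tr in enumerate(dataset.traces):
            g = f.create_group(f"trace_{i:06d}")
            g.create_dataset("donor", data=tr.donor)
            g.create_dataset("acceptor", data=tr.acceptor)
            if tr.truth is not None:
                g.create_dataset("true_states", data=tr.truth.states)
                g.attrs["bleach_frame"] = (
                    -1 if tr.truth.bleach_frame is None else tr.truth.bleach_frame)
                g.create_dataset(
                    "blink_intervals",
                    data=np.array(tr.truth.blink_intervals, dtype=int).reshape(-1, 2))


def load_dataset_hdf5(path: str | Path) -> TraceDataset:
    import h5py

    with h5py.File(path, "r") as f:
        model = ConformationalModel.from_dict(json.loads(f.attrs["model"]))
        frame_dt = float(f.attrs["frame_dt"])
        traces = []
        for key in sorted(f.keys()):
            g = f[key]
            truth = None
            if "true_states" in g:
                bf = int(g.attrs["bleach_frame"])
                truth = TraceTruth(
                    states=g["true_states"][...],
                    bleach_frame=None if bf < 0 else bf,
                    blink_intervals=tuple(map(tuple, g["blink_intervals"][...])),
                )
            traces.append(Trace(donor=g["donor"][...], acceptor=g["acceptor"][...],
                                frame_dt=frame_dt, truth=truth))
        return TraceDataset(traces=tuple(traces),
                            concentration=float(f.attrs["concentration"]),
                            model=model, seed=int(f.attrs["seed"]))
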