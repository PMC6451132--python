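"""Titration analysis: fraction-classical observations and binding-model fits.

The fraction of ribosomes in the Classical state, estimated from idealized
FRET trajectories, is modelled as a function of drug concentration [I] by

    f_c([I]) = (1 + [I]/K_I) / (1 + K_0 + ([I]/K_I) * (1 + 1/K_2))

and fitted by weighted nonlinear least squares with the parameters optimized
on a log scale (positivity by construction) from multiple starting points.
``f_c`` is pooled over frames across traces by default (a per-trace-mean mode
is available) and its standard error is obtained by bootstrapping traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic_data import (
    ConfigurationError,
    ConformationalModel,
    PhotophysicsParams,
    ThermoParams,
    TraceDataset,
    equilibrium_occupancy,
    simulate_titration_dataset,
)
from . import idealization, trace_qc

__all__ = [
    "TitrationPoint",
    "FitResult",
    "fraction_classical",
    "predict_fraction_classical",
    "fit_titration",
    "population_histogram",
    "idealize_dataset",
    "titration_curve",
    "recover_titration",
]


@dataclass(frozen=True)
class TitrationPoint:
    concentration: float     # uM
    fraction_classical: float
    sem: float
    n_traces: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_classical <= 1.0):
            raise ValueError("fraction_classical must lie in [0, 1]")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class FitResult:
    thermo: ThermoParams
    stderr: dict            # per-parameter standard errors (linear scale)
    rss: float              # (weighted) residual sum of squares
    converged: bool
    n_points: int
    weakly_identified: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.rss):
            raise ValueError("residual sum of squares must be finite")


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def fraction_classical(
    paths: list[idealization.IdealizedPath],
    concentration: float,
    classical_state: int = 0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    pooled: bool = True,
) -> TitrationPoint:
    """Fraction of idealized frames assigned to the Classical state.

    Pools frames across traces (default) or averages per-trace fractions;
    the SEM comes from a seeded bootstrap over traces.
    """
    if not paths:
        raise ValueError("no idealized traces")
    counts = np.array([
        (int(np.sum(p.states == classical_state)), len(p.states)) for p in paths
    ], dtype=float)
    total = counts[:, 1].sum()
    if total == 0:
        raise ValueError("zero assigned frames; fraction undefined")

    if pooled:
        fc = counts[:, 0].sum() / total
    else:
        fc = float(np.mean(counts[:, 0] / np.maximum(counts[:, 1], 1)))

    n = len(paths)
    if n == 1:
        sem = 0.0
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boot = counts[idx]  # (B, n, 2)
        if pooled:
            fcs = boot[:, :, 0].sum(axis=1) / np.maximum(boot[:, :, 1].sum(axis=1), 1)
        else:
            fcs = np.mean(boot[:, :, 0] / np.maximum(boot[:, :, 1], 1), axis=1)
        sem = float(np.std(fcs))
    return TitrationPoint(concentration=concentration,
                          fraction_classical=float(np.clip(fc, 0.0, 1.0)),
                          sem=sem, n_traces=n)


def predict_fraction_classical(thermo: ThermoParams, concentration: float) -> float:
    """Model-predicted f_c; the classical component of the binding equilibrium."""
    return equilibrium_occupancy(thermo, concentration)[0]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _model_fc(log_params: np.ndarray, conc: np.ndarray) -> np.ndarray:
    K0, K2, KI = np.exp(log_params)
    x = conc / KI
    return (1.0 + x) / (1.0 + K0 + x * (1.0 + 1.0 / K2))


def fit_titration(points: list[TitrationPoint], use_weights: bool = True) -> FitResult:
    """Weighted least-squares fit of the binding model to titration points.

    Weights are 1/sem^2 (unweighted fallback when any sem is zero).
    Parameters are optimized as log(K0, K2, KI) from a multi-start grid; the
    reported standard errors come from the local curvature at the optimum
    (delta method back to the linear scale).  K2 (and any other parameter)
    is flagged as weakly identified when its relative standard error
    exceeds 1.
    """
    if len(points) < 4:
        raise ConfigurationError("need at least 4 titration points")
    conc = np.array([p.concentration for p in points], dtype=float)
    fc = np.array([p.fraction_classical for p in points], dtype=float)
    sems = np.array([p.sem for p in points], dtype=float)
    if 0.0 not in conc:
        raise ConfigurationError("titration must include a drug-free point")
    pos = conc[conc > 0]
    if len(pos) == 0 or pos.max() / pos.min() < 10:
        raise ConfigurationError(
            "positive concentrations must span at least one decade")

    if use_weights and np.all(sems > 0):
        w = 1.0 / sems**2
    else:
        w = np.ones_like(sems)
    sqrt_w = np.sqrt(w)

    def residuals(log_params):
        return sqrt_w * (fc - _model_fc(log_params, conc))

    # multi-start: K0 from the drug-free point, KI across the measured
    # concentration range, K2 over a coarse grid
    f0 = float(np.clip(fc[conc == 0][0], 1e-3, 1 - 1e-3))
    k0_starts = [max((1.0 - f0) / f0, 1e-2)]
    ki_starts = np.geomspace(pos.min() / 3.0, pos.max() * 3.0, 6)
    k2_starts = [3.0, 10.0, 30.0]

    best = None
    for k0 in k0_starts:
        for k2 in k2_starts:
            for ki in ki_starts:
                res = least_squares(residuals, np.log([k0, k2, ki]),
                                    bounds=(-23.0, 23.0), max_nfev=2000)
                if best is None or res.cost < best.cost:
                    best = res
    assert best is not None

    log_opt = best.x
    K0, K2, KI = np.exp(log_opt)
    rss = float(np.sum(best.fun**2))

    n, p = len(points), 3
    stderr = {"K0": np.inf, "K2": np.inf, "KI": np.inf}
    if n > p:
        s2 = rss / (n - p)
        JtJ = best.jac.T @ best.jac
        try:
            cov_log = s2 * np.linalg.inv(JtJ)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
            stderr = {"K0": float(K0 * se_log[0]),
                      "K2": float(K2 * se_log[1]),
                      "KI": float(KI * se_log[2])}
        except np.linalg.LinAlgError:
            pass

    weak = tuple(
        name for name, val in (("K0", K0), ("K2", K2), ("KI", KI))
        if not np.isfinite(stderr[name]) or stderr[name] / val > 1.0
    )
    return FitResult(thermo=ThermoParams(K0=float(K0), K2=float(K2), KI=float(KI)),
                     stderr=stderr, rss=rss,
                     converged=bool(best.status > 0), n_points=n,
                     weakly_identified=weak)


def fit_titration_shared_k0(
    points_by_drug: dict, use_weights: bool = True
) -> dict:
    """Joint fit of several titrations sharing one K_0 within a species.

    ``points_by_drug`` maps a drug label to its list of TitrationPoint.
    K_0 is common; each drug gets its own K_2 and K_I.  Returns a dict of
    per-drug FitResult (all carrying the shared K_0) keyed like the input.
    """
    labels = list(points_by_drug)
    if not labels:
        raise ConfigurationError("no titrations supplied")
    singles = {lab: fit_titration(points_by_drug[lab], use_weights)
               for lab in labels}

    conc, fc, sqw, drug_idx = [], [], [], []
    for d, lab in enumerate(labels):
        for p in points_by_drug[lab]:
            conc.append(p.concentration)
            fc.append(p.fraction_classical)
            sqw.append(1.0 / p.sem if (use_weights and p.sem > 0) else 1.0)
            drug_idx.append(d)
    conc = np.array(conc)
    fc = np.array(fc)
    sqw = np.array(sqw)
    if use_weights and np.any(np.array([p.sem for pts in points_by_drug.values()
                                        for p in pts]) == 0):
        sqw = np.ones_like(sqw)
    drug_idx = np.array(drug_idx)
    D = len(labels)

    def residuals(theta):
        k0 = np.exp(theta[0])
        k2 = np.exp(theta[1:1 + D])[drug_idx]
        ki = np.exp(theta[1 + D:])[drug_idx]
        x = conc / ki
        pred = (1.0 + x) / (1.0 + k0 + x * (1.0 + 1.0 / k2))
        return sqw * (fc - pred)

    x0 = np.concatenate([
        [np.log(np.mean([singles[lab].thermo.K0 for lab in labels]))],
        [np.log(singles[lab].thermo.K2) for lab in labels],
        [np.log(singles[lab].thermo.KI) for lab in labels]])
    res = least_squares(residuals, x0, bounds=(-23.0, 23.0), max_nfev=5000)
    k0 = float(np.exp(res.x[0]))
    out = {}
    for d, lab in enumerate(labels):
        k2 = float(np.exp(res.x[1 + d]))
        ki = float(np.exp(res.x[1 + D + d]))
        out[lab] = FitResult(
            thermo=ThermoParams(K0=k0, K2=k2, KI=ki),
            stderr={"K0": np.nan, "K2": np.nan, "KI": np.nan},
            rss=float(np.sum(res.fun**2)),
            converged=bool(res.status > 0),
            n_points=len(points_by_drug[lab]))
    return out


def bootstrap_ci(
    points: list[TitrationPoint],
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Parametric bootstrap confidence intervals for the fitted constants.

    Resamples each point's f_c from N(f_c, sem), refits, and returns
    percentile intervals {"K0": (lo, hi), "K2": ..., "KI": ...}.
    """
    rng = np.random.default_rng(seed)
    draws = {"K0": [], "K2": [], "KI": []}
    for _ in range(n_boot):
        pts = [TitrationPoint(p.concentration,
                              float(np.clip(rng.normal(p.fraction_classical,
                                                       max(p.sem, 1e-6)),
                                            0.0, 1.0)),
                              p.sem, p.n_traces) for p in points]
        try:
            r = fit_titration(pts)
        except (ConfigurationError, ValueError):
            continue
        draws["K0"].append(r.thermo.K0)
        draws["K2"].append(r.thermo.K2)
        draws["KI"].append(r.thermo.KI)
    alpha = 100 * (1.0 - level) / 2.0
    return {k: tuple(np.percentile(v, [alpha, 100 - alpha]))
            for k, v in draws.items() if v}


# ---------------------------------------------------------------------------
# Population histograms
# ---------------------------------------------------------------------------

def population_histogram(
    fret_series_collection: list[np.ndarray],
    bin_width: float = 0.02,
    lo: float = -0.1,
    hi: float = 1.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area FRET occupancy histogram pooled over traces.

    Returns ``(bin_edges, density)`` on [lo, hi]; NaN-masked frames are
    dropped.  Per-concentration histograms from a titration stack directly
    into the usual contour/ridge panels.
    """
    if not fret_series_collection:
        raise ValueError("no FRET series supplied")
    pooled = np.concatenate([np.asarray(s, dtype=float).ravel()
                             for s in fret_series_collection])
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError("no unmasked frames to histogram")
    n_bins = int(round((hi - lo) / bin_width))
    density, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi),
                                  density=True)
    return edges, density


# ---------------------------------------------------------------------------
# Plotting hooks
# ---------------------------------------------------------------------------

def plot_titration(points, fit: FitResult | None = None, ax=None, **kwargs):
    """Isotherm overlay: f_c observations with the fitted binding curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    conc = np.array([p.concentration for p in points])
    fc = np.array([p.fraction_classical for p in points])
    sem = np.array([p.sem for p in points])
    ax.errorbar(conc, fc, yerr=sem, fmt="o", **kwargs)
    if fit is not None:
        floor = max(conc[conc > 0].min() / 10, 1e-3) if np.any(conc > 0) else 1e-3
        grid = np.concatenate([[0.0], np.geomspace(floor, conc.max() * 3, 200)])
        ax.plot(grid, [predict_fraction_classical(fit.thermo, c) for c in grid])
    ax.set_xscale("symlog", linthresh=max(conc[conc > 0].min(), 1e-3)
                  if np.any(conc > 0) else 1.0)
    ax.set_xlabel("drug concentration (uM)")
    ax.set_ylabel("fraction classical")
    return ax


def plot_histogram_panels(series_by_concentration: dict, bin_width=0.02, axes=None):
    """Stacked population-FRET histogram panels, one per concentration."""
    import matplotlib.pyplot as plt

    concs = sorted(series_by_concentration)
    if axes is None:
        _, axes = plt.subplots(len(concs), 1, sharex=True,
                               figsize=(4, 1.2 * len(concs)))
        axes = np.atleast_1d(axes)
    for ax, c in zip(axes, concs):
        edges, density = population_histogram(series_by_concentration[c],
                                              bin_width=bin_width)
        ax.stairs(density, edges, fill=True)
        ax.set_ylabel(f"{c:g} uM", rotation=0, ha="right")
    axes[-1].set_xlabel("FRET efficiency")
    return axes


# ---------------------------------------------------------------------------
# Pipeline: dataset -> QC -> HMM -> titration point -> fit
# ---------------------------------------------------------------------------

def idealize_dataset(
    dataset: TraceDataset,
    spec: idealization.HMMSpec | None = None,
    criteria: trace_qc.QCCriteria | None = None,
    apply_quality_control: bool = True,
) -> tuple[list[idealization.IdealizedPath], idealization.GaussianHMM]:
    """QC-filter a dataset, fit a shared HMM and idealize every survivor.

    The pre-bleach segment of each trace comes from photobleach detection
    (never from simulation ground truth).  The default HMM spec fixes the
    emission parameters at the dataset's species model.
    """
    if spec is None:
        spec = idealization.HMMSpec.for_model(dataset.model)
    if apply_quality_control:
        filtered, report = trace_qc.apply_qc(dataset, criteria)
        bleach = report.loc[report["passed"], "bleach_frame"].to_numpy()
    else:
        filtered = dataset
        bleach = [None] * len(dataset)
    if len(filtered) == 0:
        raise ValueError("no traces survived QC")

    series = [
        idealization.compute_fret(
            tr, bleach_frame=int(b) if b is not None else "auto")
        for tr, b in zip(filtered.traces, bleach)
    ]
    hmm = idealization.fit_hmm(series, spec)
    paths = idealization.idealize_many(series, hmm)
    return paths, hmm


def titration_curve(
    datasets: list[TraceDataset],
    spec: idealization.HMMSpec | None = None,
    criteria: trace_qc.QCCriteria | None = None,
    classical_state: int = 0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[TitrationPoint]:
    """Per-concentration fraction-classical observations from raw datasets."""
    points = []
    for i, ds in enumerate(datasets):
        paths, _ = idealize_dataset(ds, spec=spec, criteria=criteria)
        points.append(fraction_classical(
            paths, ds.concentration, classical_state=classical_state,
            n_bootstrap=n_bootstrap, seed=seed + i))
    return points


def recover_titration(
    model: ConformationalModel,
    thermo: ThermoParams,
    photo: PhotophysicsParams,
    concentrations: list[float],
    n_traces: int,
    seed: int,
    spec: idealization.HMMSpec | None = None,
    criteria: trace_qc.QCCriteria | None = None,
) -> FitResult:
    """Simulate a titration and run the full analysis pipeline on it.

    simulate -> trace QC -> shared-HMM idealization per concentration ->
    pooled fraction classical -> weighted binding-model fit.  Used for
    parameter-recovery studies with the published dissociation constants as
    generating truth.
    """
    datasets = simulate_titration_dataset(
        model, thermo, photo, concentrations, n_traces, seed)
    points = titration_curve(datasets, spec=spec, criteria=criteria, seed=seed)
    return fit_titration(points)
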