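"""ThT aggregation-kinetics fitting.

Thioflavin T fluorescence time courses are fitted to the logistic growth
model

    F(t) = F0 + (Fmax - F0) / (1 + exp[-k (t - t_half)])

where F0 is the pre-aggregation baseline, Fmax the post-aggregation
plateau, k the apparent growth rate (per minute) and t_half the half-time.
The lag time is t_half - 2/k, the standard tangent-intersection onset
estimate for sigmoidal ThT kinetics.  Parameter uncertainties come from a
seeded residual-resampling bootstrap on the replicate-mean trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ParameterError

_PARAM_NAMES = ("F0", "Fmax", "k", "t_half")


@dataclass
class KineticsDataset:
    """Replicate fluorescence traces at one condition; time in minutes."""

    time: np.ndarray                 # strictly increasing, minutes
    replicates: np.ndarray           # (n_replicates, n_time), arbitrary units
    condition: str = ""
    ratio: float | None = None       # ligand:protein molar ratio if known

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time vector must be strictly increasing")
        if self.replicates.shape[1] != self.time.size:
            raise ParameterError("trace length differs from time vector")

    def mean_trace(self) -> np.ndarray:
        return self.replicates.mean(axis=0)

    def sem_trace(self) -> np.ndarray:
        n = self.replicates.shape[0]
        if n < 2:
            return np.zeros(self.time.size)
        return self.replicates.std(axis=0, ddof=1) / np.sqrt(n)


@dataclass
class LogisticFitResult:
    condition: str
    ratio: float | None
    fit_flag: str                      # ok | no_aggregation | poor_fit
    F0: float | None = None
    Fmax: float | None = None
    k: float | None = None             # per minute
    t_half: float | None = None        # minutes
    lag: float | None = None           # minutes, t_half - 2/k
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    rss: float | None = None


def logistic(t: np.ndarray, f0: float, fmax: float, k: float, t_half: float) -> np.ndarray:
    return f0 + (fmax - f0) / (1.0 + np.exp(-k * (t - t_half)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    f0, fmax = float(y.min()), float(y.max())
    rise = fmax - f0
    frac = (y - f0) / rise if rise > 0 else np.zeros_like(y)
    t_half = float(np.interp(0.5, _monotone(frac), t))
    t10 = float(np.interp(0.1, _monotone(frac), t))
    t90 = float(np.interp(0.9, _monotone(frac), t))
    k = 4.0 / (t90 - t10) if t90 > t10 else 4.0 / (t[-1] - t[0])
    return np.array([f0, fmax, k, t_half])


def _monotone(frac: np.ndarray) -> np.ndarray:
    # np.interp needs a non-decreasing abscissa
    return np.maximum.accumulate(frac)


def _baseline_noise_sd(t: np.ndarray, y: np.ndarray) -> float:
    n = max(5, y.size // 10)
    base = y[:n]
    # detrend so a sloping baseline does not inflate the noise estimate
    coef = np.polyfit(t[:n], base, 1)
    return float(np.std(base - np.polyval(coef, t[:n])))


def _bounded_fit(t: np.ndarray, y: np.ndarray, p0: np.ndarray) -> np.ndarray:
    span = t[-1] - t[0]
    rise = max(y.max() - y.min(), 1e-12)
    lower = [y.min() - rise, y.min() - rise, 1e-9, t[0] - 0.5 * span]
    upper = [y.max() + rise, y.max() + rise, np.inf, t[-1] + 0.5 * span]
    p0 = np.clip(p0, lower, upper)
    popt, _ = curve_fit(logistic, t, y, p0=p0, bounds=(lower, upper), maxfev=2000)
    return popt


def fit_logistic(
    dataset: KineticsDataset,
    n_boot: int = 1000,
    seed: int = 0,
    no_aggregation_factor: float = 5.0,
) -> LogisticFitResult:
    """Fit the logistic model to the replicate-mean trace of one condition.

    Traces whose total rise does not exceed ``no_aggregation_factor`` times
    the baseline noise SD are flagged ``no_aggregation`` and not fitted.
    Bootstrap confidence intervals (2.5/97.5 percentiles) are obtained by
    residual resampling around the fitted curve with a fixed seed; the lag
    time is propagated through each bootstrap replicate.
    """
    t = dataset.time
    if t.size < 8:
        raise ParameterError("need at least 8 time points to fit")
    y = dataset.mean_trace()
    noise = _baseline_noise_sd(t, y)
    rise = float(np.mean(y[-3:]) - np.mean(y[:3]))
    if rise <= no_aggregation_factor * noise:
        return LogisticFitResult(dataset.condition, dataset.ratio, "no_aggregation",
                                 n_boot=0, seed=seed)

    try:
        popt = _bounded_fit(t, y, _initial_guess(t, y))
    except (RuntimeError, ValueError):
        return LogisticFitResult(dataset.condition, dataset.ratio, "poor_fit",
                                 n_boot=0, seed=seed)
    f0, fmax, k, t_half = popt
    if fmax < f0:
        return LogisticFitResult(dataset.condition, dataset.ratio, "poor_fit",
                                 n_boot=0, seed=seed)
    yfit = logistic(t, *popt)
    residuals = y - yfit
    rss = float((residuals ** 2).sum())

    rng = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    for _ in range(n_boot):
        y_star = yfit + rng.choice(residuals, size=residuals.size, replace=True)
        try:
            samples.append(_bounded_fit(t, y_star, popt))
        except (RuntimeError, ValueError):
            continue
    ci: dict[str, tuple[float, float]] = {}
    if samples:
        arr = np.asarray(samples)
        lags = arr[:, 3] - 2.0 / arr[:, 2]
        stacked = np.column_stack([arr, lags])
        for name, col in zip((*_PARAM_NAMES, "lag"), stacked.T):
            lo, hi = np.percentile(col, [2.5, 97.5])
            ci[name] = (float(lo), float(hi))

    return LogisticFitResult(
        condition=dataset.condition, ratio=dataset.ratio, fit_flag="ok",
        F0=float(f0), Fmax=float(fmax), k=float(k), t_half=float(t_half),
        lag=float(t_half - 2.0 / k), ci=ci, n_boot=len(samples), seed=seed,
        rss=rss,
    )


def dose_response_summary(results: list[LogisticFitResult]) -> pd.DataFrame:
    """Tidy Fmax / t_half / lag table across ligand ratios, with CIs."""
    if not results:
        raise ParameterError("no fit results given")
    rows = []
    for r in results:
        row: dict = {"condition": r.condition, "ratio": r.ratio, "fit_flag": r.fit_flag}
        for name in ("F0", "Fmax", "k", "t_half", "lag"):
            row[name] = getattr(r, name if name != "t_half" else "t_half")
        for name, (lo, hi) in r.ci.items():
            row[f"{name}_lo"] = lo
            row[f"{name}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def read_kinetics_csv(path) -> list[KineticsDataset]:
    """Read a long-format plate table: time_min, value, replicate, condition.

    An optional ``ratio`` column attaches the numeric ligand:protein ratio.
    Returns one dataset per condition, in file order of first appearance.
    """
    df = pd.read_csv(path)
    required = {"time_min", "value", "replicate", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"kinetics CSV missing columns: {sorted(missing)}")
    datasets = []
    for cond in df["condition"].drop_duplicates():
        sub = df[df["condition"] == cond]
        times = np.sort(sub["time_min"].unique())
        reps = []
        for rep in sorted(sub["replicate"].unique()):
            r = sub[sub["replicate"] == rep].sort_values("time_min")
            if not np.array_equal(r["time_min"].to_numpy(), times):
                raise ParameterError(f"replicate {rep} of {cond} has a different time grid")
            reps.append(r["value"].to_numpy())
        ratio = float(sub["ratio"].iloc[0]) if "ratio" in sub.columns else None
        datasets.append(KineticsDataset(times, np.array(reps), str(cond), ratio))
    return datasets
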