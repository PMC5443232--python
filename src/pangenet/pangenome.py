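"""Core/pan-genome rarefaction and saturation-curve fitting.

Genomes are added to the analysis in random order; at each step the core
genome is the set of gene families present in *all* genomes sampled so far
and the pangenome is the set present in at least one.  Averaging over many
random orderings (10 by default) gives the familiar core-decay and
pan-growth curves, which are then summarised by regression:

* core decay  : ``F_c(n) = kappa * exp(-n / tau) + omega`` — ``omega`` is the
  asymptotic (stable) core size in gene families, ``tau`` the decay constant
  in genomes;
* pan growth  : Heaps' law ``F_p(n) = K * n**gamma`` (``gamma`` > 0 signals an
  open pangenome) or an exponential-plus-linear alternative
  ``kappa * exp(-n / tau) + tg * n + C``.

Fits are nonlinear least squares on the per-step *means* across orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class RarefactionSamples:
    """Core/pan sizes for each random genome ordering.

    ``core_sizes`` and ``pan_sizes`` are (n_permutations x G) integer arrays;
    column ``n-1`` holds the size after the n-th genome was added.
    """

    n_genomes_axis: np.ndarray
    core_sizes: np.ndarray
    pan_sizes: np.ndarray
    n_permutations: int
    seed: int | None

    def mean_core(self) -> np.ndarray:
        return self.core_sizes.mean(axis=0)

    def mean_pan(self) -> np.ndarray:
        return self.pan_sizes.mean(axis=0)

    def validate(self) -> None:
        if np.any(np.diff(self.core_sizes, axis=1) > 0):
            raise AssertionError("core sizes must be non-increasing along each permutation")
        if np.any(np.diff(self.pan_sizes, axis=1) < 0):
            raise AssertionError("pan sizes must be non-decreasing along each permutation")


@dataclass
class CurveFit:
    model: str
    params: dict[str, float]
    rss: float


def rarefy(matrix, n_permutations: int = 10, seed: int | None = None) -> RarefactionSamples:
    """Random-addition rarefaction of a presence/absence matrix.

    ``matrix`` is a families x genomes 0/1 DataFrame (or array).  For each of
    ``n_permutations`` random genome orderings, the core and pan sizes are
    recorded after each addition.
    """
    values = np.asarray(matrix, dtype=bool)
    n_families, n_genomes = values.shape
    if n_genomes < 2:
        raise ValueError("rarefaction needs at least two genomes")
    rng = np.random.default_rng(seed)
    core = np.empty((n_permutations, n_genomes), dtype=int)
    pan = np.empty((n_permutations, n_genomes), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        present = values[:, order]
        core[p] = np.logical_and.accumulate(present, axis=1).sum(axis=0)
        pan[p] = np.logical_or.accumulate(present, axis=1).sum(axis=0)
    samples = RarefactionSamples(
        np.arange(1, n_genomes + 1), core, pan, n_permutations, seed)
    samples.validate()
    return samples


def _core_model(n, kappa, tau, omega):
    return kappa * np.exp(-n / tau) + omega


def fit_core_decay(samples: RarefactionSamples) -> CurveFit:
    """Fit the exponential core-decay curve to mean core sizes."""
    n = samples.n_genomes_axis.astype(float)
    y = samples.mean_core()
    if len(np.unique(n)) < 3:
        raise ValueError("core fit needs at least three genome counts")
    if np.ptp(y) == 0:
        return CurveFit("core_exponential", {"kappa": 0.0, "tau": 1.0, "omega": float(y[0])}, 0.0)
    omega0 = float(y[-1])
    kappa0 = max(float(y[0] - omega0), 1e-6)
    tau0 = max(len(n) / 3.0, 1.0)
    try:
        popt, _ = curve_fit(
            _core_model, n, y, p0=[kappa0, tau0, omega0],
            bounds=([0, 1e-9, 0], [np.inf, np.inf, np.inf]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"core-decay fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _core_model(n, *popt)) ** 2))
    return CurveFit("core_exponential", dict(zip(("kappa", "tau", "omega"), map(float, popt))), rss)


def _heaps_model(n, big_k, gamma):
    return big_k * np.power(n, gamma)


def _exp_linear_model(n, kappa, tau, tg, c):
    return kappa * np.exp(-n / tau) + tg * n + c


def fit_pan_growth(samples: RarefactionSamples, model: str = "heaps_power") -> CurveFit:
    """Fit the pangenome growth curve to mean pan sizes."""
    n = samples.n_genomes_axis.astype(float)
    y = samples.mean_pan()
    if len(np.unique(n)) < 3:
        raise ValueError("pan fit needs at least three genome counts")
    if model == "heaps_power":
        # log-log start values; gamma ~ 0 handled by the optimizer
        slope, intercept = np.polyfit(np.log(n), np.log(np.maximum(y, 1e-9)), 1)
        popt, _ = curve_fit(
            _heaps_model, n, y, p0=[np.exp(intercept), slope], maxfev=20000)
        params = {"K": float(popt[0]), "gamma": float(popt[1])}
        rss = float(np.sum((y - _heaps_model(n, *popt)) ** 2))
        return CurveFit("heaps_power", params, rss)
    if model == "exponential_linear":
        tg0 = max(float((y[-1] - y[0]) / (n[-1] - n[0])), 0.0)
        p0 = [max(float(y[0]), 1.0), max(len(n) / 3.0, 1.0), tg0, float(y[0])]
        popt, _ = curve_fit(_exp_linear_model, n, y, p0=p0, maxfev=20000)
        params = dict(zip(("kappa", "tau", "tg", "C"), map(float, popt)))
        rss = float(np.sum((y - _exp_linear_model(n, *popt)) ** 2))
        return CurveFit("pan_exponential_linear", params, rss)
    raise ValueError(f"unknown pan model: {model!r}")
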