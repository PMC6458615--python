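"""Pan/core-genome accumulation curves and openness models.

Pan-genome growth is modeled by Heap's law, P(n) = kappa * n^gamma: on a
log-log scale this is a straight line, and gamma > 0 classifies the
pan-genome as open (it keeps growing as genomes are added).  Core-genome
shrinkage is modeled by a single exponential decay C(n) = Omega +
A * exp(-n / tau), whose asymptote Omega predicts the minimum core size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def presence_matrix(
    counts: dict[str, dict[str, int]], genomes: list[str] | None = None
) -> pd.DataFrame:
    """Family-by-genome copy-count matrix from nested dicts."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    if genomes is not None:
        for g in genomes:
            if g not in df.columns:
                df[g] = 0
        df = df[list(genomes)]
    return df.sort_index()


@dataclass
class AccumulationCurve:
    n: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "pan_mean": self.pan_mean,
                "pan_sd": self.pan_sd,
                "core_mean": self.core_mean,
                "core_sd": self.core_sd,
            }
        )


@dataclass
class HeapsFit:
    kappa: float
    gamma: float
    r2: float

    @property
    def open_pangenome(self) -> bool:
        return self.gamma > 0


@dataclass
class CoreDecayFit:
    amplitude: float  # A
    tau: float
    omega: float  # predicted minimum core size

    def predict(self, n: np.ndarray) -> np.ndarray:
        return self.omega + self.amplitude * np.exp(-np.asarray(n, float) / self.tau)


def accumulation_curves(
    matrix: pd.DataFrame, n_permutations: int = 100, seed: int = 0
) -> AccumulationCurve:
    """Permutation pan/core accumulation curves.

    For each random genome ordering, pan(n) counts families present in at
    least one of the first n genomes and core(n) counts families present in
    all of them; means and standard deviations are taken over orderings.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] < 2:
        raise ValueError("presence matrix needs >= 1 family and >= 2 genomes")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    present = matrix.to_numpy() >= 1  # families x genomes
    n_genomes = present.shape[1]
    pans = np.empty((n_permutations, n_genomes), dtype=float)
    cores = np.empty((n_permutations, n_genomes), dtype=float)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        cum_any = np.logical_or.accumulate(present[:, order], axis=1)
        cum_all = np.logical_and.accumulate(present[:, order], axis=1)
        pans[p] = cum_any.sum(axis=0)
        cores[p] = cum_all.sum(axis=0)
    return AccumulationCurve(
        n=np.arange(1, n_genomes + 1),
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0),
        n_permutations=n_permutations,
        seed=seed,
    )


def fit_heaps(curve: AccumulationCurve) -> HeapsFit:
    """Least-squares fit of log pan_mean = log kappa + gamma * log n."""
    if len(curve.n) < 3:
        raise ValueError("Heap's fit needs >= 3 curve points")
    if np.any(curve.pan_mean <= 0):
        raise ValueError("pan_mean must be strictly positive")
    x = np.log(curve.n.astype(float))
    y = np.log(curve.pan_mean)
    gamma, log_kappa = np.polyfit(x, y, 1)
    resid = y - (log_kappa + gamma * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return HeapsFit(kappa=float(np.exp(log_kappa)), gamma=float(gamma), r2=r2)


def fit_core_decay(curve: AccumulationCurve) -> CoreDecayFit:
    """Nonlinear least squares of C(n) = Omega + A * exp(-n / tau).

    Multi-start over tau in {1, 3, 10} with Omega_0 = min core_mean and
    A_0 = core_mean(1) - Omega_0; returns the lowest-loss converged fit.
    """
    n = curve.n.astype(float)
    c = curve.core_mean.astype(float)
    if len(n) < 3:
        raise ValueError("core decay fit needs >= 3 curve points")

    def model(x, amp, tau, omega):
        return omega + amp * np.exp(-x / tau)

    omega0 = float(c.min())
    a0 = max(float(c[0] - omega0), 1e-6)
    best: tuple[float, CoreDecayFit] | None = None
    failures: list[str] = []
    for tau0 in (1.0, 3.0, 10.0):
        try:
            popt, _ = curve_fit(
                model,
                n,
                c,
                p0=(a0, tau0, omega0),
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # no convergence from this start
            failures.append(f"tau0={tau0}: {exc}")
            continue
        loss = float(np.sum((model(n, *popt) - c) ** 2))
        fit = CoreDecayFit(amplitude=float(popt[0]), tau=float(popt[1]), omega=float(popt[2]))
        if best is None or loss < best[0]:
            best = (loss, fit)
    if best is None:
        raise RuntimeError("core decay fit failed from all starts: " + "; ".join(failures))
    return best[1]


def singleton_stats(matrix: pd.DataFrame) -> tuple[int, float]:
    """(number of families present in exactly one genome, fraction of pan)."""
    if matrix.shape[0] == 0:
        raise ValueError("presence matrix is empty")
    present = matrix.to_numpy() >= 1
    n_singleton = int((present.sum(axis=1) == 1).sum())
    return n_singleton, n_singleton / matrix.shape[0]


def pan_core_sizes(matrix: pd.DataFrame) -> tuple[int, int]:
    """(pan = total families with >=1 genome, core = families in all genomes)."""
    present = matrix.to_numpy() >= 1
    return int((present.any(axis=1)).sum()), int(present.all(axis=1).sum())
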