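"""Fluorescence-anisotropy titrations: K_d fitting and energy conversions.

A titration measures anisotropy of a labelled DNA probe (held at a fixed,
low concentration; 5 nM by default) across a range of protein
concentrations.  Under the single-site model the expected anisotropy is

    A([P]) = A_free + (A_bound - A_free) * [P] / (K_d + [P])

Binding free energy uses the dissociation convention
ΔG_dissociation = −RT ln K_d (K_d in molar), so larger ΔG means tighter
binding.  A ligand-depletion-corrected variant (quadratic occupancy with
the probe concentration) is available behind ``depletion=True`` for probes
not far below K_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .genotype_space import ProteinGenotype, REGenotype

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "TitrationCurve",
    "BindingEstimate",
    "ReplicateSummary",
    "SingleSiteBinding",
    "fit_single_site",
    "kd_to_dg",
    "dg_to_kd",
    "aggregate_replicates",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_PROBE_CONC_M = 5e-9


class InsufficientDataError(ValueError):
    """Too few usable titration points to fit the binding model."""


@dataclass(frozen=True)
class TitrationCurve:
    """One replicate titration of one TF:RE pair."""

    protein: ProteinGenotype
    probe: REGenotype
    replicate: int
    concentrations_M: tuple[float, ...]
    anisotropy: tuple[float, ...]
    probe_conc_M: float = DEFAULT_PROBE_CONC_M

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations_M, dtype=float)
        if conc.size != len(self.anisotropy):
            raise ValueError("concentration/anisotropy length mismatch")
        if conc.size < 5:
            raise InsufficientDataError("a titration needs at least 5 points")
        if np.any(conc <= 0):
            raise ValueError("protein concentrations must be strictly positive")


@dataclass(frozen=True)
class BindingEstimate:
    """Fitted single-site binding parameters for one titration."""

    Kd_M: float
    dG_kcal_mol: float
    baseline: float
    plateau: float
    rss: float
    converged: bool
    in_range: bool
    temperature_K: float = DEFAULT_TEMPERATURE_K

    @property
    def K1_per_M(self) -> float:
        """Half-site association constant, 1/K_d."""
        return 1.0 / self.Kd_M


@dataclass(frozen=True)
class ReplicateSummary:
    mean_dG: float
    sem_dG: float | None
    n: int


def kd_to_dg(
    Kd_M: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    R: float = GAS_CONSTANT_KCAL,
) -> float:
    """ΔG_dissociation = −RT ln(K_d), kcal/mol, K_d in molar."""
    if Kd_M <= 0:
        raise ValueError("K_d must be positive")
    return -R * temperature_K * math.log(Kd_M)


def dg_to_kd(
    dG_kcal_mol: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    R: float = GAS_CONSTANT_KCAL,
) -> float:
    """Exact inverse of :func:`kd_to_dg`."""
    if not math.isfinite(dG_kcal_mol):
        raise ValueError("ΔG must be finite")
    return math.exp(-dG_kcal_mol / (R * temperature_K))


def _hyperbola(p, kd, base, plat):
    return base + (plat - base) * p / (kd + p)


def _depletion(p, kd, base, plat, d):
    # quadratic occupancy of the probe (total concentration d)
    s = p + d + kd
    frac = (s - np.sqrt(s * s - 4.0 * p * d)) / (2.0 * d)
    return base + (plat - base) * frac


class SingleSiteBinding(BaseEstimator):
    """Nonlinear least-squares fit of the single-site anisotropy model.

    Parameters
    ----------
    depletion : bool
        If True, use the probe-depletion-corrected quadratic model
        (requires the probe concentration).
    probe_conc_M : float
        Probe concentration for the depletion model.
    temperature_K, R : float
        Constants for the K_d → ΔG conversion.
    max_restarts : int
        Additional fits from log-spaced K_d starting values if the first
        attempt fails to converge.

    Fitted attributes (after ``fit``): ``kd_``, ``dg_``, ``baseline_``,
    ``plateau_``, ``rss_``, ``converged_``, ``in_range_``.
    """

    def __init__(
        self,
        depletion: bool = False,
        probe_conc_M: float = DEFAULT_PROBE_CONC_M,
        temperature_K: float = DEFAULT_TEMPERATURE_K,
        R: float = GAS_CONSTANT_KCAL,
        max_restarts: int = 5,
    ):
        self.depletion = depletion
        self.probe_conc_M = probe_conc_M
        self.temperature_K = temperature_K
        self.R = R
        self.max_restarts = max_restarts

    def _model(self, p, kd, base, plat):
        if self.depletion:
            return _depletion(p, kd, base, plat, self.probe_conc_M)
        return _hyperbola(p, kd, base, plat)

    def _log_model(self, p, log10_kd, base, plat):
        # optimisation runs in log10(K_d) so all parameters are O(1)
        return self._model(p, 10.0 ** log10_kd, base, plat)

    def fit(self, X, y=None, initial_kd: float | None = None):
        """Fit to concentrations ``X`` (molar) and anisotropy ``y``."""
        p = np.asarray(X, dtype=float).ravel()
        a = np.asarray(y, dtype=float).ravel()
        usable = np.isfinite(p) & np.isfinite(a) & (p > 0)
        p, a = p[usable], a[usable]
        if p.size < 4:
            raise InsufficientDataError(
                f"need at least 4 usable points, got {p.size}"
            )
        order = np.argsort(p)
        p, a = p[order], a[order]

        base0, plat0 = float(a.min()), float(a.max())
        if initial_kd is None:
            # concentration nearest the half-maximal anisotropy
            half = 0.5 * (base0 + plat0)
            initial_kd = float(p[np.argmin(np.abs(a - half))])
        starts = [initial_kd] + list(
            np.geomspace(p.min(), p.max(), self.max_restarts)
        )
        span = plat0 - base0 if plat0 > base0 else 1.0
        lo, hi = math.log10(p.min()) - 6.0, math.log10(p.max()) + 6.0
        bounds = (
            [lo, base0 - 10 * span, base0 - 10 * span],
            [hi, plat0 + 10 * span, plat0 + 10 * span],
        )
        best = None
        converged = False
        for kd0 in starts:
            try:
                popt, _ = curve_fit(
                    self._log_model,
                    p,
                    a,
                    p0=[math.log10(kd0), base0, plat0],
                    bounds=bounds,
                    maxfev=10000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((a - self._log_model(p, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
            converged = True
            break
        if best is None:
            # bounded restarts exhausted: flagged failure, not an exception
            popt = np.array([math.log10(initial_kd), base0, plat0])
            rss = float(np.sum((a - self._log_model(p, *popt)) ** 2))
            best = (popt, rss)
        popt, rss = best
        self.kd_ = float(10.0 ** popt[0])
        self.baseline_ = float(popt[1])
        self.plateau_ = float(popt[2])
        self.rss_ = rss
        self.converged_ = converged
        self.in_range_ = bool(p.min() <= self.kd_ <= p.max())
        self.dg_ = kd_to_dg(self.kd_, self.temperature_K, self.R)
        self.n_points_ = int(p.size)
        return self

    def predict(self, X):
        p = np.asarray(X, dtype=float)
        return self._model(p, self.kd_, self.baseline_, self.plateau_)

    def estimate_(self) -> BindingEstimate:
        return BindingEstimate(
            Kd_M=self.kd_,
            dG_kcal_mol=self.dg_,
            baseline=self.baseline_,
            plateau=self.plateau_,
            rss=self.rss_,
            converged=self.converged_,
            in_range=self.in_range_,
            temperature_K=self.temperature_K,
        )


def fit_single_site(
    curve: TitrationCurve,
    initial_kd: float | None = None,
    depletion: bool = False,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> BindingEstimate:
    """Fit one titration replicate to the single-site model."""
    est = SingleSiteBinding(
        depletion=depletion,
        probe_conc_M=curve.probe_conc_M,
        temperature_K=temperature_K,
    )
    est.fit(curve.concentrations_M, curve.anisotropy, initial_kd=initial_kd)
    return est.estimate_()


def aggregate_replicates(
    estimates: Sequence[BindingEstimate | float],
) -> ReplicateSummary:
    """Mean and SEM (sample sd / sqrt n) of replicate ΔG estimates."""
    if len(estimates) == 0:
        raise ValueError("no replicate estimates to aggregate")
    vals = np.array(
        [e.dG_kcal_mol if isinstance(e, BindingEstimate) else float(e) for e in estimates]
    )
    mean = float(vals.mean())
    if vals.size == 1:
        return ReplicateSummary(mean_dG=mean, sem_dG=None, n=1)
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return ReplicateSummary(mean_dG=mean, sem_dG=sem, n=int(vals.size))
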