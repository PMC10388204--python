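"""One-site binding analysis of isothermal titration calorimetry data.

The model is the standard single-site (Wiseman) isotherm with the
MicroCal displaced-volume bookkeeping: after cumulative injected volume
dV the effective cell concentrations are scaled by (1 - dV/2V0), the
bound concentration solves the binding quadratic

    B = 1/2 [ (N*M + X + K_D) - sqrt((N*M + X + K_D)^2 - 4 N*M*X) ],

the cumulative heat content is Q = B * dH * V0, and the per-injection
heat (normalized per mole of injectant) applies the half-displaced-
volume correction before adding a constant heat-of-dilution offset.
The stoichiometry N multiplies the binding-site concentration inside the
quadratic, keeping N and dH separately identifiable.

Units: volumes in microliters, concentrations molar, heats kcal/mol of
injectant, K_D molar.  The model depends only on volume *ratios*, so the
volume unit cancels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = ["ItcIsotherm", "ItcFit", "default_protocol", "large_aliquot_protocol",
           "model_heats", "fit_isotherm"]

_LOG10_KD_BOUNDS = (-8.0, -2.0)  # K_D search range, molar


@dataclass
class ItcIsotherm:
    """Injection protocol plus (optionally) measured per-injection heats.

    ``heats`` are normalized per mole of injectant (kcal/mol); None for a
    bare protocol awaiting simulation.
    """

    cell_volume: float                 # microliters
    cell_concentration: float          # molar (protein, in the cell)
    syringe_concentration: float       # molar (ligand)
    injection_volumes: np.ndarray      # microliters, one per injection
    heats: np.ndarray | None = None    # kcal per mole of injectant
    temperature: float = 298.15        # kelvin

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats must match injection_volumes in length")
            if not np.all(np.isfinite(self.heats)):
                raise ValueError("heats must be finite")


@dataclass
class ItcFit:
    """One-site fit parameters (also used as simulation ground truth)."""

    N: float = 1.0
    K_D: float = 1e-5                  # molar
    dH: float = -5.0                   # kcal/mol
    offset: float = 0.0                # kcal/mol of injectant
    sse: float = np.nan
    converged: bool = False
    no_binding: bool = False
    low_confidence: bool = False       # c-value < 1: K_D poorly constrained
    uncertainties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.K_D > 0:
            raise ValueError("K_D must be positive")


def default_protocol(
    n_injections: int = 19,
    injection_volume: float = 2.0,
    cell_volume: float = 280.0,
    cell_concentration: float = 0.05e-3,
    syringe_concentration: float = 0.5e-3,
) -> ItcIsotherm:
    """19 x 2 ul injections into the 280 ul cell (0.5 mM ligand into
    0.05 mM protein).  The ligand/protein concentrations follow the
    measured protocol; the reported 40 ul aliquot volume would overflow
    the cell after ~7 injections, so the schedule defaults to a standard
    19 x 2 ul series (see :func:`large_aliquot_protocol` for the literal
    reported values).
    """
    return ItcIsotherm(
        cell_volume=cell_volume,
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=np.full(n_injections, injection_volume),
    )


def large_aliquot_protocol(n_injections: int = 7) -> ItcIsotherm:
    """The literal reported schedule: 40 ul aliquots of 0.5 mM ligand
    into a 280 ul cell of 0.05 mM protein (overfills the cell after ~7
    injections; kept selectable for fidelity to the measured protocol)."""
    return ItcIsotherm(
        cell_volume=280.0,
        cell_concentration=0.05e-3,
        syringe_concentration=0.5e-3,
        injection_volumes=np.full(n_injections, 40.0),
    )


def model_heats(params: ItcFit, protocol: ItcIsotherm) -> np.ndarray:
    """Per-injection heats (kcal/mol of injectant) of the one-site model."""
    V0 = protocol.cell_volume
    dV = protocol.injection_volumes
    cumV = np.cumsum(dV)
    dilution = 1.0 - cumV / (2.0 * V0)
    M = protocol.cell_concentration * dilution
    X = protocol.syringe_concentration * (cumV / V0) * dilution
    b = params.N * M + X + params.K_D
    disc = b * b - 4.0 * params.N * M * X
    if np.any(disc < 0):
        warnings.warn("binding quadratic discriminant clamped at 0", stacklevel=2)
        disc = np.clip(disc, 0.0, None)
    B = 0.5 * (b - np.sqrt(disc))  # bound concentration, molar
    # cumulative heat content in kcal; V0 in liters
    Q = B * params.dH * (V0 * 1e-6)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dQ = Q - Qprev + (dV / V0) * (Q + Qprev) / 2.0
    moles_injected = protocol.syringe_concentration * dV * 1e-6
    return dQ / moles_injected + params.offset


def fit_isotherm(
    isotherm: ItcIsotherm,
    init: ItcFit | None = None,
    n_starts: int = 12,
    seed: int = 0,
) -> ItcFit:
    """Least-squares one-site fit with multi-start over K_D.

    Starts are log-spaced over K_D in [1e-8, 1e-2] M (plus the optional
    ``init``); the best sum of squared residuals wins.  Parameter
    uncertainties from the local curvature are advisory.  A fit pinned at
    the upper K_D bound or with a negligible binding signal is flagged
    ``no_binding``; a c-value (N * M0 / K_D) below 1 sets
    ``low_confidence``.
    """
    if isotherm.heats is None:
        raise ValueError("isotherm has no heats to fit")
    heats = isotherm.heats
    if len(heats) < 5:
        raise ValueError("need >= 5 informative injections")

    def residuals(theta):
        N, log10_kd, dH, offset = theta
        p = ItcFit(N=N, K_D=10.0 ** log10_kd, dH=dH, offset=offset)
        return model_heats(p, isotherm) - heats

    dh0 = float(heats[0] - heats[-1])
    if dh0 == 0.0:
        dh0 = -1.0
    off0 = float(np.mean(heats[-3:]))
    lo = [0.05, _LOG10_KD_BOUNDS[0], -500.0, -50.0]
    hi = [20.0, _LOG10_KD_BOUNDS[1], 500.0, 50.0]
    starts = [np.array([1.0, lk, dh0, off0]) for lk in np.linspace(-7.5, -2.5, n_starts)]
    if init is not None:
        starts.append(np.array([init.N, np.log10(init.K_D), init.dH, init.offset]))

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # noqa: BLE001 - keep best partial result
            logger.debug("ITC start failed: %s", exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all ITC fit starts failed")

    N, log10_kd, dH, offset = best.x
    K_D = 10.0 ** log10_kd
    sse = float(2.0 * best.cost)
    fit = ItcFit(N=N, K_D=K_D, dH=dH, offset=offset, sse=sse,
                 converged=bool(best.status > 0))

    # advisory curvature uncertainties
    n, p = len(heats), 4
    try:
        JtJ = best.jac.T @ best.jac
        cov = np.linalg.inv(JtJ) * max(sse, 1e-30) / max(n - p, 1)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        fit.uncertainties = {
            "N": float(se[0]),
            "log10_K_D": float(se[1]),
            "dH": float(se[2]),
            "offset": float(se[3]),
        }
    except np.linalg.LinAlgError:
        pass

    signal = np.max(np.abs(model_heats(fit, isotherm) - fit.offset))
    if log10_kd >= _LOG10_KD_BOUNDS[1] - 1e-3 or signal < 1e-3:
        fit.no_binding = True
        logger.info("fit flagged: no detectable binding")
    c_value = fit.N * isotherm.cell_concentration / fit.K_D
    if c_value < 1.0:
        fit.low_confidence = True
    return fit
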