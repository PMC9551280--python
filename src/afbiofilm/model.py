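"""Core model functions and parameter container.

The physical picture: a ship-hull coating releases a biocide that diffuses
into the seawater and is degraded at a uniform rate, producing an
exponentially decaying concentration profile away from the surface.  The
nascent biofilm is discretised into 1-micron "microhabitat" slices, each of
which sees a fixed biocide concentration.  Microbes are characterised by a
single trait, their minimum inhibitory concentration (MIC): below their MIC
they grow, above it they are killed, with both rates set by a single
pharmacodynamic response curve.  Immigrants arriving from the ocean draw
their MIC from a log-normal distribution calibrated to a chosen mean MIC and
a chosen fraction of immigrants resistant to the surface concentration.

This module holds the deterministic building blocks: the biocide gradient,
the pharmacodynamic rate, the log-normal MIC calibration, and the validated
parameter set.  The stochastic engine lives in :mod:`afbiofilm.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ModelParams",
    "Ecotype",
    "biocide_concentration",
    "pharmacodynamic_rate",
    "lognormal_stats",
    "solve_lognormal_params",
    "sample_mic",
    "InfeasibleMICError",
    "DEFAULTS",
]


class InfeasibleMICError(ValueError):
    """No log-normal distribution matches the requested mean/tail pair."""


class Ecotype(NamedTuple):
    """A biocide-resistance lineage: a unique id plus a fixed MIC (ppm).

    MIC values are continuous and inherited unchanged on division
    (no mutation), so each immigration event founds a fresh ecotype.
    """

    id: int
    mic: float


def biocide_concentration(i, c_max: float, alpha: float, delta_z: float):
    """Biocide concentration (ppm) at the midpoint of microhabitat ``i``.

    The profile is geometric in the slice index:
    ``c_i = c_max * exp(-alpha * (i + 1/2) * delta_z)``,
    the steady state of diffusion from the surface with uniform degradation.

    Parameters
    ----------
    i : int or array of int
        Microhabitat index, 0 at the surface.
    c_max : float
        Concentration at the coating-seawater interface (ppm).
    alpha : float
        Gradient steepness (1/um).
    delta_z : float
        Slice thickness (um).
    """
    i = np.asarray(i)
    if np.any(i < 0):
        raise ValueError("microhabitat index must be >= 0")
    out = c_max * np.exp(-alpha * (i + 0.5) * delta_z)
    return out if out.ndim else float(out)


def pharmacodynamic_rate(c, mic, r_max: float):
    """Signed per-capita growth/kill rate (1/h) at biocide concentration ``c``.

    phi(c, MIC) = r_max * (1 - 6 (c/MIC)^2 / (5 + (c/MIC)^2))

    Positive below the MIC (growth, up to ``r_max`` at c=0), zero at c=MIC,
    and negative above it, saturating at ``-5 r_max`` for c >> MIC.  A single
    parameter ``r_max`` therefore sets both the maximal growth rate and the
    scale of biocide-mediated killing.
    """
    c = np.asarray(c, dtype=float)
    mic = np.asarray(mic, dtype=float)
    if np.any(mic <= 0):
        raise ValueError("MIC must be strictly positive")
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    u = (c / mic) ** 2
    out = r_max * (1.0 - 6.0 * u / (5.0 + u))
    return out if out.ndim else float(out)


def lognormal_stats(mu: float, sigma: float, threshold: float) -> tuple[float, float]:
    """Mean MIC and exceedance probability of a log-normal MIC distribution.

    Returns ``(exp(mu + sigma^2/2), P(MIC > threshold))`` where
    ``P(MIC > t) = [1 - erf((ln t - mu) / (sigma sqrt(2)))] / 2``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mean = math.exp(mu + sigma**2 / 2.0)
    exceed = stats.norm.sf((math.log(threshold) - mu) / sigma)
    return mean, float(exceed)


def solve_lognormal_params(
    mic_ave: float, pc_res: float, c_max: float
) -> tuple[float, float]:
    """Calibrate (mu, sigma) of the immigrant MIC distribution.

    Solves the two constraints

        exp(mu + sigma^2/2) = mic_ave          (mean MIC, ppm)
        P(MIC > c_max)      = pc_res           (resistant fraction)

    in closed form.  With ``z`` the upper-tail standard-normal quantile of
    ``pc_res``, sigma satisfies the quadratic
    ``sigma^2/2 - z*sigma + ln(c_max/mic_ave) = 0``.  Both roots satisfy the
    constraints when real and positive; the smaller positive root (the
    narrower distribution) is returned, and
    ``mu = ln(mic_ave) - sigma^2/2``.

    Raises
    ------
    InfeasibleMICError
        If no positive real root exists for the requested combination.
    """
    if mic_ave <= 0:
        raise ValueError("mic_ave must be > 0")
    if not 0.0 < pc_res < 1.0:
        raise ValueError("pc_res must lie strictly between 0 and 1")
    if c_max <= 0:
        raise ValueError("c_max must be > 0")

    z = float(stats.norm.isf(pc_res))
    disc = z * z - 2.0 * math.log(c_max / mic_ave)
    if disc < 0:
        raise InfeasibleMICError(
            f"no log-normal with mean {mic_ave} ppm and "
            f"P(MIC > {c_max} ppm) = {pc_res}"
        )
    root = math.sqrt(disc)
    candidates = [z - root, z + root]
    positive = [s for s in candidates if s > 0]
    if not positive:
        raise InfeasibleMICError(
            f"no positive-width log-normal with mean {mic_ave} ppm and "
            f"P(MIC > {c_max} ppm) = {pc_res}"
        )
    sigma = min(positive)
    mu = math.log(mic_ave) - sigma**2 / 2.0
    return mu, sigma


def sample_mic(rng: np.random.Generator, mu: float, sigma: float, size=None):
    """Draw i.i.d. MIC values (ppm) from the immigrant log-normal."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


# Baseline parameter set: marine antifouling coating releasing ~5 ppm of
# biocide at the surface, colonised by marine microbes with growth and
# mortality rates typical of ocean communities.  Units in field docstrings.
DEFAULTS: dict[str, float] = {
    "c_max": 5.0,          # ppm, surface biocide concentration
    "alpha": 0.01,         # 1/um, gradient steepness
    "delta_z": 1.0,        # um, microhabitat thickness
    "delta_a": 0.25,       # mm^2, lateral area (0.5 mm x 0.5 mm)
    "r_max": 0.083,        # 1/h, max growth rate / kill-rate scale
    "d_uniform": 0.018,    # 1/h, biocide-independent mortality
    "K": 550.0,            # microbes per microhabitat, carrying capacity
    "N_star": 412.5,       # microbes, biofilm-transition threshold (0.75 K)
    "mic_ave": 3.179,      # ppm, mean immigrant MIC
    "pc_res": 0.16,        # fraction of immigrants with MIC > c_max
    "r_imm": 20.0,         # 1/h, immigration rate into the edge habitat
    "r_mig": 0.1,          # 1/h, per-capita migration rate
    "r_det": 0.22 * 0.083, # 1/h, per-capita detachment rate at the edge
    "t_max": 4380.0,       # h, simulated-time cap (6 months)
    "L_max": 40,           # microhabitats, thickness cap
    "tau": 0.1,            # h, tau-leap interval
    "record_dt": 10.0,     # h, snapshot interval
}

_CONSISTENCY_RTOL = 1e-6

# baseline MIC calibration, solved once so ModelParams() is valid as-is
_MU0, _SIGMA0 = solve_lognormal_params(
    DEFAULTS["mic_ave"], DEFAULTS["pc_res"], DEFAULTS["c_max"]
)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set for one simulation, with derived MIC calibration.

    The stored (``mic_mu``, ``mic_sigma``) and the derived
    (``mic_ave``, ``pc_res``) must describe the same log-normal: this is
    validated on construction.  Use :meth:`create` to build a parameter set
    from partial input (missing values fall back to the baseline defaults and
    the MIC calibration is solved automatically), and :meth:`evolve` to
    change parameters while keeping the calibration consistent.
    """

    c_max: float = DEFAULTS["c_max"]
    alpha: float = DEFAULTS["alpha"]
    delta_z: float = DEFAULTS["delta_z"]
    delta_a: float = DEFAULTS["delta_a"]
    r_max: float = DEFAULTS["r_max"]
    d_uniform: float = DEFAULTS["d_uniform"]
    K: float = DEFAULTS["K"]
    N_star: float = DEFAULTS["N_star"]
    mic_mu: float = _MU0
    mic_sigma: float = _SIGMA0
    mic_ave: float = DEFAULTS["mic_ave"]
    pc_res: float = DEFAULTS["pc_res"]
    r_imm: float = DEFAULTS["r_imm"]
    r_mig: float = DEFAULTS["r_mig"]
    r_det: float = DEFAULTS["r_det"]
    t_max: float = DEFAULTS["t_max"]
    L_max: int = int(DEFAULTS["L_max"])
    tau: float = DEFAULTS["tau"]
    record_dt: float = DEFAULTS["record_dt"]
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "c_max", "alpha", "delta_z", "delta_a", "r_max", "d_uniform",
            "r_imm", "r_mig", "r_det", "record_dt",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N_star <= 0 or self.K < self.N_star:
            raise ValueError("need K >= N_star > 0")
        if self.L_max < 1:
            raise ValueError("L_max must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.mic_sigma <= 0:
            raise ValueError("mic_sigma must be > 0")
        if not 0.0 < self.pc_res < 1.0:
            raise ValueError("pc_res must lie strictly between 0 and 1")
        mean, exceed = lognormal_stats(self.mic_mu, self.mic_sigma, self.c_max)
        if not math.isclose(mean, self.mic_ave, rel_tol=_CONSISTENCY_RTOL):
            raise ValueError(
                f"mic_ave={self.mic_ave} inconsistent with "
                f"(mic_mu, mic_sigma): implied mean {mean:.6g}"
            )
        if not math.isclose(exceed, self.pc_res, rel_tol=_CONSISTENCY_RTOL):
            raise ValueError(
                f"pc_res={self.pc_res} inconsistent with "
                f"(mic_mu, mic_sigma): implied exceedance {exceed:.6g}"
            )

    @classmethod
    def create(cls, **overrides) -> "ModelParams":
        """Build a parameter set, filling gaps from the baseline defaults.

        If ``mic_mu``/``mic_sigma`` are not given, they are solved from
        (``mic_ave``, ``pc_res``, ``c_max``).  If they are given, the derived
        pair is recomputed from them (any supplied ``mic_ave``/``pc_res``
        must agree).  Unknown keys are rejected.
        """
        valid = {f.name for f in fields(cls)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        values = dict(DEFAULTS)
        values["seed"] = None
        values.update(overrides)
        values["L_max"] = int(values["L_max"])
        if "mic_mu" in overrides or "mic_sigma" in overrides:
            if "mic_mu" not in overrides or "mic_sigma" not in overrides:
                raise ValueError("mic_mu and mic_sigma must be given together")
            mean, exceed = lognormal_stats(
                values["mic_mu"], values["mic_sigma"], values["c_max"]
            )
            if "mic_ave" in overrides and not math.isclose(
                mean, values["mic_ave"], rel_tol=_CONSISTENCY_RTOL
            ):
                raise ValueError("mic_ave inconsistent with given (mic_mu, mic_sigma)")
            if "pc_res" in overrides and not math.isclose(
                exceed, values["pc_res"], rel_tol=_CONSISTENCY_RTOL
            ):
                raise ValueError("pc_res inconsistent with given (mic_mu, mic_sigma)")
            # keep caller-supplied derived values when consistent, so that
            # dump -> load round trips are exact
            if "mic_ave" not in overrides:
                values["mic_ave"] = mean
            if "pc_res" not in overrides:
                values["pc_res"] = exceed
        else:
            values["mic_mu"], values["mic_sigma"] = solve_lognormal_params(
                values["mic_ave"], values["pc_res"], values["c_max"]
            )
        return cls(**values)

    def evolve(self, **changes) -> "ModelParams":
        """Return a copy with ``changes`` applied and the MIC calibration
        re-solved from (mic_ave, pc_res, c_max) unless mu/sigma are set
        explicitly."""
        base = {f.name: getattr(self, f.name) for f in fields(self)}
        base.update(changes)
        if "mic_mu" not in changes and "mic_sigma" not in changes:
            base.pop("mic_mu")
            base.pop("mic_sigma")
        else:
            base.pop("mic_ave")
            base.pop("pc_res")
        return ModelParams.create(**base)

    def concentration(self, i):
        """Biocide concentration (ppm) in microhabitat ``i``."""
        return biocide_concentration(i, self.c_max, self.alpha, self.delta_z)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d
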