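"""Auxiliary-signal priors and the multiplicative output modulator.

Seizure-conditioned densities p(d|z') are Gaussian-kernel KDEs with Scott's
bandwidth fitted to auxiliary observations taken at seizure onsets (e.g.
clock hour).  Under independence of the auxiliary signals and the EEG, the
posterior of a seizure given all evidence factorizes into the network output
times the likelihood ratios p(d_i|z') / p(d_i); the product of those ratios
multiplies the preictal pre-softmax output.  Multiplying both outputs would
cancel in the softmax, so the ratio is applied to the preictal component
only (a log-domain additive variant is available behind a flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

#: Floor applied to conditional densities so a zero KDE value cannot veto
#: the EEG evidence outright.
DENSITY_FLOOR = 1e-6


@dataclass
class AuxiliaryPrior:
    """Gaussian-kernel KDE p(d|z') plus a baseline density p(d).

    ``domain`` is either ``("circular", period)`` — evaluated by wrapping
    kernel replicas at +/- one period — or ``("linear", lo, hi)`` with a
    uniform baseline 1/(hi - lo).
    """

    observations: np.ndarray
    bandwidth: float
    domain: tuple = ("circular", 24.0)
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    @property
    def is_circular(self) -> bool:
        return self.domain[0] == "circular"

    @property
    def period(self) -> float:
        return float(self.domain[1]) if self.is_circular else float("nan")

    def conditional(self, v: float | np.ndarray) -> np.ndarray | float:
        """KDE density p(v|z'), floored at ``floor``."""
        v = np.asarray(v, dtype=float)
        obs, h = self.observations, self.bandwidth
        if self.is_circular:
            p = self.period
            vv = np.mod(v, p)
            shifts = np.array([-p, 0.0, p])
            centers = (obs[:, None] + shifts[None, :]).ravel()
        else:
            vv = v
            centers = obs
        dens = norm.pdf(vv[..., None], loc=centers, scale=h).sum(axis=-1) / len(obs)
        out = np.maximum(dens, self.floor)
        return float(out) if out.ndim == 0 else out

    def baseline(self, v: float | np.ndarray) -> np.ndarray | float:
        """Uninformative reference density p(v): uniform over the domain."""
        v = np.asarray(v, dtype=float)
        if self.is_circular:
            val = 1.0 / self.period
        else:
            val = 1.0 / (self.domain[2] - self.domain[1])
        out = np.full(v.shape, val)
        return float(val) if out.ndim == 0 else out

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(
            json.dumps(
                {
                    "observations": self.observations.tolist(),
                    "bandwidth": self.bandwidth,
                    "domain": list(self.domain),
                    "floor": self.floor,
                }
            )
        )
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "AuxiliaryPrior":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["observations"]),
            d["bandwidth"],
            tuple(d["domain"]),
            d.get("floor", DENSITY_FLOOR),
        )


@dataclass
class FusionFactor:
    """Product of per-signal likelihood ratios p(d_i|z') / p(d_i)."""

    components: list[float] = field(default_factory=list)

    @property
    def value(self) -> float:
        return float(np.prod(self.components)) if self.components else 1.0


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule: n^(-1/5) times the sample standard deviation."""
    values = np.asarray(values, dtype=float)
    return float(len(values) ** (-1.0 / 5.0) * values.std(ddof=1))


def fit_auxiliary_prior(
    values: Sequence[float],
    domain: tuple = ("circular", 24.0),
    bandwidth: float | None = None,
) -> AuxiliaryPrior:
    """Fit the seizure-conditioned KDE from onset-time observations."""
    values = np.asarray(list(values), dtype=float)
    if len(values) < 2:
        raise ValueError(
            "need at least 2 observations to fit a KDE; pass bandwidth= to override"
        )
    if bandwidth is None:
        bandwidth = scott_bandwidth(values)
        if bandwidth <= 0:
            raise ValueError(
                "observations have zero variance; pass an explicit bandwidth"
            )
    if domain[0] == "circular":
        values = np.mod(values, domain[1])
    return AuxiliaryPrior(values, bandwidth, tuple(domain))


def evaluate_prior(prior: AuxiliaryPrior, v: float) -> tuple[float, float]:
    """(conditional density p(v|z'), baseline density p(v)) at one value."""
    return float(prior.conditional(v)), float(prior.baseline(v))


def fusion_factor(
    priors: Sequence[AuxiliaryPrior], values: Sequence[float]
) -> FusionFactor:
    """Multiply per-signal likelihood ratios; empty input gives the identity."""
    if len(priors) != len(values):
        raise ValueError(
            f"got {len(priors)} priors but {len(values)} auxiliary values"
        )
    comps = []
    for prior, v in zip(priors, values):
        cond, base = evaluate_prior(prior, v)
        comps.append(cond / base)
    return FusionFactor(comps)


def modulate_output(
    outputs: np.ndarray, factor: FusionFactor | float, log_domain: bool = False
) -> np.ndarray:
    """Apply the modulator to the pre-softmax output pair.

    The preictal component (index 1) is multiplied by the factor; with
    ``log_domain=True`` the log of the factor is added instead (the additive
    Bayes-composition variant).
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape[-1] != 2:
        raise ValueError("outputs must have final dimension 2")
    f = factor.value if isinstance(factor, FusionFactor) else float(factor)
    if not np.isfinite(f) or f <= 0:
        raise ValueError(f"fusion factor must be finite and positive, got {f}")
    out = outputs.copy()
    if log_domain:
        out[..., 1] += np.log(f)
    else:
        out[..., 1] *= f
    return out


def tod_factors(
    prior: AuxiliaryPrior, clock_hours: Sequence[float]
) -> np.ndarray:
    """Per-segment time-of-day fusion factors for an array of clock hours."""
    hours = np.asarray(list(clock_hours), dtype=float)
    cond = np.maximum(prior.conditional(hours), prior.floor)
    base = prior.baseline(hours)
    return np.asarray(cond / base, dtype=float)
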