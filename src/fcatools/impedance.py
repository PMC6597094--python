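"""Impedance (distance-decay) functions.

An impedance function maps a travel cost to a weight in [0, 1] and is
non-increasing in cost; it defines the catchment areas of the floating
catchment area methods. Three kinds are supported:

``binary``
    1 up to a threshold ``d0``, 0 beyond — the classic 2SFCA catchment.
``stepwise``
    Piecewise-constant weights ``k_1 >= k_2 >= ... >= k_R`` on brackets
    ``(d_{r-1}, d_r]`` (with ``d_0 = 0``), 0 beyond the last break — the
    E2SFCA form. Bracket boundaries are closed on the right: a cost exactly
    equal to a break takes the nearer bracket's weight.
``gaussian``
    ``exp(-d^2 / (2 sigma^2))`` with an optional hard cutoff.

:func:`gaussian_stepwise` discretizes a Gaussian into a stepwise spec by
evaluating it at each bracket's upper break, the usual way travel-survey
calibrated decay curves are turned into service-area rings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenario import CostMatrix

__all__ = [
    "ImpedanceSpec",
    "WeightMatrix",
    "binary",
    "stepwise",
    "gaussian",
    "gaussian_stepwise",
    "evaluate",
    "parse_impedance",
]


@dataclass(frozen=True)
class ImpedanceSpec:
    """Parametrized impedance function.

    Use the :func:`binary`, :func:`stepwise`, :func:`gaussian` or
    :func:`gaussian_stepwise` constructors rather than building directly.
    """

    kind: str
    threshold: float | None = None          # binary d0
    breaks: tuple[float, ...] = ()          # stepwise d_1 < ... < d_R
    weights: tuple[float, ...] = ()         # stepwise k_1 >= ... >= k_R
    sigma: float | None = None              # gaussian
    cutoff: float | None = None             # gaussian hard cutoff

    def __post_init__(self) -> None:
        if self.kind == "binary":
            if self.threshold is None or self.threshold <= 0:
                raise ValueError("binary impedance needs a threshold d0 > 0")
        elif self.kind == "stepwise":
            b = np.asarray(self.breaks, dtype=float)
            k = np.asarray(self.weights, dtype=float)
            if b.size == 0 or b.size != k.size:
                raise ValueError("stepwise impedance needs matching breaks and weights")
            if np.any(np.diff(b) <= 0) or b[0] <= 0:
                raise ValueError("breaks must be positive and strictly increasing")
            if np.any(k <= 0) or np.any(k > 1):
                raise ValueError("stepwise weights must lie in (0, 1]")
            if np.any(np.diff(k) > 0):
                raise ValueError("stepwise weights must be non-increasing")
        elif self.kind == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian impedance needs sigma > 0")
            if self.cutoff is not None and self.cutoff <= 0:
                raise ValueError("gaussian cutoff must be positive")
        else:
            raise ValueError(f"unknown impedance kind {self.kind!r}")

    @property
    def tag(self) -> str:
        """Compact string form, also accepted by :func:`parse_impedance`."""
        if self.kind == "binary":
            return f"binary:{self.threshold:g}"
        if self.kind == "stepwise":
            body = ",".join(f"{d:g}={k:g}" for d, k in zip(self.breaks, self.weights))
            return f"stepwise:{body}"
        base = f"gaussian:{self.sigma:g}"
        return base if self.cutoff is None else f"{base}@{self.cutoff:g}"


def binary(threshold: float) -> ImpedanceSpec:
    """All-or-nothing catchment: weight 1 for cost <= ``threshold``, else 0."""
    return ImpedanceSpec(kind="binary", threshold=float(threshold))


def stepwise(breaks, weights) -> ImpedanceSpec:
    """Piecewise-constant decay with weight ``weights[r]`` on ``(d_{r-1}, d_r]``."""
    return ImpedanceSpec(
        kind="stepwise",
        breaks=tuple(float(b) for b in breaks),
        weights=tuple(float(k) for k in weights),
    )


def gaussian(sigma: float, cutoff: float | None = None) -> ImpedanceSpec:
    """Continuous Gaussian decay ``exp(-d^2 / (2 sigma^2))``."""
    return ImpedanceSpec(
        kind="gaussian",
        sigma=float(sigma),
        cutoff=None if cutoff is None else float(cutoff),
    )


def gaussian_stepwise(breaks, sigma: float) -> ImpedanceSpec:
    """Discretize a Gaussian into a stepwise spec.

    Each bracket ``(d_{r-1}, d_r]`` gets the Gaussian evaluated at its upper
    break, ``k_r = exp(-d_r^2 / (2 sigma^2))``; weight is 0 beyond the last
    break. With ``sigma = 15`` minutes over breaks (5, 10, 15, 20, 30, 45)
    this yields the weights (0.946, 0.801, 0.607, 0.411, 0.135, 0.011).
    """
    b = np.asarray(breaks, dtype=float)
    if b.size == 0 or np.any(np.diff(b) <= 0) or b[0] <= 0:
        raise ValueError("breaks must be positive and strictly increasing")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = np.exp(-(b**2) / (2.0 * float(sigma) ** 2))
    return stepwise(b, k)


@dataclass
class WeightMatrix:
    """Impedance weights W(d_ij) in [0, 1] over an origin-destination grid."""

    values: np.ndarray
    origin_ids: list[str]
    dest_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.origin_ids), len(self.dest_ids)):
            raise ValueError("weight matrix shape does not match id lists")
        if np.any(self.values < 0) or np.any(self.values > 1) or np.any(
            np.isnan(self.values)
        ):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def evaluate(costs: CostMatrix, spec: ImpedanceSpec) -> WeightMatrix:
    """Evaluate an impedance spec over a cost matrix.

    Unreachable pairs (cost ``inf``) get weight exactly 0 under every kind.
    """
    c = costs.cost
    if spec.kind == "binary":
        w = (c <= spec.threshold).astype(float)
    elif spec.kind == "stepwise":
        b = np.asarray(spec.breaks)
        k = np.concatenate([np.asarray(spec.weights), [0.0]])
        # side='left' puts a cost equal to a break into the lower bracket
        idx = np.searchsorted(b, c, side="left")
        idx = np.where(np.isfinite(c), idx, len(b))
        w = k[idx]
    else:  # gaussian
        with np.errstate(over="ignore"):
            w = np.where(
                np.isfinite(c), np.exp(-(c**2) / (2.0 * spec.sigma**2)), 0.0
            )
        if spec.cutoff is not None:
            w = np.where(c <= spec.cutoff, w, 0.0)
    return WeightMatrix(w, costs.origin_ids, costs.dest_ids)


def parse_impedance(text: str) -> ImpedanceSpec:
    """Parse a compact impedance string.

    Formats: ``binary:15`` — threshold in minutes;
    ``stepwise:5=0.946,10=0.801,...`` — break=weight pairs;
    ``gaussian:15`` or ``gaussian:15@45`` — sigma, optional cutoff;
    ``gstep:15@5,10,15,20,30,45`` — Gaussian sigma discretized over breaks.
    """
    try:
        kind, _, body = text.partition(":")
        kind = kind.strip().lower()
        if kind == "binary":
            return binary(float(body))
        if kind == "stepwise":
            pairs = [p.split("=") for p in body.split(",")]
            return stepwise([float(d) for d, _ in pairs], [float(k) for _, k in pairs])
        if kind == "gaussian":
            sigma, _, cut = body.partition("@")
            return gaussian(float(sigma), float(cut) if cut else None)
        if kind == "gstep":
            sigma, _, brk = body.partition("@")
            return gaussian_stepwise([float(b) for b in brk.split(",")], float(sigma))
    except (ValueError, IndexError) as exc:
        if isinstance(exc, ValueError) and "impedance" in str(exc):
            raise
        raise ValueError(f"cannot parse impedance string {text!r}") from exc
    raise ValueError(
        f"unknown impedance kind in {text!r}; expected binary:, stepwise:, "
        "gaussian: or gstep:"
    )
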