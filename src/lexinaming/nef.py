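"""Leaky integrate-and-fire tuning curves and least-squares decoders.

This is the representation layer: a vector is encoded by an array of scalar
neural ensembles (one ensemble per vector dimension), each neuron having a
random maximum firing rate, a random intercept, and a +-1 encoder.  The value
carried by a dimension is decoded from the ensemble's filtered activity with
weights obtained by regularised least squares over the neuron tuning curves.

The same tuning curves drive both backends of the simulator: the spiking
backend generates spikes from the membrane equation, while the direct backend
evaluates the static rate curves, which makes it deterministic and smooth but
keeps neuron-level semantics (in particular, silencing a neuron removes its
decoder contribution identically in both backends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LIFParams", "lif_rate", "gain_bias", "EnsembleArray", "solve_decoders"]


@dataclass(frozen=True)
class LIFParams:
    """Neuron and simulation constants.

    Defaults follow the common conventions for this class of model: 20 ms
    membrane time constant, 2 ms refractory period, maximum firing rates
    drawn uniformly from 200-400 Hz, intercepts uniform over (-1, 1), and a
    1 ms simulation step.
    """

    tau_m: float = 0.020
    tau_ref: float = 0.002
    rate_min: float = 200.0
    rate_max: float = 400.0
    intercept_low: float = -1.0
    intercept_high: float = 1.0
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if not 0 < self.rate_min < self.rate_max:
            raise ValueError("rates must satisfy 0 < rate_min < rate_max")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def lif_rate(J: np.ndarray, params: LIFParams) -> np.ndarray:
    """Steady-state LIF firing rate (Hz) for input current ``J``.

    ``a(J) = 1 / (tau_ref - tau_m * log(1 - 1/J))`` for ``J > 1``, else 0.
    """
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    active = J > 1.0 + 1e-12
    Ja = J[active]
    out[active] = 1.0 / (
        params.tau_ref - params.tau_m * np.log1p(-1.0 / Ja)
    )
    return out


def gain_bias(
    max_rates: np.ndarray, intercepts: np.ndarray, params: LIFParams
) -> tuple[np.ndarray, np.ndarray]:
    """Gain and bias current such that a neuron is silent below its intercept
    and fires at its maximum rate when the encoded projection equals 1."""
    max_rates = np.asarray(max_rates, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    inv = 1.0 / max_rates
    # current at which the neuron reaches its max rate
    J_max = 1.0 / (1.0 - np.exp((params.tau_ref - inv) / params.tau_m))
    gain = (J_max - 1.0) / (1.0 - intercepts)
    bias = 1.0 - gain * intercepts
    return gain, bias


def solve_decoders(
    activities: np.ndarray,
    targets: np.ndarray,
    reg: float = 0.1,
) -> np.ndarray:
    """Ridge-regularised least-squares decoders.

    Parameters
    ----------
    activities:
        ``(..., n_neurons, n_eval)`` tuning-curve samples.
    targets:
        ``(..., n_eval)`` target function values at the same samples.
    reg:
        Regularisation as a fraction of the maximum activity; the ridge
        parameter is ``n_eval * (reg * max(A))**2``.

    Returns
    -------
    ``(..., n_neurons)`` decoder weights minimising the regularised squared
    decoding error.
    """
    A = np.asarray(activities, dtype=float)
    Y = np.asarray(targets, dtype=float)
    n_eval = A.shape[-1]
    amax = float(np.max(A)) if A.size else 0.0
    if amax <= 0.0:
        raise ValueError(
            "degenerate tuning: no neuron is ever active over the sample range"
        )
    lam = n_eval * (reg * amax) ** 2
    G = A @ np.swapaxes(A, -1, -2)
    G += lam * np.eye(A.shape[-2])
    b = A @ Y[..., None]
    return np.linalg.solve(G, b)[..., 0]


class EnsembleArray:
    """``dims`` scalar LIF ensembles of ``n_per`` neurons each.

    Each ensemble encodes one dimension of a vector over ``[-radius, radius]``
    with +-1 encoders.  ``decoders`` are solved for a per-dimension target
    function (identity by default).
    """

    def __init__(
        self,
        dims: int,
        n_per: int,
        params: LIFParams,
        rng: np.random.Generator,
        radius: float = 1.0,
        intercept_range: "tuple[float, float] | None" = None,
        encoders: str = "mixed",
        target_fn=None,
        n_eval: int = 120,
    ):
        if dims < 1:
            raise ValueError("dims must be a positive integer")
        if n_per < 1:
            raise ValueError("n_per must be a positive integer")
        self.dims = dims
        self.n_per = n_per
        self.params = params
        self.radius = float(radius)

        lo, hi = (
            (params.intercept_low, params.intercept_high)
            if intercept_range is None
            else intercept_range
        )
        shape = (dims, n_per)
        self.max_rates = rng.uniform(params.rate_min, params.rate_max, size=shape)
        self.intercepts = rng.uniform(lo, hi, size=shape)
        if encoders == "mixed":
            self.enc = rng.choice([-1.0, 1.0], size=shape)
        elif encoders == "positive":
            self.enc = np.ones(shape)
        else:
            raise ValueError(f"unknown encoder scheme: {encoders!r}")
        self.gain, self.bias = gain_bias(self.max_rates, self.intercepts, params)

        # normalised eval grid xi = x / radius
        xi = np.linspace(-1.0, 1.0, n_eval)
        J = self.gain[..., None] * (self.enc[..., None] * xi) + self.bias[..., None]
        A = lif_rate(J, params)
        if target_fn is None:
            y = self.radius * xi  # identity decode in unscaled units
            Y = np.broadcast_to(y, (dims, n_eval))
        else:
            Y = np.asarray(target_fn(self.radius * xi), dtype=float)
            Y = np.broadcast_to(Y, (dims, n_eval))
        self.decoders = solve_decoders(A, Y)

    @property
    def n_neurons(self) -> int:
        return self.dims * self.n_per

    def currents(self, x: np.ndarray) -> np.ndarray:
        """Input currents ``J`` for a represented vector ``x`` (shape (dims,))."""
        xi = np.asarray(x, dtype=float) / self.radius
        return self.gain * (self.enc * xi[:, None]) + self.bias

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Static firing rates at represented vector ``x``."""
        return lif_rate(self.currents(x), self.params)

    def decode(self, activities: np.ndarray) -> np.ndarray:
        """Decode a vector from per-neuron activities (shape (dims, n_per))."""
        return np.einsum("dn,dn->d", self.decoders, activities)
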