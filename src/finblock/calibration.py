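"""Metropolis-Hastings fitting of channel conductances to spike features.

A generic random-walk sampler over maximal conductances: proposals are
Gaussian in log space (so bounds and positivity are natural), the likelihood
is Gaussian over a normalised spike-feature vector (count, first-spike
latency, peak amplitude by default), and the chain is fully reproducible
under its seed.  This mirrors the conductance-fitting step used to adapt a
ganglion-cell template to target electrophysiology, but runs against any
objective mapping parameters to features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .membrane_dynamics import MechanismSet, scale_conductance
from .morphology import FibreModel
from .simulator import StimulusProtocol, simulate

__all__ = [
    "FitSpec",
    "FitResult",
    "spike_features",
    "make_conductance_objective",
    "metropolis_hastings_fit",
]


@dataclass(frozen=True)
class FitSpec:
    """Free parameters, targets and sampler settings for one fit.

    ``params``: (name, lower, upper) bounds per free parameter -- for
    conductance fits the name is ``region/channel`` and the value is the
    scale factor applied to the bound mechanism's maximal conductance.
    ``feature_sigma`` is the likelihood width on normalised features.
    """

    params: tuple[tuple[str, float, float], ...]
    targets: Mapping[str, float]
    weights: Mapping[str, float] | None = None
    proposal_scale: float = 0.1  # sd of the log-space Gaussian step
    chain_length: int = 2000
    seed: int = 0
    feature_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain length must be >= 1")
        for name, lo, hi in self.params:
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"parameter {name!r}: bounds must be finite, "
                                 "positive and ordered")


@dataclass
class FitResult:
    chain: pd.DataFrame  # one row per iteration: params, loss, accepted
    best_params: dict[str, float]
    best_loss: float
    acceptance_rate: float
    metadata: dict = field(default_factory=dict)


def spike_features(result, site: str = "node_B") -> dict[str, float]:
    """Spike count, first-spike latency (ms) and peak potential (mV)."""
    spikes = result.spike_times_ms[site]
    return {
        "spike_count": float(len(spikes)),
        "first_latency_ms": float(spikes[0]) if len(spikes) else
            float(result.t_ms[-1]),
        "peak_mv": float(np.max(result.traces_mv[site])),
    }


def make_conductance_objective(model: FibreModel,
                               bindings: Mapping[str, MechanismSet],
                               protocol: StimulusProtocol,
                               site: str = "node_B",
                               settle_ms: float = 60.0,
                               ) -> Callable[[Mapping[str, float]], dict]:
    """Objective mapping ``{'region/channel': factor}`` to spike features."""
    def objective(params: Mapping[str, float]) -> dict[str, float]:
        b = dict(bindings)
        for name, factor in params.items():
            region, _, channel = name.partition("/")
            b = scale_conductance(b, region, channel, factor)
        res = simulate(model, b, None, protocol, settle_ms=settle_ms)
        return spike_features(res, site)

    return objective


def _loss(features: Mapping[str, float], spec: FitSpec) -> float:
    w = dict(spec.weights or {})
    total = 0.0
    for fname, target in spec.targets.items():
        scale = max(abs(target), 1.0)
        resid = (features[fname] - target) / scale
        total += w.get(fname, 1.0) * resid * resid
    return total


def metropolis_hastings_fit(spec: FitSpec,
                            objective: Callable[[Mapping[str, float]], Mapping[str, float]],
                            initial: Mapping[str, float] | None = None
                            ) -> FitResult:
    """Random-walk Metropolis-Hastings over positive bounded parameters.

    Symmetric Gaussian proposals in log space; a proposal outside its bounds
    is rejected outright (uniform prior on the box).  Acceptance probability
    ``min(1, exp((loss - loss') / (2 sigma^2)))`` so a strictly better
    proposal is always accepted.  Identical seeds give identical chains.
    """
    rng = np.random.default_rng(spec.seed)
    names = [p[0] for p in spec.params]
    lo = np.array([p[1] for p in spec.params])
    hi = np.array([p[2] for p in spec.params])
    if initial is not None:
        x = np.array([initial[n] for n in names], dtype=float)
    else:
        x = np.sqrt(lo * hi)  # geometric midpoint of the box
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("initial point outside bounds")

    loss = _loss(objective(dict(zip(names, x))), spec)
    best_x, best_loss = x.copy(), loss
    two_s2 = 2.0 * spec.feature_sigma**2
    rows = []
    n_accept = 0
    for it in range(spec.chain_length):
        step = rng.normal(0.0, spec.proposal_scale, size=len(names))
        cand = x * np.exp(step)
        if np.any(cand < lo) or np.any(cand > hi):
            accepted = False
            cand_loss = np.inf
        else:
            cand_loss = _loss(objective(dict(zip(names, cand))), spec)
            log_ratio = (loss - cand_loss) / two_s2
            accepted = np.log(rng.uniform()) < log_ratio
        if accepted:
            x, loss = cand, cand_loss
            n_accept += 1
            if loss < best_loss:
                best_x, best_loss = x.copy(), loss
        rows.append({**dict(zip(names, x)), "loss": loss,
                     "accepted": bool(accepted)})

    rate = n_accept / spec.chain_length
    if n_accept == 0:
        warnings.warn(
            "Metropolis-Hastings chain accepted no proposals; the proposal "
            f"scale ({spec.proposal_scale}) is likely too wide for the "
            "posterior, or the initial point is a strong optimum.",
            RuntimeWarning,
        )
    return FitResult(
        chain=pd.DataFrame(rows),
        best_params=dict(zip(names, best_x)),
        best_loss=float(best_loss),
        acceptance_rate=rate,
        metadata={
            "seed": spec.seed,
            "loss_form": "gaussian-normalised-features (declared default)",
            "proposal": "log-space gaussian random walk",
        },
    )
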