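"""Dissipative (λ-ensemble) trajectory analysis on Markov state models.

Each jump i→j of a reversible Markov chain produces entropy
``q_ij = ln(T_ij / T_ji)`` (kT units; antisymmetric, zero on the
diagonal). Exponentially tilting the path ensemble by its accumulated
dissipation, with bias strength λ, reweights every path by
``exp((λ-1) Σ q)``; λ = 1 is the unbiased ensemble and λ = 2 the
dissipative ensemble used here. The tilted path sum is generated by the
matrix

``T̃_ij(λ) = T_ij · exp((λ-1) q_ij) = T_ij^λ / T_ji^(λ-1)``

which reduces to T at λ = 1 and is generally *not* stochastic — its powers
accumulate the path weights, and only the final state distribution is
normalized (the conditional distribution of the biased ensemble).

The dissipative free energy change of a state is the negative log-ratio of
its probability in the biased (λ = 2) vs unbiased (λ = 1) ensembles at the
probe time; negative values mark states *enriched* by dissipative
dynamics. For a detailed-balanced chain the per-path dissipation
telescopes to ``ln(π_end/π_start)``, a useful closed-form check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EstimationError, NumericalError
from .geometry import FeatureMatrix
from .landscape import LandscapeGrid, ProbabilityEvolution, _auto_edges, _deposit, propagate
from .msm import MarkovModel

__all__ = [
    "TiltedEnsembleResult",
    "jump_dissipation",
    "tilt_matrix",
    "biased_propagate",
    "dissipation_surface",
]


@dataclass
class TiltedEnsembleResult:
    """Per-state dissipative free energy changes at multiples of the lag.

    ``delta_F[k, i] = -ln(p̃_i(kτ) / p_i(kτ))`` with p̃ the (normalized)
    biased and p the unbiased distribution; NaN marks states whose
    unbiased probability is zero (undefined ratio). ``log_partition[k]``
    is the log of the total biased path weight, so the *raw* (unnormalized)
    convention is recovered as ``delta_F - log_partition`` per time.
    """

    lambda_bias: float
    times_ns: np.ndarray
    delta_F: np.ndarray  # (n_times, n_states), kT
    biased_distributions: np.ndarray
    unbiased_distributions: np.ndarray
    log_partition: np.ndarray

    def delta_F_raw(self) -> np.ndarray:
        """Raw-weight convention: -ln(w̃_i(t)/p_i(t)) without normalization."""
        return self.delta_F - self.log_partition[:, None]

    def to_dataframe(self):
        import pandas as pd

        n_times, n_states = self.delta_F.shape
        return pd.DataFrame(
            {
                "time_ns": np.repeat(self.times_ns, n_states),
                "state": np.tile(np.arange(n_states), n_times),
                "delta_F_kT": self.delta_F.ravel(),
                "lambda": self.lambda_bias,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def jump_dissipation(model: MarkovModel) -> np.ndarray:
    """Per-jump entropy production ``q_ij = ln(T_ij/T_ji)`` on edges.

    Requires the edge set to be symmetric (T_ij > 0 ⇔ T_ji > 0), which the
    symmetrized estimator guarantees; a one-sided edge is a contract
    violation. Non-edges carry 0 in the returned matrix (they never enter
    tilted products because T_ij = 0 there).
    """
    t = model.transition_matrix
    fwd = t > 0
    if not np.array_equal(fwd, fwd.T):
        bad = np.argwhere(fwd & ~fwd.T)
        i, j = bad[0]
        raise EstimationError(
            f"one-sided edge {i}->{j}: T[{i},{j}] > 0 but T[{j},{i}] = 0; "
            "jump dissipation requires a symmetric edge set"
        )
    q = np.zeros_like(t)
    mask = fwd & ~np.eye(t.shape[0], dtype=bool)
    q[mask] = np.log(t[mask] / t.T[mask])
    return q


def tilt_matrix(model: MarkovModel, lambda_bias: float) -> np.ndarray:
    """Tilted generator ``T̃_ij = T_ij exp((λ-1) q_ij)``.

    λ = 1 returns T exactly. The result is generally not row-stochastic
    and is deliberately never renormalized: its k-th power is the weighted
    path sum of the λ-ensemble.
    """
    if not np.isfinite(lambda_bias):
        raise NumericalError("lambda_bias must be finite")
    t = model.transition_matrix
    if lambda_bias == 1.0:
        return t.copy()
    q = jump_dissipation(model)
    return t * np.exp((lambda_bias - 1.0) * q)


def biased_propagate(
    model: MarkovModel,
    lambda_bias: float,
    p0: np.ndarray,
    n_steps: int,
) -> TiltedEnsembleResult:
    """Propagate the λ-tilted path ensemble and compare to the unbiased one.

    ``p̃(kτ) ∝ p0 · T̃ᵏ`` renormalized at each step (the accumulated log
    normalization is tracked so raw weights remain recoverable and the
    propagation cannot underflow); ``delta_F_i = -ln(p̃_i/p_i)`` against the
    unbiased propagation from the same ``p0``.
    """
    unbiased = propagate(model, p0, n_steps)
    t_tilt = tilt_matrix(model, lambda_bias)
    n = model.n_states
    p = np.asarray(p0, float) / np.sum(p0)
    dists = np.empty((n_steps + 1, n))
    logz = np.zeros(n_steps + 1)
    dists[0] = p
    acc = 0.0
    for k in range(1, n_steps + 1):
        nxt = dists[k - 1] @ t_tilt
        total = nxt.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise NumericalError(
                f"biased mass underflowed/overflowed at step {k} (total={total}); "
                "per-step renormalization failed — propagate in log space"
            )
        acc += np.log(total)
        dists[k] = nxt / total
        logz[k] = acc
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dists / unbiased.distributions
        delta = -np.log(ratio)
    delta = np.where(unbiased.distributions > 0, delta, np.nan)
    # where both are zero the ratio is 0/0; keep NaN. Where biased is zero
    # but unbiased positive, delta is +inf (state never reached by biased
    # paths) — that is a legitimate value, not an error.
    delta = np.where(
        (unbiased.distributions > 0) & (dists == 0.0), np.inf, delta
    )
    if lambda_bias == 1.0:
        delta = np.where(unbiased.distributions > 0, 0.0, np.nan)
    return TiltedEnsembleResult(
        lambda_bias=lambda_bias,
        times_ns=unbiased.times_ns,
        delta_F=delta,
        biased_distributions=dists,
        unbiased_distributions=unbiased.distributions,
        log_partition=logz,
    )


def dissipation_surface(
    result: TiltedEnsembleResult,
    representatives: Mapping[int, np.ndarray],
    features: FeatureMatrix,
    op_pair: tuple[str, str],
    bins: int | tuple[np.ndarray, np.ndarray] = 50,
    time_indices: Sequence[int] | None = None,
) -> LandscapeGrid:
    """Project dissipative free energy changes onto an order-parameter pair.

    Biased and unbiased distributions are deposited with identical
    representative draws and identical bins; the surface is
    ``-ln(mass_biased / mass_unbiased)`` per bin. Bins unoccupied in the
    unbiased projection are marked unoccupied (+inf placeholder).
    """
    xvals = features.column(op_pair[0])
    yvals = features.column(op_pair[1])
    if isinstance(bins, int):
        x_edges = _auto_edges(xvals, bins)
        y_edges = _auto_edges(yvals, bins)
    else:
        x_edges, y_edges = (np.asarray(b, float) for b in bins)
    if time_indices is None:
        time_indices = range(len(result.times_ns))
    time_indices = list(time_indices)
    mass_b = _deposit(
        result.biased_distributions[time_indices], representatives, xvals, yvals, x_edges, y_edges
    )
    mass_u = _deposit(
        result.unbiased_distributions[time_indices], representatives, xvals, yvals, x_edges, y_edges
    )
    mass_b /= mass_b.sum(axis=(1, 2), keepdims=True)
    mass_u /= mass_u.sum(axis=(1, 2), keepdims=True)
    occupied = mass_u > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = -np.log(np.where(occupied, mass_b, 1.0) / np.where(occupied, mass_u, 1.0))
    delta = np.where(occupied, delta, np.inf)
    return LandscapeGrid(
        op_names=(op_pair[0], op_pair[1]),
        x_edges=x_edges,
        y_edges=y_edges,
        times_ns=result.times_ns[time_indices],
        free_energy=delta,
        occupied=occupied,
    )
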