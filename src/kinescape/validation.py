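"""Markov model validation.

Two standard diagnostics:

* **Implied relaxation timescales.** For each candidate lag τ a model is
  built (count → trim → estimate) and the relaxation times
  ``t_k = -τ / ln μ_k`` of its top non-unit eigenvalues are reported.
  Lag-independence of the timescales beyond some τ indicates the dynamics
  are Markovian at that lag, which is the usual heuristic for choosing it.

* **Chapman–Kolmogorov basin-escape test.** The probability of remaining
  in a chosen basin of states after k lag times, predicted by propagating
  the model (``T^k``), is compared against the same quantity measured
  directly from the raw discrete trajectories, with binomial standard
  errors. Agreement within sampling error validates the model's
  memorylessness on the slow process of escaping that basin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EstimationError
from .msm import DiscreteTrajectorySet, MarkovModel, build_msm

__all__ = ["TimescaleScan", "CKComparison", "implied_timescales", "ck_test"]


@dataclass
class TimescaleScan:
    """Implied relaxation timescales per lag.

    ``timescales[i, k]`` is the k-th slowest relaxation time (ns) at
    ``lags_ns[i]``; NaN marks eigenvalues that were non-positive at that
    lag (undefined timescale, never fabricated).
    """

    lags_ns: np.ndarray
    timescales: np.ndarray
    n_states: np.ndarray  # post-trim model size per lag

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, lag in enumerate(self.lags_ns):
            for k in range(self.timescales.shape[1]):
                rows.append(
                    {
                        "lag_ns": lag,
                        "rank": k + 1,
                        "timescale_ns": self.timescales[i, k],
                        "n_states": self.n_states[i],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CKComparison:
    """Model vs empirical basin-survival curves at multiples of the lag."""

    basin: np.ndarray
    probe_multiples: np.ndarray
    times_ns: np.ndarray
    model_curve: np.ndarray
    empirical_curve: np.ndarray
    empirical_se: np.ndarray
    n_samples: np.ndarray

    def max_z(self) -> float:
        """Largest |model - empirical| in units of the empirical SE."""
        se = np.where(self.empirical_se > 0, self.empirical_se, np.inf)
        return float(np.max(np.abs(self.model_curve - self.empirical_curve) / se))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": self.probe_multiples,
                "time_ns": self.times_ns,
                "model_survival": self.model_curve,
                "empirical_survival": self.empirical_curve,
                "empirical_se": self.empirical_se,
                "n_samples": self.n_samples,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def implied_timescales(
    trajs: DiscreteTrajectorySet,
    lags_steps: Sequence[int],
    n_timescales: int = 3,
    mode: str = "sliding",
) -> TimescaleScan:
    """Scan implied relaxation timescales over candidate lag times.

    Estimation failures at a single lag (e.g. no countable transitions)
    yield a NaN row rather than aborting the scan.
    """
    lags_steps = list(lags_steps)
    if not lags_steps:
        raise EstimationError("no lags given")
    dt = trajs.frame_interval_ns
    ts = np.full((len(lags_steps), n_timescales), np.nan)
    ns = np.zeros(len(lags_steps), dtype=int)
    for i, lag in enumerate(lags_steps):
        try:
            model, _, _ = build_msm(trajs, lag, mode=mode)
        except EstimationError:
            continue
        ns[i] = model.n_states
        evals = model.eigenvalues(k=n_timescales + 1)[1:]  # drop the Perron root
        if evals.size and evals.max() >= 1.0 - 1e-12:
            raise EstimationError(
                f"lag {lag}: non-Perron eigenvalue at 1 — disconnected components "
                "survived trimming"
            )
        tau = lag * dt
        for k, mu in enumerate(evals[:n_timescales]):
            if mu > 0:
                ts[i, k] = -tau / np.log(mu)
    return TimescaleScan(
        lags_ns=np.asarray(lags_steps, float) * dt,
        timescales=ts,
        n_states=ns,
    )


def ck_test(
    model: MarkovModel,
    trajs: DiscreteTrajectorySet,
    basin: Sequence[int],
    probe_multiples: Sequence[int],
    lag_steps: int | None = None,
) -> CKComparison:
    """Chapman–Kolmogorov basin-escape test.

    Model curve: start from the stationary distribution restricted to the
    basin (renormalized), propagate k lag steps, sum the probability still
    inside the basin. Empirical curve: over all frames in the basin, the
    fraction whose frame k·lag later (same trajectory) is still in the
    basin, with binomial standard errors. ``trajs`` must be labeled in the
    model's (post-trim) state space.
    """
    basin = np.asarray(sorted(set(int(b) for b in basin)), dtype=int)
    if basin.size == 0:
        raise EstimationError("basin is empty")
    if basin.min() < 0 or basin.max() >= model.n_states:
        raise EstimationError(
            f"basin states {basin.tolist()} outside model state space [0, {model.n_states})"
        )
    probes = np.asarray(sorted(set(int(k) for k in probe_multiples)), dtype=int)
    if np.any(probes < 0):
        raise EstimationError("probe multiples must be >= 0")
    if lag_steps is None:
        lag_steps = int(round(model.lag_ns / trajs.frame_interval_ns))
        if not np.isclose(lag_steps * trajs.frame_interval_ns, model.lag_ns):
            raise EstimationError("model lag is not a multiple of the frame interval")

    in_basin = np.isin(trajs.state_labels, basin)
    if not np.any(in_basin & (trajs.state_labels >= 0)):
        raise EstimationError(f"basin {basin.tolist()} never visited in the data")

    # model curve
    p = np.zeros(model.n_states)
    p[basin] = model.stationary[basin]
    p /= p.sum()
    t_mat = model.transition_matrix
    model_curve = np.empty(probes.size)
    emp = np.empty(probes.size)
    se = np.empty(probes.size)
    n_samp = np.zeros(probes.size, dtype=int)
    k_max = probes.max() if probes.size else 0
    survived = {0: 1.0}
    pk = p.copy()
    curve_at = {}
    for k in range(k_max + 1):
        if k > 0:
            pk = pk @ t_mat
        curve_at[k] = float(pk[basin].sum())
    basin_mask_by_segment = []
    for _, labels in trajs.segments():
        basin_mask_by_segment.append((labels, np.isin(labels, basin)))
    for j, k in enumerate(probes):
        model_curve[j] = curve_at[k]
        shift = k * lag_steps
        hits = 0
        total = 0
        for labels, mask in basin_mask_by_segment:
            if shift >= labels.size:
                continue
            start = mask[: labels.size - shift] if shift else mask
            later = mask[shift:]
            valid = start & (labels[: labels.size - shift] >= 0) if shift else start
            total += int(valid.sum())
            hits += int((valid & later).sum())
        if total == 0:
            emp[j] = np.nan
            se[j] = np.nan
        else:
            phat = hits / total
            emp[j] = phat
            se[j] = np.sqrt(max(phat * (1 - phat), 0.0) / total)
        n_samp[j] = total
    return CKComparison(
        basin=basin,
        probe_multiples=probes,
        times_ns=probes * lag_steps * trajs.frame_interval_ns,
        model_curve=model_curve,
        empirical_curve=emp,
        empirical_se=se,
        n_samples=n_samp,
    )
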