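"""Model / Results interface for fitting co-evolution models to panels.

``CoevolutionModel`` binds a :class:`~coevnet.panel.CoevolutionPanel` to a
:class:`~coevnet.effects.ModelSpec`; ``fit`` runs the Robbins-Monro
method-of-moments estimator and returns a ``CoevolutionResults`` carrying
estimates, standard errors and convergence diagnostics, with a formatted
``summary()`` table.  Forward simulation at arbitrary parameter values
hangs off the model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .effects import EffectContext, ModelSpec
from .estimate import (
    CONVERGENCE_T_THRESHOLD,
    EstimationResult,
    EstimationSettings,
    convergence_check,
    initial_theta,
    observed_targets,
    robbins_monro,
)
from .panel import CoevolutionPanel
from .report import significance_marker
from .simulate import simulate_panel

__all__ = ["CoevolutionModel", "CoevolutionResults"]


class CoevolutionModel:
    """A stochastic actor-based co-evolution model bound to observed data."""

    def __init__(self, panel: CoevolutionPanel, spec: ModelSpec) -> None:
        if spec.n_periods != panel.n_periods:
            raise ValueError(
                f"spec has {spec.n_periods} periods but panel has {panel.n_periods}"
            )
        self.panel = panel
        self.spec = spec
        self.context = EffectContext.from_panel(panel)

    @classmethod
    def from_files(
        cls,
        network_paths: Sequence[str],
        behavior_path: str,
        covariate_path: str,
        spec: ModelSpec,
    ) -> "CoevolutionModel":
        from .panel import read_panel

        return cls(read_panel(network_paths, behavior_path, covariate_path), spec)

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names()

    def start_params(self) -> np.ndarray:
        return initial_theta(self.panel, self.spec)

    def observed_targets(self) -> np.ndarray:
        return observed_targets(self.panel, self.spec, self.context)

    def fit(
        self,
        start_params: np.ndarray | None = None,
        settings: EstimationSettings | None = None,
        seed: int | np.random.Generator | None = None,
    ) -> "CoevolutionResults":
        """Estimate theta by Robbins-Monro stochastic approximation."""
        result = robbins_monro(
            self.panel, self.spec, init=start_params, settings=settings, rng=seed
        )
        return CoevolutionResults(self, result)

    def simulate(
        self,
        theta: np.ndarray,
        seed: int | np.random.Generator | None = None,
        keep_trace: bool = False,
    ):
        """Forward-simulate a panel from the observed first wave at theta."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return simulate_panel(
            self.panel.networks[0],
            self.panel.behaviors[0],
            self.panel.covariates,
            np.asarray(theta, dtype=float),
            self.spec,
            rng,
            ctx=self.context,
            keep_trace=keep_trace,
        )


class CoevolutionResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    def __init__(self, model: CoevolutionModel, result: EstimationResult) -> None:
        self.model = model
        self._result = result
        names = result.param_names
        self.params = pd.Series(result.theta_hat, index=names, name="theta")
        self.bse = pd.Series(result.standard_errors, index=names, name="se")
        self.convergence_t = pd.Series(result.convergence_t, index=names, name="conv_t")
        self.observed_targets = pd.Series(result.observed, index=names)
        self.simulated_targets_mean = pd.Series(result.simulated_mean, index=names)

    @property
    def converged(self) -> bool:
        """True iff every |convergence t-ratio| < 0.1."""
        return self._result.converged

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    def convergence_report(self):
        return convergence_check(self._result)

    def to_frame(self) -> pd.DataFrame:
        frame = self._result.to_frame()
        rate_mask = self.model.spec.is_rate()
        frame["sig"] = [
            "" if rate else significance_marker(beta, se) if se > 0 else ""
            for beta, se, rate in zip(frame["theta"], frame["se"], rate_mask)
        ]
        return frame

    def summary(self) -> str:
        """Aligned text table: effect, estimate, s.e., significance, conv t."""
        frame = self.to_frame()
        spec = self.model.spec
        lines = ["Stochastic actor-based co-evolution model", ""]
        lines.append(
            f"{'Effect':44s} {'theta':>8s} {'s.e.':>7s} {'':3s} {'conv_t':>7s}"
        )
        lines.append("-" * 72)
        n_net_block = spec.n_network_rates + spec.n_behavior_rates + len(
            spec.network_effects
        )
        headers = {
            0: "Rate parameters",
            spec.n_network_rates + spec.n_behavior_rates: "Network equation",
            n_net_block: "Behavior equation",
        }
        for pos, (name, row) in enumerate(frame.iterrows()):
            if pos in headers:
                lines.append(f"[{headers[pos]}]")
            lines.append(
                f"{name:44s} {row['theta']:8.3f} {row['se']:7.3f} "
                f"{row['sig']:3s} {row['conv_t']:7.3f}"
            )
        lines.append("-" * 72)
        status = "yes" if self.converged else "NO"
        lines.append(
            f"Converged (all |t| < {CONVERGENCE_T_THRESHOLD}): {status}   "
            f"phase-3 simulations: {self._result.n_phase3}"
        )
        lines.append("Significance: *** p<0.001, ** p<0.01, * p<0.05, † p<0.1 "
                     "(two-sided normal approximation)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        status = "converged" if self.converged else "not converged"
        return f"<CoevolutionResults: {len(self.params)} parameters, {status}>"
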