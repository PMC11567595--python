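"""statsmodels-style front end: a model object built from a dataset whose
``fit`` returns a results object carrying the posterior.

    >>> model = XaGenerationModel(dataset)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> bands = res.prediction_bands(ExperimentCondition.one(0.128), times)
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import (
    Chain,
    FitConfig,
    LogLikelihood,
    ParameterSpace,
    PosteriorSummary,
    prediction_bands,
    run_four_step,
)
from .protocols import Dataset, ExperimentCondition, ObservableMapping

__all__ = ["XaGenerationModel", "XaGenerationResults"]


class XaGenerationModel:
    """Bayesian kinetic model of activated-factor-X generation.

    Wraps a measurement :class:`~tfpikinetics.protocols.Dataset` together
    with the constrained parameter space and the proportional-error
    likelihood; ``fit`` runs the four-step estimation.
    """

    def __init__(
        self,
        dataset: Dataset,
        variant: str = "full",
        observable: ObservableMapping = "free_xa",
        sigma_max: float = 1.0,
        free_k_minus_4: bool = False,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.dataset = dataset
        self.space = ParameterSpace(
            variant=variant, sigma_max=sigma_max, free_k_minus_4=free_k_minus_4
        )
        self.observable = observable
        self.loglike = LogLikelihood(dataset, self.space, observable, rtol, atol)
        self._config_fields = dict(
            variant=variant, mapping=observable, sigma_max=sigma_max,
            free_k_minus_4=free_k_minus_4, rtol=rtol, atol=atol,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "XaGenerationModel":
        return cls(Dataset.from_frame(df), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "XaGenerationModel":
        return cls(Dataset.from_csv(path), **kwargs)

    @property
    def exog_names(self) -> tuple[str, ...]:
        return self.space.names

    def loglikelihood(self, theta: np.ndarray) -> float:
        return self.loglike(theta)

    def fit(self, config: FitConfig | None = None, **overrides) -> "XaGenerationResults":
        """Run the four-step estimation (LHS pre-exploration, fixed-proposal
        Metropolis, adaptive Metropolis, thinning) and return the results."""
        if config is None:
            config = FitConfig(**{**self._config_fields, **overrides})
        elif overrides:
            config = replace(config, **overrides)
        thinned, summary = run_four_step(self.loglike, self.space, config)
        return XaGenerationResults(self, thinned, summary, config)


class XaGenerationResults:
    """Posterior results of :meth:`XaGenerationModel.fit`."""

    def __init__(
        self,
        model: XaGenerationModel,
        chain: Chain,
        summary: PosteriorSummary,
        config: FitConfig,
    ):
        self.model = model
        self.chain = chain
        self._summary = summary
        self.config = config

    @property
    def params(self) -> pd.Series:
        """Posterior medians of the free parameters."""
        t = self._summary.table
        free = t[t["kind"] == "free"]
        return pd.Series(free["median"].to_numpy(), index=free["parameter"])

    def conf_int(self, kind: str | None = None) -> pd.DataFrame:
        """95% equal-tailed credible intervals (free parameters by
        default; ``kind='derived'`` for the derived constants)."""
        t = self._summary.table
        if kind is not None:
            t = t[t["kind"] == kind]
        return t.set_index("parameter")[["ci_lower", "ci_upper"]]

    def summary(self) -> PosteriorSummary:
        return self._summary

    def predict(
        self, condition: ExperimentCondition, times: Sequence[float]
    ) -> np.ndarray:
        """Model prediction mu(t) at the posterior-median parameters."""
        theta = self.params.reindex(list(self.model.space.names)).to_numpy()
        return self.model.loglike.predict(theta, condition, np.asarray(times, float))

    def prediction_bands(
        self,
        condition: ExperimentCondition,
        times: Sequence[float],
        levels: Sequence[float] = (0.70, 0.90, 0.99),
        max_draws: int | None = 400,
        seed=0,
    ) -> pd.DataFrame:
        return prediction_bands(
            self.chain, condition, times, self.model.loglike,
            levels=levels, max_draws=max_draws, seed=seed,
        )

    def manifest(self) -> dict:
        """Reproducibility record: seeds, counts, bounds, fixed constants."""
        space = self.model.space
        return {
            "config": asdict(self.config),
            "param_names": list(space.names),
            "bounds_upper": [float(v) for v in space.upper],
            "fixed_constants": {
                "K_M_nM": space.K_M, "K_D3_nM": space.K_D3, "K_D4_nM": space.K_D4,
            },
            "n_measurements": {
                "experiment_1": self.model.dataset.n_measurements(1),
                "experiment_2": self.model.dataset.n_measurements(2),
            },
            "acceptance_rate": self.chain.acceptance_rate,
            "lag1_autocorr": self.chain.diagnostics.get("lag1_autocorr", {}),
        }

    def save(self, outdir: str | Path) -> None:
        """Persist chain CSV, summary CSV and the run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.chain.to_csv(outdir / "chain.csv")
        self._summary.to_csv(outdir / "summary.csv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2) + "\n"
        )
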