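"""Statsmodels-style front end: ExtinctionRiskModel / ExtinctionRiskResults.

The model holds the assembled feature matrix and the Red-List-derived
binary response; ``fit()`` grows the conditional inference forest and
returns a results object carrying per-species probabilities, the
max-kappa classification threshold, cross-validated skill, permutation
importance, partial dependence, and the geographic risk products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cif import ConditionalInferenceForest, ForestConfig
from .evaluate import CVResult, cross_validate, max_kappa_threshold
from .geography import (
    DEFAULT_LATENT_STATUSES,
    RiskAssessment,
    attribution_map,
    attribution_scores,
    build_risk_sets,
    mean_velocity_per_species,
)
from .interpret import (
    ImportanceTable,
    PDCurve,
    partial_dependence,
    permutation_importance,
    reference_profile,
)
from .traits import dichotomize_series
from .zonal import DEFAULT_FEATURES, FeatureMatrix

__all__ = ["ExtinctionRiskModel", "ExtinctionRiskResults"]


class ExtinctionRiskModel:
    """Conditional-inference-forest model of species threat status.

    Parameters
    ----------
    features
        Assembled :class:`FeatureMatrix` (intrinsic + extrinsic columns).
    statuses
        Red List codes per species (index-aligned with the features).
        Data Deficient species are unlabeled: scored but never trained on.
    config
        Forest hyperparameters (500 trees by default).
    feature_columns
        Subset/order of feature columns to model; defaults to every
        column in the matrix.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        statuses: pd.Series,
        config: ForestConfig | None = None,
        feature_columns: list[str] | None = None,
    ):
        self.features = features
        self.statuses = statuses.reindex(features.data.index)
        self.config = config or ForestConfig()
        self.feature_columns = list(feature_columns or features.feature_names)
        self.labels = dichotomize_series(self.statuses)
        self._X, self._names, self._kinds = features.to_matrix(self.feature_columns)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        rasters: dict,
        atlas,
        config: ForestConfig | None = None,
        feature_columns: list[str] | None = None,
        **assemble_kwargs,
    ) -> "ExtinctionRiskModel":
        """Build the model straight from a trait table, raster stack and
        range atlas (runs the zonal extraction)."""
        from .zonal import assemble_features

        features = assemble_features(table, rasters, atlas, **assemble_kwargs)
        statuses = table.set_index("species_id")["redlist_status"]
        cols = feature_columns or [c for c in DEFAULT_FEATURES if c in features.feature_names]
        return cls(features, statuses, config=config, feature_columns=cols)

    @property
    def n_species(self) -> int:
        return len(self.features.data)

    @property
    def n_labeled(self) -> int:
        return int((~self.labels.isna()).sum())

    def fit(self, seed: int = 0) -> "ExtinctionRiskResults":
        forest = ConditionalInferenceForest.fit(
            self._X, self.labels.to_numpy(dtype=float), self._names, self._kinds,
            config=self.config, seed=seed,
        )
        probabilities = pd.Series(
            forest.predict_proba(self._X), index=self.features.data.index,
            name="probability",
        )
        labeled = ~self.labels.isna()
        threshold = max_kappa_threshold(
            probabilities[labeled].to_numpy(), self.labels[labeled].to_numpy()
        )
        return ExtinctionRiskResults(
            model=self, forest=forest, probabilities=probabilities,
            threshold=threshold, seed=seed,
        )


@dataclass
class ExtinctionRiskResults:
    """Fitted forest plus the derived per-species assessments.

    ``threshold`` is the max-kappa cutoff from the full-data fit's
    in-sample scores; after :meth:`cross_validate` the pooled-holdout
    threshold (the canonical one) is used for risk sets instead.
    """

    model: ExtinctionRiskModel
    forest: ConditionalInferenceForest
    probabilities: pd.Series
    threshold: float
    seed: int
    cv_result: CVResult | None = None
    _profile: dict | None = field(default=None, repr=False)

    # -- evaluation -------------------------------------------------------

    def cross_validate(self, k: int = 10, seed: int | None = None) -> CVResult:
        labeled = ~self.model.labels.isna()
        idx = np.nonzero(labeled.to_numpy())[0]
        self.cv_result = cross_validate(
            self.model._X[idx], self.model.labels.to_numpy(dtype=float)[idx],
            self.model._names, self.model._kinds,
            k=k, config=self.model.config,
            seed=self.seed if seed is None else seed,
        )
        return self.cv_result

    @property
    def classification_threshold(self) -> float:
        """Pooled cross-validated max-kappa threshold when available,
        else the full-fit in-sample one."""
        if self.cv_result is not None:
            return self.cv_result.threshold
        return self.threshold

    # -- interpretation ---------------------------------------------------

    def reference_profile(self) -> dict:
        if self._profile is None:
            self._profile = reference_profile(self._features_modeled())
        return self._profile

    def _features_modeled(self) -> FeatureMatrix:
        fm = self.model.features
        return FeatureMatrix(
            data=fm.data[self.model.feature_columns],
            kinds={k: fm.kinds[k] for k in self.model.feature_columns},
            levels={k: list(v) for k, v in fm.levels.items() if k in self.model.feature_columns},
        )

    def variable_importance(self, n_reps: int = 5, seed: int | None = None) -> ImportanceTable:
        return permutation_importance(
            self.forest, self.model._X, self.model.labels.to_numpy(dtype=float),
            n_reps=n_reps, seed=self.seed if seed is None else seed,
        )

    def partial_dependence(self, feature: str, n_grid: int = 50) -> PDCurve:
        return partial_dependence(
            self.forest, self._features_modeled(), feature,
            n_grid=n_grid, profile=self.reference_profile(),
        )

    # -- geography --------------------------------------------------------

    def attribution_scores(self, focal: str) -> pd.Series:
        return attribution_scores(
            self.forest, self._features_modeled(), focal, profile=self.reference_profile()
        )

    def attribution_map(self, focal: str, atlas):
        return attribution_map(self.attribution_scores(focal), atlas)

    def risk_sets(
        self,
        latent_statuses=DEFAULT_LATENT_STATUSES,
        velocity_grid=None,
        atlas=None,
    ) -> RiskAssessment:
        velocities = None
        if velocity_grid is not None and atlas is not None:
            velocities = mean_velocity_per_species(velocity_grid, atlas)
        return build_risk_sets(
            self.probabilities, self.model.statuses, self.classification_threshold,
            latent_statuses=latent_statuses, velocities=velocities,
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels tradition."""
        lines = []
        prevalence = float(self.model.labels.mean())
        lines.append("Extinction risk conditional inference forest")
        lines.append("=" * 52)
        lines.append(f"Species (total / labeled):  {self.model.n_species} / {self.model.n_labeled}")
        lines.append(f"Features:                   {len(self.model.feature_columns)}")
        lines.append(f"Trees:                      {self.forest.n_trees}")
        lines.append(f"At-risk prevalence:         {prevalence:.3f}")
        lines.append(f"Max-kappa threshold (fit):  {self.threshold:.3f}")
        if self.cv_result is not None:
            p = self.cv_result.pooled
            lines.append("-" * 52)
            lines.append("10-fold cross-validation (pooled holdout)")
            lines.append(f"  AUC          {p['auc']:.3f}")
            lines.append(f"  accuracy     {p['accuracy']:.3f}")
            lines.append(f"  sensitivity  {p['sensitivity']:.3f}")
            lines.append(f"  specificity  {p['specificity']:.3f}")
            lines.append(f"  kappa        {p['kappa']:.3f}")
            lines.append(f"  threshold    {p['threshold']:.3f}")
        lines.append("=" * 52)
        return "\n".join(lines)
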