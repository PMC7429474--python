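"""End-to-end analysis: counts -> filtered fitness -> error model -> merged scores."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alt_models import (
    BayesRegularizedErrorModel,
    Enrich2ErrorModel,
    VarianceErrorModel,
    count_based_error,
)
from .error_model import ErrorModelParams, FitConfig, fit_error_model, predict_variant_error
from .fitness import (
    FitnessTable,
    NormalizationParams,
    compute_fitness,
    merge_replicates,
    normalize_scale_shift,
)
from .io import (
    ExperimentDesign,
    HighConfidenceSelection,
    ThresholdPolicy,
    VariantCountTable,
    apply_count_thresholds,
    filter_substitutions,
    select_high_confidence,
)


@dataclass
class AnalysisResult:
    """All intermediate and final products of one analysis run."""

    counts: VariantCountTable
    design: ExperimentDesign
    mask: pd.DataFrame
    fitness: FitnessTable
    normalization: NormalizationParams | None
    high_confidence: HighConfidenceSelection
    params: ErrorModelParams | None
    variance: pd.DataFrame
    merged: pd.DataFrame

    def fitness_frame(self) -> pd.DataFrame:
        """Wide per-variant output table (per-replicate and merged scores)."""
        out = pd.DataFrame(index=self.fitness.fitness.index)
        out["n_subs"] = self.fitness.n_subs
        for rep in self.fitness.replicate_ids:
            out[f"fitness_{rep}"] = self.fitness.fitness[rep]
            out[f"sigma_{rep}"] = np.sqrt(self.variance[rep])
        out["fitness"] = self.merged["fitness"]
        out["sigma"] = self.merged["sigma"]
        out["variance"] = self.merged["variance"]
        out["n_replicates_used"] = self.merged["n_replicates_used"]
        return out.rename_axis("variant_id")


def analyze(
    table: VariantCountTable,
    design: ExperimentDesign,
    policy: ThresholdPolicy | None = None,
    normalize: bool = True,
    error_model: str = "dimsum",
    config: FitConfig | None = None,
) -> AnalysisResult:
    """Run the full fitness/error workflow on a count table.

    Applies the substitution cap and hard/soft count thresholds, computes
    per-replicate log-enrichment fitness, optionally removes linear
    inter-replicate differences, fits the requested error model on the
    high-confidence pool, predicts per-variant errors and merges replicates
    by inverse-variance weighting.
    """
    policy = policy or ThresholdPolicy()
    config = config or FitConfig()
    table = filter_substitutions(table, policy)
    mask = apply_count_thresholds(table, design, policy)
    ft = compute_fitness(table, design, mask.to_numpy())
    norm = None
    if normalize and design.n_replicates >= 2:
        ft, norm = normalize_scale_shift(ft)
    hc = select_high_confidence(table, design)

    params = None
    if error_model == "dimsum":
        params = fit_error_model(ft, table, design, config, hc_mask=hc.mask)
        variance = predict_variant_error(params, table, design)
        variance = variance.where(ft.fitness.notna())
        merged = merge_replicates(ft, variance)
    elif error_model == "count":
        variance = ft.variance.copy()
        merged = merge_replicates(ft, variance)
    elif error_model == "enrich2":
        est = Enrich2ErrorModel().fit(
            ft.fitness.to_numpy(), table.input_counts(design), table.output_counts(design)
        )
        var = count_based_error(table.input_counts(design), table.output_counts(design))
        var = var + np.nan_to_num(est.s2_, nan=0.0)[:, None]
        variance = pd.DataFrame(var, index=ft.fitness.index, columns=ft.replicate_ids)
        variance = variance.where(ft.fitness.notna())
        merged = merge_replicates(ft, variance)
    elif error_model in ("variance", "bayesreg"):
        F = ft.fitness.to_numpy()
        if error_model == "variance":
            est = VarianceErrorModel().fit(F)
        else:
            est = BayesRegularizedErrorModel().fit(F, table.input_counts(design))
        variance = ft.variance.copy()  # per-replicate errors stay count-based
        merged = merge_replicates(ft, variance)
        merged["fitness"] = np.nanmean(F, axis=1)
        merged["variance"] = est.merged_variance_
        merged["sigma"] = np.sqrt(est.merged_variance_)
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return AnalysisResult(table, design, mask, ft, norm, hc, params, variance, merged)
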