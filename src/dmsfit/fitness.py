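"""Per-replicate fitness scores, replicate normalization and merging.

Fitness of variant i in replicate r is the natural-log enrichment relative
to the wild type::

    f_{r,i} = ln( (N_out_i / N_in_i) * (N_in_wt / N_out_wt) )

Error variances start from Poisson counting statistics, ``1/N_in + 1/N_out``
(wild-type count terms are omitted: wild-type counts are large and their
contribution negligible).  Replicates are optionally aligned by a linear
scale-and-shift, and per-variant scores are merged across replicates by
inverse-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExperimentDesign, VariantCountTable


@dataclass
class FitnessTable:
    """Per-variant, per-replicate fitness scores and error variances.

    ``fitness`` and ``variance`` are variants x replicates frames with NaN
    marking entries that are unusable (zero counts or threshold-masked).
    """

    fitness: pd.DataFrame
    variance: pd.DataFrame
    n_subs: pd.Series
    wild_type_id: str

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.fitness.columns)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.fitness.index.to_numpy()

    def usable(self) -> pd.DataFrame:
        return self.fitness.notna()

    def copy(self) -> "FitnessTable":
        return FitnessTable(
            self.fitness.copy(), self.variance.copy(), self.n_subs.copy(), self.wild_type_id
        )


@dataclass
class NormalizationParams:
    """Per-replicate linear correction ``g = scale * f + shift``."""

    replicate_ids: list[str]
    scale: np.ndarray
    shift: np.ndarray
    n_iter: int
    objective: float


def poisson_error(
    table: VariantCountTable,
    design: ExperimentDesign,
    mask: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Poisson (count-based) fitness variance: ``1/N_in + 1/N_out`` per replicate."""
    inp = table.input_counts(design)
    out = table.output_counts(design)
    ok = (inp > 0) & (out > 0)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    with np.errstate(divide="ignore"):
        var = np.where(ok, 1.0 / inp + 1.0 / out, np.nan)
    return pd.DataFrame(var, index=table.variant_ids, columns=design.replicate_ids)


def compute_fitness(
    table: VariantCountTable,
    design: ExperimentDesign,
    mask: pd.DataFrame | np.ndarray | None = None,
) -> FitnessTable:
    """Natural-log enrichment relative to wild type, per replicate.

    Entries with zero input or output counts (or masked out) are NaN.  The
    attached variance is the Poisson baseline.  Raises if any wild-type
    count is zero — the reference must be observed in every sample.
    """
    inp = table.input_counts(design)
    out = table.output_counts(design)
    wt = table.wildtype_index
    if (inp[wt] <= 0).any() or (out[wt] <= 0).any():
        raise ValueError("wild-type count of zero in a design sample")
    ok = (inp > 0) & (out > 0)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            ok,
            np.log(out / inp) + np.log(inp[wt] / out[wt])[None, :],
            np.nan,
        )
    fitness = pd.DataFrame(f, index=table.variant_ids, columns=design.replicate_ids)
    variance = poisson_error(table, design, mask)
    n_subs = pd.Series(table.n_subs, index=table.variant_ids, name="n_subs")
    return FitnessTable(fitness, variance, n_subs, table.variant_ids[wt])


def _alignment_objective(values: np.ndarray) -> float:
    return float(((values - values.mean(axis=1, keepdims=True)) ** 2).sum())


def normalize_scale_shift(
    ft: FitnessTable,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[FitnessTable, NormalizationParams]:
    """Remove linear inter-replicate differences in fitness scores.

    Fits a slope and offset per replicate minimizing the sum of squared
    deviations between each variant's corrected replicate scores and their
    average, subject to the geometric mean of the slopes being one (without
    this constraint the objective is trivially minimized by collapsing all
    scores to a point).  Solved by alternating least squares over variants
    usable in every replicate; converged when the relative objective change
    drops below ``tol``.  Finally all scores are shifted so that the
    wild-type fitness averages zero across replicates.
    """
    F_all = ft.fitness.to_numpy(dtype=float)
    n_rep = F_all.shape[1]
    if n_rep < 2:
        raise ValueError("normalization needs at least two replicates")
    complete = np.isfinite(F_all).all(axis=1)
    if complete.sum() < 2:
        raise ValueError("need at least two variants usable in all replicates")
    F = F_all[complete]
    fvar = F.var(axis=0)
    if (fvar <= 0).any():
        raise ValueError("a replicate has constant fitness; slope is undefined")
    fmean = F.mean(axis=0)

    scale = np.ones(n_rep)
    shift = np.zeros(n_rep)
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        G = F * scale + shift
        gbar = G.mean(axis=1)
        # per-replicate OLS of the per-variant averages on the raw scores
        cov = ((F - fmean) * (gbar - gbar.mean())[:, None]).mean(axis=0)
        new_scale = cov / fvar
        if (new_scale <= 0).any():
            raise ValueError("normalization produced a non-positive slope")
        new_scale /= np.exp(np.log(new_scale).mean())  # geometric mean = 1
        new_shift = gbar.mean() - new_scale * fmean
        scale, shift = new_scale, new_shift
        obj = _alignment_objective(F * scale + shift)
        if abs(prev - obj) <= tol * max(obj, 1.0):
            prev = obj
            break
        prev = obj

    # wild-type centering: average wild-type score across replicates -> 0
    wt_row = ft.fitness.index.get_loc(ft.wild_type_id)
    wt_scores = F_all[wt_row] * scale + shift
    shift = shift - np.nanmean(wt_scores)

    new_fitness = ft.fitness * scale + shift
    new_variance = ft.variance * scale**2
    params = NormalizationParams(ft.replicate_ids, scale, shift, it, prev)
    return (
        FitnessTable(new_fitness, new_variance, ft.n_subs.copy(), ft.wild_type_id),
        params,
    )


def merge_replicates(
    ft: FitnessTable,
    variance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Inverse-variance weighted average of fitness across replicates.

    Returns a frame indexed by variant with columns ``fitness`` (weighted
    mean), ``variance`` (``1 / sum(1/sigma^2)``), ``sigma`` and
    ``n_replicates_used``.  Variants usable in a single replicate pass
    through unchanged; variants usable nowhere get NaN.
    """
    var = ft.variance if variance is None else variance
    F = ft.fitness.to_numpy(dtype=float)
    V = var.to_numpy(dtype=float)
    ok = np.isfinite(F) & np.isfinite(V) & (V > 0)
    w = np.where(ok, 1.0 / np.where(ok, V, 1.0), 0.0)
    wsum = w.sum(axis=1)
    n_used = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fbar = np.where(wsum > 0, (np.where(ok, F, 0.0) * w).sum(axis=1) / wsum, np.nan)
        vbar = np.where(wsum > 0, 1.0 / wsum, np.nan)
    return pd.DataFrame(
        {
            "fitness": fbar,
            "variance": vbar,
            "sigma": np.sqrt(vbar),
            "n_replicates_used": n_used,
        },
        index=ft.fitness.index,
    )
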