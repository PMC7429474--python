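"""Error-model calibration diagnostics.

The central check: if the error model describes the data, the difference
between a replicate's fitness score and the merged score of the remaining
replicates, standardized by the combined predicted error,

    z_{j,i} = (fbar_{r!=j,i} - f_{j,i}) / sqrt(sigmabar^2_{r!=j,i} + sigma^2_{j,i})

should be standard normal.  A mean away from zero flags bias; a standard
deviation away from one flags mis-estimated error magnitude.  The headline
summary is the *relative error magnitude* ``1 / sd(z)``: 1 means the errors
are estimated at the right size, < 1 means they are underestimated.

:func:`loo_crossval` performs the stricter leave-one-out variant: the error
model is refitted on all but one replicate and the held-out replicate's
error is predicted from training-replicate parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alt_models import (
    BayesRegularizedErrorModel,
    CountErrorModel,
    Enrich2ErrorModel,
    VarianceErrorModel,
    count_based_error,
)
from .error_model import DimsumErrorModel, FitConfig

MODELS = ("dimsum", "variance", "bayesreg", "count", "enrich2")


@dataclass
class DiagnosticsResult:
    """Pooled cross-validated z-scores and their calibration summary."""

    model: str
    z: np.ndarray
    p: np.ndarray
    z_mean: float
    z_sd: float
    relative_error_magnitude: float
    per_replicate: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.z)


def replicate_zscores(
    merged_train_fitness: np.ndarray,
    merged_train_variance: np.ndarray,
    test_fitness: np.ndarray,
    test_variance: np.ndarray,
) -> np.ndarray:
    """z = (fbar_train - f_test) / sqrt(var_train + var_test), elementwise."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return (np.asarray(merged_train_fitness, float) - np.asarray(test_fitness, float)) / np.sqrt(
            np.asarray(merged_train_variance, float) + np.asarray(test_variance, float)
        )


def zscore_pvalues(z: np.ndarray) -> np.ndarray:
    """Two-sided normal-test P value for each z-score.

    Clamped to the smallest positive float so that extreme z-scores (where
    the survival function underflows) still yield a P value in (0, 1].
    """
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, np.finfo(float).tiny)


def _weighted_merge(F: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(F) & np.isfinite(V) & (V > 0)
    w = np.where(ok, 1.0 / np.where(ok, V, 1.0), 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fbar = np.where(wsum > 0, (np.where(ok, F, 0.0) * w).sum(axis=1) / wsum, np.nan)
        vbar = np.where(wsum > 0, 1.0 / wsum, np.nan)
    return fbar, vbar


def _summarize(z_all: np.ndarray, p_all: np.ndarray, per_rep, model: str) -> DiagnosticsResult:
    ok = np.isfinite(z_all)
    z_all, p_all = z_all[ok], p_all[ok]
    if len(z_all) < 2:
        raise ValueError("not enough z-scores to summarize")
    z_sd = float(np.std(z_all, ddof=1))
    return DiagnosticsResult(
        model=model,
        z=z_all,
        p=p_all,
        z_mean=float(np.mean(z_all)),
        z_sd=z_sd,
        relative_error_magnitude=1.0 / z_sd if z_sd > 0 else np.inf,
        per_replicate=per_rep,
    )


def loo_crossval(
    fitness: np.ndarray,
    input_counts: np.ndarray,
    output_counts: np.ndarray,
    n_subs: np.ndarray | None = None,
    model: str = "dimsum",
    config: FitConfig | None = None,
    replicate_ids: list[str] | None = None,
) -> DiagnosticsResult:
    """Leave-one-out cross-validated calibration of an error model.

    For each replicate j in turn the chosen error model is (re)fitted on the
    remaining replicates; z-scores compare the held-out scores against the
    training merge, with the held-out error predicted from training-derived
    quantities only:

    * ``dimsum`` — averaged training terms: ``mbar_in/N_in + mbar_out/N_out + abar``;
    * ``count`` — ``1/N_in + 1/N_out`` of the held-out replicate;
    * ``enrich2`` — count-based plus the training random-effects term;
    * ``variance`` / ``bayesreg`` — training merged variance inflated by
      ``n/(n-1)`` (these models carry no count information about the test
      replicate, so the z denominator is this single term).

    The input arrays should be the high-confidence pool (wild type
    excluded); rows are expected finite in all replicates.  Needs at least
    three replicates so every training set supports a variance estimate.
    """
    if model not in MODELS:
        raise ValueError(f"unknown error model {model!r}; choose from {MODELS}")
    config = config or FitConfig()
    F = np.asarray(fitness, dtype=float)
    Nin = np.asarray(input_counts, dtype=float)
    Nout = np.asarray(output_counts, dtype=float)
    n_rep = F.shape[1]
    if n_rep < 3:
        raise ValueError("leave-one-out diagnostics need at least three replicates")
    ids = replicate_ids or [str(k + 1) for k in range(n_rep)]
    seeds = np.random.SeedSequence(config.random_seed).spawn(n_rep)

    z_parts, p_parts, per_rep = [], [], {}
    for j in range(n_rep):
        tr = [r for r in range(n_rep) if r != j]
        Ftr, Nin_tr, Nout_tr = F[:, tr], Nin[:, tr], Nout[:, tr]
        f_test, nin_j, nout_j = F[:, j], Nin[:, j], Nout[:, j]

        if model == "dimsum":
            est = DimsumErrorModel(
                n_bootstraps=config.n_bootstraps,
                max_variants_per_bootstrap=config.max_variants_per_bootstrap,
                random_state=seeds[j].generate_state(1)[0] % (2**31),
                tol=config.tol,
            ).fit(Ftr, Nin_tr, Nout_tr, n_subs=n_subs)
            v_tr = est.predict_variance(Nin_tr, Nout_tr)
            fbar, vbar = _weighted_merge(Ftr, v_tr)
            v_test = (
                est.m_input_.mean() / nin_j + est.m_output_.mean() / nout_j + est.a_.mean()
            )
            denom2 = vbar + v_test
        elif model == "count":
            v_tr = count_based_error(Nin_tr, Nout_tr)
            fbar, vbar = _weighted_merge(Ftr, v_tr)
            denom2 = vbar + count_based_error(nin_j, nout_j)
        elif model == "enrich2":
            est = Enrich2ErrorModel().fit(Ftr, Nin_tr, Nout_tr)
            v_tr = count_based_error(Nin_tr, Nout_tr) + est.s2_[:, None]
            fbar, vbar = _weighted_merge(Ftr, v_tr)
            denom2 = vbar + est.holdout_variance(nin_j, nout_j)
        elif model == "variance":
            est = VarianceErrorModel().fit(Ftr)
            fbar = np.nanmean(Ftr, axis=1)
            denom2 = est.holdout_variance()
        else:  # bayesreg
            est = BayesRegularizedErrorModel().fit(Ftr, Nin_tr)
            fbar = np.nanmean(Ftr, axis=1)
            denom2 = est.holdout_variance()

        with np.errstate(invalid="ignore", divide="ignore"):
            z = (fbar - f_test) / np.sqrt(denom2)
        ok = np.isfinite(z)
        p = zscore_pvalues(z[ok])
        z_parts.append(z[ok])
        p_parts.append(p)
        if ok.sum() >= 2:
            sd = float(np.std(z[ok], ddof=1))
            per_rep[ids[j]] = {
                "z_mean": float(np.mean(z[ok])),
                "z_sd": sd,
                "relative_error_magnitude": 1.0 / sd if sd > 0 else np.inf,
                "n": int(ok.sum()),
            }
    return _summarize(np.concatenate(z_parts), np.concatenate(p_parts), per_rep, model)


def calibration_report(
    result: DiagnosticsResult,
    sd_band: tuple[float, float] = (0.9, 1.1),
    bias_threshold: float = 0.1,
) -> dict:
    """Structured calibration summary with verdicts and QQ coordinates.

    Verdicts follow the z-diagnostic rules: a z standard deviation above the
    band means errors are *underestimated*, below it *overestimated*,
    within it *calibrated*; a z mean beyond ``bias_threshold`` in magnitude
    additionally flags *biased* fitness estimates.  A degenerate z spread
    (all scores identical) yields the verdict ``indeterminate``.
    """
    z = np.sort(result.z)
    n = len(z)
    theo_z = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    p = np.sort(result.p)
    theo_p = (np.arange(1, n + 1) - 0.5) / n
    verdicts: list[str] = []
    if result.z_sd <= 0 or not np.isfinite(result.z_sd):
        verdicts.append("indeterminate")
    else:
        if result.z_sd > sd_band[1]:
            verdicts.append("underestimated")
        elif result.z_sd < sd_band[0]:
            verdicts.append("overestimated")
        else:
            verdicts.append("calibrated")
        if abs(result.z_mean) > bias_threshold:
            verdicts.append("biased")
    ks = stats.kstest(result.p, "uniform")
    return {
        "model": result.model,
        "n": n,
        "z_mean": result.z_mean,
        "z_sd": result.z_sd,
        "relative_error_magnitude": result.relative_error_magnitude,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "verdicts": verdicts,
        "per_replicate": result.per_replicate,
        "qq_z": {"theoretical": theo_z.tolist(), "observed": z.tolist()},
        "qq_p": {"theoretical": theo_p.tolist(), "observed": p.tolist()},
    }
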