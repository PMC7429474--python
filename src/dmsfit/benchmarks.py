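"""Self-contained validation protocols on synthetic data with known truth.

Three standard checks of the error model, each run over several generator
seeds and averaged:

* :func:`loo_calibration` — generate over-dispersed data (one replicate with
  a large multiplicative input term plus a small additive term everywhere),
  run leave-one-out cross-validation, and report the relative error
  magnitude, which should be close to 1 if the model attributes errors
  correctly;
* :func:`multiplicative_recovery` — misreport one replicate's input counts
  by a known factor and check the fitted input term recovers it;
* :func:`additive_recovery` — inject count-independent Gaussian noise into
  one replicate's normalized fitness scores immediately before fitting and
  check the fitted additive term (in s.d. units) recovers its magnitude.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .error_model import FitConfig, fit_error_model
from .fitness import compute_fitness, normalize_scale_shift
from .io import select_high_confidence
from .diagnostics import loo_crossval
from .simulate import SyntheticSpec, generate_counts


def _prepare(spec: SyntheticSpec):
    table, design, truth = generate_counts(spec)
    ft = compute_fitness(table, design)
    ft, _ = normalize_scale_shift(ft)
    sel = select_high_confidence(table, design)
    pool = sel.mask & ~table.is_wildtype
    return table, design, ft, pool


def loo_calibration(
    seeds: Sequence[int],
    m_input: tuple[float, ...] = (5.0, 1.0, 1.0),
    additive_sd: float = 0.05,
    n_bootstraps: int = 100,
) -> dict:
    """Mean leave-one-out relative error magnitude over seeded datasets."""
    rels = []
    n_pool = 0
    for seed in seeds:
        spec = SyntheticSpec(
            seed=int(seed),
            m_input=m_input,
            additive_sd=(additive_sd,) * 3,
        )
        table, design, ft, pool = _prepare(spec)
        res = loo_crossval(
            ft.fitness.to_numpy()[pool],
            table.input_counts(design)[pool],
            table.output_counts(design)[pool],
            n_subs=table.n_subs[pool],
            model="dimsum",
            config=FitConfig(n_bootstraps=n_bootstraps, random_seed=int(seed)),
        )
        rels.append(res.relative_error_magnitude)
        n_pool = max(n_pool, int(pool.sum()))
    return {"value": float(np.mean(rels)), "per_seed": rels, "n": n_pool}


def multiplicative_recovery(
    factor: float,
    seeds: Sequence[int],
    n_bootstraps: int = 100,
) -> dict:
    """Mean fitted input term for a replicate misreported by ``factor``."""
    fitted = []
    n_pool = 0
    for seed in seeds:
        spec = SyntheticSpec(seed=int(seed), m_input=(factor, 1.0, 1.0))
        table, design, ft, pool = _prepare(spec)
        params = fit_error_model(
            ft, table, design,
            FitConfig(n_bootstraps=n_bootstraps, random_seed=int(seed)),
            hc_mask=pool,
        )
        fitted.append(float(params.m_input[0]))
        n_pool = max(n_pool, int(pool.sum()))
    return {"value": float(np.mean(fitted)), "per_seed": fitted, "n": n_pool}


def additive_recovery(
    noise_sd: float,
    seeds: Sequence[int],
    n_bootstraps: int = 100,
) -> dict:
    """Mean fitted sqrt(a) for a replicate with injected fitness noise."""
    fitted = []
    n_pool = 0
    for seed in seeds:
        spec = SyntheticSpec(seed=int(seed))
        table, design, ft, pool = _prepare(spec)
        rng = np.random.default_rng(int(seed) + 1_000_003)
        ft.fitness.iloc[:, 0] += rng.normal(0.0, noise_sd, len(ft.fitness))
        params = fit_error_model(
            ft, table, design,
            FitConfig(n_bootstraps=n_bootstraps, random_seed=int(seed)),
            hc_mask=pool,
        )
        fitted.append(float(np.sqrt(params.a[0])))
        n_pool = max(n_pool, int(pool.sum()))
    return {"value": float(np.mean(fitted)), "per_seed": fitted, "n": n_pool}
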