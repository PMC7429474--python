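"""Synthetic DMS data with known truth, and simulators of common pathologies.

The generator emulates the salient structure of deep mutational scanning
count data: a hierarchical variant library (the wild type is orders of
magnitude more abundant than single mutants, which are more abundant than
double mutants), Poisson sampling of sequencing counts around true
frequencies, selection acting multiplicatively on frequencies through a true
fitness value, and two injectable error pathologies —

* multiplicative over-dispersion, realised by *misreporting* counts: the
  reported count is ``m`` times the actually sampled count, so the true
  sampling variance is ``m``-fold the variance implied by the reported
  count (the same manipulation used to validate the error model);
* additive noise, zero-mean Gaussian perturbations of each replicate's true
  log-enrichment before output sampling.

Bottleneck simulators thin a count table the way a library / replicate /
DNA-extraction bottleneck would (Poisson thinning factors followed by
multinomial resequencing at the original depth), and a sequencing-error
cascade leaks a fixed fraction of reads from each mutation order into the
next.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExperimentDesign, Replicate, VariantCountTable

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """Generating conditions for a synthetic DMS experiment.

    Defaults describe a 10-position protein library sequenced at 5e6 reads
    per sample: the wild type holds 10% of the library, the 190 single
    mutants share 45%, and 4809 sampled double mutants share the remaining
    45%, with lognormal within-order abundance jitter.  True fitness is
    bimodal: a neutral peak at 0 and a deleterious mode around -2 (natural
    log units).  ``m_input`` / ``m_output`` / ``additive_sd`` inject the two
    error pathologies per replicate.
    """

    n_positions: int = 10
    alphabet: str = AA_ALPHABET
    n_replicates: int = 3
    n_doubles: int = 4809
    wt_frequency: float = 0.1
    order_mass: dict[int, float] = field(default_factory=lambda: {1: 0.45, 2: 0.45})
    abundance_sigma: float = 0.5
    fraction_deleterious: float = 0.4
    neutral_sd: float = 0.15
    deleterious_mean: float = -2.0
    deleterious_sd: float = 0.5
    depth: float = 5e6
    output_depth: float | None = None
    m_input: tuple[float, ...] | None = None
    m_output: tuple[float, ...] | None = None
    additive_sd: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 < self.wt_frequency < 1):
            raise ValueError("wt_frequency must be in (0, 1)")
        for name in ("m_input", "m_output"):
            vals = getattr(self, name)
            if vals is not None and any(v < 1 for v in vals):
                raise ValueError(f"{name} factors must be >= 1")

    def _per_replicate(self, vals, default: float) -> np.ndarray:
        if vals is None:
            return np.full(self.n_replicates, default)
        arr = np.asarray(vals, dtype=float)
        if arr.shape != (self.n_replicates,):
            raise ValueError("per-replicate parameter has wrong length")
        return arr


@dataclass
class SyntheticTruth:
    """Everything the generator knew: injected parameters and true fitness."""

    fitness: np.ndarray  # aligned with the count-table rows
    frequencies: np.ndarray
    spec: SyntheticSpec

    def to_json(self, path: str | Path) -> None:
        doc = {
            "fitness": self.fitness.tolist(),
            "frequencies": self.frequencies.tolist(),
            "spec": _spec_to_doc(self.spec),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            fitness=np.asarray(doc["fitness"]),
            frequencies=np.asarray(doc["frequencies"]),
            spec=_spec_from_doc(doc["spec"]),
        )


def _spec_to_doc(spec: SyntheticSpec) -> dict:
    doc = asdict(spec)
    doc["order_mass"] = {str(k): v for k, v in spec.order_mass.items()}
    for name in ("m_input", "m_output", "additive_sd"):
        if doc[name] is not None:
            doc[name] = list(doc[name])
    return doc


def _spec_from_doc(doc: dict) -> SyntheticSpec:
    doc = dict(doc)
    doc["order_mass"] = {int(k): v for k, v in doc["order_mass"].items()}
    for name in ("m_input", "m_output", "additive_sd"):
        if doc[name] is not None:
            doc[name] = tuple(doc[name])
    return SyntheticSpec(**doc)


def _make_variants(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Wild type, all single mutants and a sample of distinct double mutants."""
    L, alpha = spec.n_positions, spec.alphabet
    A = len(alpha)
    wt = "".join(rng.choice(list(alpha), size=L))
    singles = []
    for pos in range(L):
        for letter in alpha:
            if letter != wt[pos]:
                singles.append(wt[:pos] + letter + wt[pos + 1 :])
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    n_space = len(pairs) * (A - 1) ** 2
    if spec.n_doubles > n_space:
        raise ValueError(f"only {n_space} distinct double mutants exist")
    idx = rng.choice(n_space, size=spec.n_doubles, replace=False)
    doubles = []
    per_pair = (A - 1) ** 2
    for k in idx:
        pair = pairs[k // per_pair]
        rem = k % per_pair
        a1 = [c for c in alpha if c != wt[pair[0]]][rem // (A - 1)]
        a2 = [c for c in alpha if c != wt[pair[1]]][rem % (A - 1)]
        s = list(wt)
        s[pair[0]], s[pair[1]] = a1, a2
        doubles.append("".join(s))
    seqs = [wt] + singles + doubles
    orders = np.array([0] + [1] * len(singles) + [2] * len(doubles))
    return seqs, orders


def generate_counts(
    spec: SyntheticSpec,
) -> tuple[VariantCountTable, ExperimentDesign, SyntheticTruth]:
    """Draw a synthetic count table with known true fitness.

    Input counts are Poisson around ``depth * freq``; output counts are
    Poisson around depth times the selection-reweighted frequencies
    ``freq * exp(f_true + eps)`` (``eps`` is the per-replicate additive
    noise, zero for the wild type so the reference stays clean).  When a
    replicate's ``m_input``/``m_output`` factor exceeds one the *reported*
    counts are the sampled counts times the factor.
    """
    rng = np.random.default_rng(spec.seed)
    seqs, orders = _make_variants(spec, rng)
    n_var = len(seqs)

    # hierarchical abundances with lognormal within-order jitter
    freq = np.empty(n_var)
    freq[0] = spec.wt_frequency
    total_mass = spec.wt_frequency + sum(spec.order_mass.values())
    for order, mass in spec.order_mass.items():
        sel = orders == order
        jitter = rng.lognormal(mean=0.0, sigma=spec.abundance_sigma, size=sel.sum())
        freq[sel] = mass * jitter / jitter.sum()
    freq /= total_mass

    # bimodal true fitness, wild type pinned at zero
    deleterious = rng.random(n_var) < spec.fraction_deleterious
    f_true = np.where(
        deleterious,
        rng.normal(spec.deleterious_mean, spec.deleterious_sd, n_var),
        rng.normal(0.0, spec.neutral_sd, n_var),
    )
    f_true[0] = 0.0

    depth_in = float(spec.depth)
    depth_out = float(spec.output_depth or spec.depth)
    if depth_in * freq[0] < 10:
        raise ValueError("depth too low to represent the wild type")
    m_in = spec._per_replicate(spec.m_input, 1.0)
    m_out = spec._per_replicate(spec.m_output, 1.0)
    add_sd = spec._per_replicate(spec.additive_sd, 0.0)

    df = pd.DataFrame({"variant_id": seqs})
    replicates = []
    for r in range(spec.n_replicates):
        rid = str(r + 1)
        inp_sample, out_sample = f"input{rid}", f"output{rid}"
        replicates.append(Replicate(rid, inp_sample, out_sample))
        n_in = rng.poisson(depth_in * freq)
        eps = rng.normal(0.0, add_sd[r], n_var) if add_sd[r] > 0 else np.zeros(n_var)
        eps[0] = 0.0
        w = freq * np.exp(f_true + eps)
        n_out = rng.poisson(depth_out * w / w.sum())
        df[inp_sample] = np.round(n_in * m_in[r]).astype(np.int64)
        df[out_sample] = np.round(n_out * m_out[r]).astype(np.int64)
    design = ExperimentDesign(tuple(replicates), seqs[0])
    table = VariantCountTable(df, seqs[0], design.sample_names)
    truth = SyntheticTruth(fitness=f_true, frequencies=freq, spec=spec)
    return table, design, truth


@dataclass(frozen=True)
class BottleneckSpec:
    """A workflow bottleneck: fraction ``alpha`` of molecules passes through."""

    kind: str = "library"  # library | replicate | extraction
    alpha: float = 0.03
    misread_probability: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.misread_probability < 1):
            raise ValueError("misread_probability must be in [0, 1)")
        if self.kind not in ("library", "replicate", "extraction"):
            raise ValueError(f"unknown bottleneck kind {self.kind!r}")


def _bottleneck_factor(counts: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Per-variant thinning factor ``b_i = Pois(N_i * alpha) / N_i``."""
    counts = np.asarray(counts, dtype=float)
    b = np.zeros(len(counts))
    pos = counts > 0
    b[pos] = rng.poisson(counts[pos] * alpha) / counts[pos]
    return b


def _resample_sample(
    counts: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial re-draw of one sample at its original depth after thinning."""
    total = int(counts.sum())
    w = counts * b
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("bottleneck removed every molecule from a sample")
    return rng.multinomial(total, w / wsum)


def _simulate_bottleneck(
    table: VariantCountTable,
    design: ExperimentDesign,
    spec: BottleneckSpec,
) -> VariantCountTable:
    rng = np.random.default_rng(spec.seed)
    new_counts: dict[str, np.ndarray] = {}
    if spec.kind == "library":
        avg_in = table.input_counts(design).mean(axis=1)
        b = _bottleneck_factor(avg_in, spec.alpha, rng)
        for sample in design.sample_names:
            new_counts[sample] = _resample_sample(table.counts([sample])[:, 0], b, rng)
    elif spec.kind == "replicate":
        for rep in design.replicates:
            b = _bottleneck_factor(table.counts([rep.input_sample])[:, 0], spec.alpha, rng)
            for sample in (rep.input_sample, rep.output_sample):
                new_counts[sample] = _resample_sample(table.counts([sample])[:, 0], b, rng)
    else:  # extraction: independent factor per sequencing sample
        for sample in design.sample_names:
            counts = table.counts([sample])[:, 0]
            b = _bottleneck_factor(counts, spec.alpha, rng)
            new_counts[sample] = _resample_sample(counts, b, rng)
    out = table.with_counts(new_counts)
    if spec.misread_probability > 0:
        out = apply_sequencing_errors(out, spec.misread_probability, rng)
    return out


def simulate_library_bottleneck(
    table: VariantCountTable, design: ExperimentDesign, spec: BottleneckSpec | None = None
) -> VariantCountTable:
    """Bottleneck before replication: one thinning factor per variant, from
    the replicate-averaged input counts, applied to every sample."""
    spec = spec or BottleneckSpec(kind="library")
    return _simulate_bottleneck(table, design, BottleneckSpec("library", spec.alpha, spec.misread_probability, spec.seed))


def simulate_replicate_bottleneck(
    table: VariantCountTable, design: ExperimentDesign, spec: BottleneckSpec | None = None
) -> VariantCountTable:
    """Bottleneck at replicate setup: an independent factor per replicate,
    from that replicate's input counts, applied to both of its samples."""
    spec = spec or BottleneckSpec(kind="replicate")
    return _simulate_bottleneck(table, design, BottleneckSpec("replicate", spec.alpha, spec.misread_probability, spec.seed))


def simulate_extraction_bottleneck(
    table: VariantCountTable, design: ExperimentDesign, spec: BottleneckSpec | None = None
) -> VariantCountTable:
    """DNA-extraction bottleneck: an independent factor per sequencing sample."""
    spec = spec or BottleneckSpec(kind="extraction")
    return _simulate_bottleneck(table, design, BottleneckSpec("extraction", spec.alpha, spec.misread_probability, spec.seed))


def apply_sequencing_errors(
    table: VariantCountTable,
    misread_probability: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> VariantCountTable:
    """Leak reads from each mutation order into the next-higher order.

    Within every sample and for each order d from the highest donor order
    downward, ``round(p * total reads of order d)`` reads are removed from
    order-d variants (without replacement, proportional to their counts) and
    distributed uniformly at random among the order-(d+1) variants present
    in the table.  Orders with no possible recipients keep their reads.
    Total reads per sample are conserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    orders = table.n_subs
    present = np.sort(np.unique(orders))
    new_counts: dict[str, np.ndarray] = {}
    for sample in table.sample_columns:
        counts = table.counts([sample])[:, 0].astype(np.int64)
        for d in present[::-1]:
            donors = np.flatnonzero(orders == d)
            recipients = np.flatnonzero(orders == d + 1)
            if len(recipients) == 0:
                continue
            total = int(counts[donors].sum())
            n_move = int(round(misread_probability * total))
            if n_move == 0:
                continue
            removed = rng.multivariate_hypergeometric(counts[donors], n_move)
            counts[donors] -= removed
            added = rng.multinomial(n_move, np.full(len(recipients), 1.0 / len(recipients)))
            counts[recipients] += added
        new_counts[sample] = counts
    return table.with_counts(new_counts)


def estimate_variant_flow(
    table: VariantCountTable,
    per_base_error: float,
    sequence_length: int | None = None,
    samples: list[str] | None = None,
) -> dict[int, float]:
    """Expected per-variant frequency purely due to sequencing errors.

    Approximates the frequency a *specific* order-d variant would reach from
    misreads of its more abundant ancestors: summed over ancestor orders
    ``k < d``, the average observed frequency of order-k variants times
    ``(e/3)^(d-k) * (1-e)^(L-(d-k))`` — a specific base misread to a
    specific alternative at each of the d-k differing positions, all other
    positions read correctly.  Returns one estimate per mutation order >= 1.
    """
    if not (0 <= per_base_error < 1):
        raise ValueError("per_base_error must be in [0, 1)")
    L = sequence_length or len(table.wild_type_sequence)
    samples = samples or table.sample_columns
    counts = table.counts(samples)
    freqs = (counts / counts.sum(axis=0, keepdims=True)).mean(axis=1)
    orders = table.n_subs
    mean_freq = {int(k): float(freqs[orders == k].mean()) for k in np.unique(orders)}
    max_order = int(orders.max())
    e = per_base_error
    flow: dict[int, float] = {}
    for d in range(1, max_order + 1):
        val = 0.0
        for k in range(d):
            if k not in mean_freq:
                continue
            step = d - k
            val += mean_freq[k] * (e / 3.0) ** step * (1.0 - e) ** (L - step)
        flow[d] = val
    return flow
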