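"""Count tables, experiment designs and variant filtering.

Deep mutational scanning (DMS) experiments sequence a variant library before
("input") and after ("output") a selection step, in several replicate
experiments.  This module holds the two tabular inputs of the analysis:

* :class:`ExperimentDesign` — which sample columns pair up into replicates,
  and the wild-type reference sequence;
* :class:`VariantCountTable` — one row per variant sequence with a
  non-negative integer read count per sample.

It also implements the filtering steps applied before fitness estimation:
a cap on the number of substitutions per variant, hard/soft minimum read
count thresholds, and the selection of the high-confidence variant pool used
to fit the error model.

Count tables are plain TSV with a header row; the variant identity column is
``nt_seq``, ``aa_seq`` or ``variant_id`` (first match wins), which makes the
tables interchangeable with DiMSum-style count-table output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

IDENTITY_COLUMNS = ("nt_seq", "aa_seq", "variant_id")


class DesignError(ValueError):
    """Experiment design is internally inconsistent or disagrees with the counts."""


class CountTableError(ValueError):
    """Count table violates a structural invariant."""


@dataclass(frozen=True)
class Replicate:
    """One replicate selection experiment: an input and an output sample."""

    replicate_id: str
    input_sample: str
    output_sample: str


@dataclass(frozen=True)
class ExperimentDesign:
    """Pairing of count-table sample columns into replicate experiments.

    Parameters
    ----------
    replicates
        One :class:`Replicate` per replicate experiment.  Replicate ids must
        be unique and every sample label may appear only once.
    wild_type_sequence
        The reference sequence; all variants must have the same length.
    """

    replicates: tuple[Replicate, ...]
    wild_type_sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicates", tuple(self.replicates))
        object.__setattr__(
            self, "wild_type_sequence", str(self.wild_type_sequence).upper()
        )
        if not self.replicates:
            raise DesignError("design needs at least one replicate")
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise DesignError("replicate ids must be unique")
        samples = self.sample_names
        if len(set(samples)) != len(samples):
            raise DesignError("each sample label may be used by only one replicate")
        if not self.wild_type_sequence:
            raise DesignError("wild-type sequence must be non-empty")

    @property
    def replicate_ids(self) -> list[str]:
        return [r.replicate_id for r in self.replicates]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def input_samples(self) -> list[str]:
        return [r.input_sample for r in self.replicates]

    @property
    def output_samples(self) -> list[str]:
        return [r.output_sample for r in self.replicates]

    @property
    def sample_names(self) -> list[str]:
        return self.input_samples + self.output_samples

    def subset(self, replicate_ids: Iterable[str]) -> "ExperimentDesign":
        """Design restricted to ``replicate_ids`` (order preserved)."""
        keep = set(replicate_ids)
        missing = keep - set(self.replicate_ids)
        if missing:
            raise DesignError(f"unknown replicate ids: {sorted(missing)}")
        reps = tuple(r for r in self.replicates if r.replicate_id in keep)
        return ExperimentDesign(reps, self.wild_type_sequence)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        reps = tuple(
            Replicate(str(r["replicate_id"]), str(r["input_sample"]), str(r["output_sample"]))
            for r in doc["replicates"]
        )
        return cls(reps, doc["wild_type_sequence"])

    @classmethod
    def from_tsv(cls, path: str | Path, wild_type_sequence: str) -> "ExperimentDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("replicate_id", "input_sample", "output_sample"):
            if col not in df.columns:
                raise DesignError(f"design table misses column {col!r}")
        reps = tuple(
            Replicate(r.replicate_id, r.input_sample, r.output_sample)
            for r in df.itertuples()
        )
        return cls(reps, wild_type_sequence)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "wild_type_sequence": self.wild_type_sequence,
            "replicates": [
                {
                    "replicate_id": r.replicate_id,
                    "input_sample": r.input_sample,
                    "output_sample": r.output_sample,
                }
                for r in self.replicates
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def hamming_distances(sequences: Sequence[str], reference: str) -> np.ndarray:
    """Hamming distance of each equal-length sequence to ``reference``."""
    ref = np.frombuffer(reference.encode("ascii"), dtype="S1")
    n = len(reference)
    for s in sequences:
        if len(s) != n:
            raise CountTableError(
                f"variant {s!r} has length {len(s)}, wild type has length {n}"
            )
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype="S1").reshape(-1, n)
    return (arr != ref[None, :]).sum(axis=1)


class VariantCountTable:
    """Per-variant read counts across all samples of a DMS experiment.

    The table is stored as a :class:`pandas.DataFrame` with columns
    ``variant_id`` (the sequence), ``n_subs`` (Hamming distance to the wild
    type, always recomputed on construction), and one integer count column
    per sample.  Exactly one row must carry the wild-type sequence.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        wild_type_sequence: str,
        sample_columns: Sequence[str],
    ) -> None:
        wt = str(wild_type_sequence).upper()
        df = df.copy()
        df["variant_id"] = df["variant_id"].astype(str).str.upper()
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].head(3).tolist()
            raise CountTableError(f"duplicate variant ids, e.g. {dups}")
        df["n_subs"] = hamming_distances(df["variant_id"].tolist(), wt)
        n_wt = int((df["n_subs"] == 0).sum())
        if n_wt != 1:
            raise CountTableError(
                f"count table must contain the wild-type sequence exactly once "
                f"(found {n_wt} rows)"
            )
        for col in sample_columns:
            if col not in df.columns:
                raise DesignError(f"count table misses sample column {col!r}")
            vals = pd.to_numeric(df[col], errors="raise")
            if (vals < 0).any():
                raise CountTableError(f"negative counts in sample {col!r}")
            if not np.allclose(vals, np.round(vals)):
                raise CountTableError(f"non-integer counts in sample {col!r}")
            df[col] = vals.astype(np.int64)
        self.wild_type_sequence = wt
        self.sample_columns = list(sample_columns)
        ordered = ["variant_id", "n_subs"] + self.sample_columns
        self.df = df[ordered].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    @property
    def n_subs(self) -> np.ndarray:
        return self.df["n_subs"].to_numpy()

    @property
    def is_wildtype(self) -> np.ndarray:
        return self.df["n_subs"].to_numpy() == 0

    @property
    def wildtype_index(self) -> int:
        return int(np.flatnonzero(self.is_wildtype)[0])

    def counts(self, samples: Sequence[str]) -> np.ndarray:
        """Counts for the given sample columns, shape (n_variants, n_samples)."""
        return self.df[list(samples)].to_numpy(dtype=float)

    def input_counts(self, design: ExperimentDesign) -> np.ndarray:
        return self.counts(design.input_samples)

    def output_counts(self, design: ExperimentDesign) -> np.ndarray:
        return self.counts(design.output_samples)

    def subset_rows(self, mask: np.ndarray) -> "VariantCountTable":
        """New table keeping rows where ``mask`` is true (wild type must survive)."""
        sub = self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return VariantCountTable(sub, self.wild_type_sequence, self.sample_columns)

    def with_counts(self, new_counts: dict[str, np.ndarray]) -> "VariantCountTable":
        df = self.df.copy()
        for sample, vals in new_counts.items():
            df[sample] = np.asarray(vals, dtype=np.int64)
        return VariantCountTable(df, self.wild_type_sequence, self.sample_columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantCountTable):
            return NotImplemented
        return (
            self.wild_type_sequence == other.wild_type_sequence
            and self.sample_columns == other.sample_columns
            and self.df.equals(other.df)
        )


def read_count_table(
    path: str | Path,
    design: ExperimentDesign,
    identity_column: str | None = None,
) -> VariantCountTable:
    """Read a TSV count table and validate it against ``design``.

    The identity column is ``identity_column`` if given, otherwise the first
    of ``nt_seq``, ``aa_seq`` or ``variant_id`` present in the header.  Row
    order is preserved; ``n_subs`` is recomputed from the sequences.
    """
    df = pd.read_csv(path, sep="\t")
    if identity_column is None:
        for cand in IDENTITY_COLUMNS:
            if cand in df.columns:
                identity_column = cand
                break
        else:
            raise CountTableError(
                f"no variant identity column ({'/'.join(IDENTITY_COLUMNS)}) in {path}"
            )
    elif identity_column not in df.columns:
        raise CountTableError(f"identity column {identity_column!r} not in {path}")
    df = df.rename(columns={identity_column: "variant_id"})
    return VariantCountTable(df, design.wild_type_sequence, design.sample_names)


def write_count_table(table: VariantCountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Read-count filtering policy.

    ``*_all`` thresholds are *hard*: a variant failing the threshold in any
    replicate's relevant sample is excluded from every replicate.  ``*_any``
    thresholds are *soft*: the variant is excluded only from the replicates
    where it fails.  Counts exactly at the threshold pass (``>=`` semantics).
    """

    min_input_all: int = 0
    min_input_any: int = 0
    min_output_all: int = 0
    min_output_any: int = 0
    max_substitutions: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_input_all", "min_input_any", "min_output_all", "min_output_any"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_input_all > 0 and self.min_input_any > 0:
            raise ValueError("hard and soft input thresholds are mutually exclusive")
        if self.min_output_all > 0 and self.min_output_any > 0:
            raise ValueError("hard and soft output thresholds are mutually exclusive")
        if self.max_substitutions is not None and self.max_substitutions < 0:
            raise ValueError("max_substitutions must be >= 0")


def filter_substitutions(
    table: VariantCountTable, policy: ThresholdPolicy | int | None
) -> VariantCountTable:
    """Drop variants with more substitutions than allowed; wild type always kept."""
    max_subs = policy.max_substitutions if isinstance(policy, ThresholdPolicy) else policy
    if max_subs is None:
        return table
    keep = (table.n_subs <= max_subs) | table.is_wildtype
    return table.subset_rows(keep)


def apply_count_thresholds(
    table: VariantCountTable,
    design: ExperimentDesign,
    policy: ThresholdPolicy,
) -> pd.DataFrame:
    """Boolean usability mask, variants x replicates.

    A replicate entry is usable when the variant has positive input and
    output counts there and survives the policy's hard/soft thresholds.
    """
    inp = table.input_counts(design)
    out = table.output_counts(design)
    usable = (inp > 0) & (out > 0)
    if policy.min_input_all > 0:
        usable &= (inp >= policy.min_input_all).all(axis=1, keepdims=True)
    if policy.min_input_any > 0:
        usable &= inp >= policy.min_input_any
    if policy.min_output_all > 0:
        usable &= (out >= policy.min_output_all).all(axis=1, keepdims=True)
    if policy.min_output_any > 0:
        usable &= out >= policy.min_output_any
    return pd.DataFrame(usable, index=table.variant_ids, columns=design.replicate_ids)


@dataclass
class HighConfidenceSelection:
    """High-confidence variant pool used to fit the error model."""

    mask: np.ndarray  # boolean, aligned with the count-table rows
    n_min: dict[str, int]  # per-replicate minimum input count
    f_min: float  # most-depleted representable fitness score

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def select_high_confidence(
    table: VariantCountTable,
    design: ExperimentDesign,
    n_min: int | dict[str, int] | None = None,
    fitness_quantile: float = 0.01,
) -> HighConfidenceSelection:
    """Select variants reliable enough to constrain the error model.

    Requirements: (a) at least one output read in every replicate's output
    sample; (b) input count in every replicate at least ``N_min``, where
    ``N_min`` is chosen so that a variant depleted to the most negative
    observable fitness score would still yield at least one expected output
    read.  ``f_min`` is estimated as the ``fitness_quantile`` quantile of
    provisional per-variant fitness scores (variants with at least one output
    read everywhere), and ``N_min_r = ceil(exp(-f_min) / depth_ratio_r)``
    with ``depth_ratio_r`` the output/input total-read ratio of replicate r.
    Pass ``n_min`` to override the automatic choice.
    """
    inp = table.input_counts(design)
    out = table.output_counts(design)
    out_ok = (out >= 1).all(axis=1)
    wt = table.wildtype_index
    f_min = np.nan
    if n_min is None:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((inp > 0) & (out > 0), out / inp, np.nan)
            wt_ratio = out[wt] / inp[wt]
            prov = np.log(ratio) - np.log(wt_ratio)[None, :]
        prov_mean = np.nanmean(prov, axis=1)
        pool = out_ok.copy()
        pool[wt] = False
        vals = prov_mean[pool]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise CountTableError("no variants with output reads in all replicates")
        f_min = float(np.quantile(vals, fitness_quantile))
        depth_ratio = out.sum(axis=0) / inp.sum(axis=0)
        n_min_arr = np.maximum(1, np.ceil(np.exp(-f_min) / depth_ratio)).astype(int)
        n_min_map = dict(zip(design.replicate_ids, (int(v) for v in n_min_arr)))
    elif isinstance(n_min, dict):
        n_min_map = {r: int(n_min[r]) for r in design.replicate_ids}
        n_min_arr = np.array([n_min_map[r] for r in design.replicate_ids])
    else:
        n_min_map = {r: int(n_min) for r in design.replicate_ids}
        n_min_arr = np.full(design.n_replicates, int(n_min))
    inp_ok = (inp >= n_min_arr[None, :]).all(axis=1)
    return HighConfidenceSelection(mask=out_ok & inp_ok, n_min=n_min_map, f_min=f_min)
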