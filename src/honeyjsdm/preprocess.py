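"""Filtering of genus-level read-count tables into model-ready responses.

Genome-skimmed honey yields a genus x sample table of read counts that is
contaminated (blank-control reads), sparse (tag jumping, misassignment) and
compositional. This module applies the conservative filtering chain used for
diet/microbiome metabarcoding data:

1. subtract blank-control reads per genus (clamped at zero),
2. zero any cell whose within-sample relative read abundance (RRA) falls
   below a cellwise threshold (default 0.001%),
3. drop genera whose mean RRA across samples falls below a genuswise
   threshold (default 0.01%),
4. optionally remove named dominant taxa and renormalise,
5. drop genera present in fewer than a minimum fraction of samples
   (default 5%) before modelling,

and finally splits the filtered RRA table into the hurdle response pair:
binary occurrence Y and log-RRA-given-presence Z.

Thresholds are accepted in percent (the scale they are usually quoted on)
and held internally as proportions. Removal thresholds are strict
(``< 0.001%``, ``< 5%``) and the retention threshold inclusive (``>= 0.01%``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HurdleResponse",
    "FilterLog",
    "subtract_blank",
    "compute_rra",
    "filter_rare",
    "remove_dominants",
    "prevalence_filter",
    "build_hurdle",
    "run_filter_chain",
]

#: Dominant taxa omitted from abundance analyses by default: a fructophilic
#: honey-stomach bacterium, an osmotolerant honey yeast, and Apis mellifera
#: filamentous virus. Each can reach >85% of reads in single samples.
DEFAULT_DOMINANTS = ("Apilactobacillus", "Zygosaccharomyces", "AmFV")


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate genus ids in count table")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample ids in count table")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in count table")


def subtract_blank(counts: pd.DataFrame, blank: pd.Series) -> pd.DataFrame:
    """Subtract blank-control reads per genus from every sample, clamped at 0.

    Parameters
    ----------
    counts : genus x sample integer table.
    blank : per-genus read counts observed in the extraction blank; genera
        absent from ``blank`` are left unchanged.
    """
    _validate_counts(counts)
    if (blank < 0).any():
        raise ValueError("blank counts must be nonnegative")
    unknown = blank.index.difference(counts.index)
    if len(unknown):
        # blank may list taxa filtered earlier; ignore them silently
        blank = blank.drop(unknown)
    out = counts.copy()
    adj = blank.reindex(counts.index, fill_value=0).to_numpy()
    out.iloc[:, :] = np.maximum(counts.to_numpy() - adj[:, None], 0)
    return out


def compute_rra(counts: pd.DataFrame) -> pd.DataFrame:
    """Relative read abundance: each cell divided by its sample's total.

    Columns of the result sum to 1. A sample with zero total reads is an
    error (its RRA is undefined), reported by name.
    """
    _validate_counts(counts)
    totals = counts.sum(axis=0)
    empty = totals.index[totals == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero total reads: {list(empty)}")
    return counts / totals


def filter_rare(
    counts: pd.DataFrame,
    cell_threshold_pct: float = 0.001,
    mean_threshold_pct: float = 0.01,
    log: "FilterLog | None" = None,
) -> pd.DataFrame:
    """Two-stage rarity filter on a count table.

    Stage 1 zeroes cells whose within-sample RRA is strictly below
    ``cell_threshold_pct`` (% scale). Stage 2 recomputes RRA on the zeroed
    table and drops genera whose unweighted mean RRA across samples is
    strictly below ``mean_threshold_pct``; genera at or above it are kept.
    """
    _validate_counts(counts)
    cell_thr = cell_threshold_pct / 100.0
    mean_thr = mean_threshold_pct / 100.0

    rra = compute_rra(counts)
    zero_mask = (rra.to_numpy() < cell_thr) & (counts.to_numpy() > 0)
    stage1 = counts.copy()
    stage1.iloc[:, :] = np.where(rra.to_numpy() < cell_thr, 0, counts.to_numpy())

    totals = stage1.sum(axis=0)
    if (totals == 0).any():
        raise ValueError(
            "cellwise RRA filter emptied sample(s): "
            f"{list(totals.index[totals == 0])}"
        )
    mean_rra = (stage1 / totals).mean(axis=1)
    keep = mean_rra >= mean_thr
    out = stage1.loc[keep]

    if log is not None:
        log.cells_zeroed = int(zero_mask.sum())
        log.genera_dropped_mean_rra = list(mean_rra.index[~keep])
        log.record("cellwise_rra", genera=out.shape[0], reads=int(out.to_numpy().sum()))
    return out


def remove_dominants(
    table: pd.DataFrame, dominant_ids: "list[str] | tuple[str, ...]" = DEFAULT_DOMINANTS,
    missing: str = "raise",
) -> pd.DataFrame:
    """Remove named dominant genera; proportions are renormalised.

    Works on counts (renormalisation is implicit in later RRA computation)
    or on an RRA table (columns rescaled to sum to 1 again). With
    ``missing="ignore"`` dominants not present in the table are skipped,
    which is convenient when the default dominant list is applied to data
    that never contained those taxa.
    """
    dominant_ids = list(dominant_ids)
    present = [g for g in dominant_ids if g in table.index]
    if missing == "raise" and len(present) != len(dominant_ids):
        unknown = sorted(set(dominant_ids) - set(present))
        raise KeyError(f"unknown genus id(s): {unknown}")
    out = table.drop(index=present)
    col_sums = out.sum(axis=0)
    looks_like_rra = np.allclose(table.sum(axis=0).to_numpy(), 1.0, atol=1e-6)
    if looks_like_rra:
        if (col_sums == 0).any():
            raise ValueError("removing dominants emptied a sample")
        out = out / col_sums
    return out


def prevalence_filter(
    Y: pd.DataFrame, min_prevalence: float = 0.05
) -> pd.DataFrame:
    """Drop genera present in strictly less than ``min_prevalence`` of samples.

    ``Y`` is a binary genus x sample matrix; a genus's prevalence is its
    occurrence fraction across all samples.
    """
    arr = Y.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("Y must be binary")
    prevalence = arr.mean(axis=1)
    return Y.loc[prevalence >= min_prevalence]


@dataclass
class HurdleResponse:
    """Paired responses for the hurdle model.

    ``Y`` is binary occurrence (genus x sample); ``Z`` is natural-log RRA
    where the genus is present and NaN elsewhere; ``log_total_reads`` is the
    per-sample log sequencing depth used as a fixed covariate.
    """

    Y: pd.DataFrame
    Z: pd.DataFrame
    log_total_reads: pd.Series

    def __post_init__(self) -> None:
        if not self.Y.columns.equals(self.Z.columns) or not self.Y.index.equals(self.Z.index):
            raise ValueError("Y and Z must share genus and sample labels")
        y = self.Y.to_numpy()
        z = self.Z.to_numpy()
        if np.isnan(z[y == 1]).any() or np.isfinite(z[y == 0]).any():
            raise ValueError("Z must be defined exactly where Y == 1")
        if not np.isfinite(self.log_total_reads.to_numpy()).all():
            raise ValueError("log_total_reads must be finite")


def build_hurdle(rra: pd.DataFrame, samples: pd.DataFrame) -> HurdleResponse:
    """Split a filtered RRA table into occurrence and log-abundance responses."""
    if not rra.columns.isin(samples.index).all():
        missing = rra.columns.difference(samples.index)
        raise ValueError(f"samples missing metadata: {list(missing)}")
    meta = samples.loc[rra.columns]
    arr = rra.to_numpy(dtype=float)
    Y = pd.DataFrame((arr > 0).astype(np.int8), index=rra.index, columns=rra.columns)
    z = np.full(arr.shape, np.nan)
    np.log(arr, out=z, where=arr > 0)
    Z = pd.DataFrame(z, index=rra.index, columns=rra.columns)
    log_total = np.log(meta["total_reads"].astype(float))
    log_total.name = "log_total_reads"
    return HurdleResponse(Y=Y, Z=Z, log_total_reads=log_total)


@dataclass
class FilterLog:
    """Record of what each filtering stage removed, serialisable to JSON."""

    stages: list = field(default_factory=list)
    cells_zeroed: int = 0
    genera_dropped_mean_rra: list = field(default_factory=list)
    genera_dropped_prevalence: list = field(default_factory=list)
    dominants_removed: list = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "cells_zeroed": self.cells_zeroed,
            "genera_dropped_mean_rra": self.genera_dropped_mean_rra,
            "genera_dropped_prevalence": self.genera_dropped_prevalence,
            "dominants_removed": self.dominants_removed,
        }


def run_filter_chain(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    blank: "pd.Series | None" = None,
    cell_threshold_pct: float = 0.001,
    mean_threshold_pct: float = 0.01,
    min_prevalence: float = 0.05,
    dominant_ids: "tuple[str, ...] | list[str]" = (),
) -> "tuple[HurdleResponse, HurdleResponse, FilterLog]":
    """Full filtering chain from raw counts to the two hurdle responses.

    Order is fixed: blank subtraction, cellwise RRA zeroing, mean-RRA genus
    drop, prevalence filter. Occurrence uses all surviving genera; the
    abundance response additionally omits ``dominant_ids`` (whose spikes
    would distort every other genus's RRA) with renormalisation.

    Returns ``(occurrence_response, abundance_response, filter_log)``.
    """
    log = FilterLog()
    log.record("input", genera=counts.shape[0], reads=int(counts.to_numpy().sum()))
    if blank is not None:
        counts = subtract_blank(counts, blank)
        log.record("blank_subtraction", genera=counts.shape[0],
                   reads=int(counts.to_numpy().sum()))
    counts = filter_rare(counts, cell_threshold_pct, mean_threshold_pct, log=log)

    rra = compute_rra(counts)
    occ = build_hurdle(rra, samples)
    kept = prevalence_filter(occ.Y, min_prevalence)
    log.genera_dropped_prevalence = list(occ.Y.index.difference(kept.index))
    occ = HurdleResponse(Y=kept, Z=occ.Z.loc[kept.index], log_total_reads=occ.log_total_reads)

    present_dominants = [g for g in dominant_ids if g in counts.index]
    log.dominants_removed = present_dominants
    ab_rra = compute_rra(remove_dominants(counts, present_dominants)) if present_dominants else rra
    ab = build_hurdle(ab_rra, samples)
    ab_keep = kept.index.intersection(ab.Y.index)
    ab = HurdleResponse(Y=ab.Y.loc[ab_keep], Z=ab.Z.loc[ab_keep],
                        log_total_reads=ab.log_total_reads)
    log.record("model_entry", occurrence_genera=occ.Y.shape[0],
               abundance_genera=ab.Y.shape[0])
    return occ, ab, log
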