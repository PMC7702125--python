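"""Expression summaries: RPKM, the log-transform rule, stage fold-changes,
row z-scores, and qPCR 2^-ddCt relative expression.

The container is a genes x samples count matrix (pandas DataFrame) with
per-gene transcript lengths and per-sample mapped-read totals.  Replicate
columns are named ``<stage>_r<i>``; replicate means are taken on the RPKM
scale before any transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "QpcrRecord",
    "rpkm",
    "log_expression",
    "stage_fold_change",
    "row_zscore",
    "ddct",
    "relative_expression",
]


def _stage_of(sample: str) -> str:
    return sample.rsplit("_r", 1)[0]


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with the derived RPKM matrix.

    rpkm[g, s] = counts[g, s] * 1e9 / (library_size[s] * gene_length[g]).
    Library sizes default to the column sums of the count matrix.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    library_sizes: pd.Series | None = None
    rpkm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        libs = self.library_sizes.reindex(self.counts.columns)
        if libs.isna().any() or (libs <= 0).any():
            raise ValueError("library sizes must be positive for every sample")
        self.gene_lengths = lengths
        self.library_sizes = libs
        self.rpkm = rpkm(self.counts, lengths, libs)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            st = _stage_of(s)
            if st not in seen:
                seen.append(st)
        return seen

    def stage_mean_rpkm(self, stage: str) -> pd.Series:
        cols = [c for c in self.counts.columns if _stage_of(c) == stage]
        if not cols:
            raise ValueError(f"stage {stage!r} not present")
        return self.rpkm[cols].mean(axis=1)


@dataclass(frozen=True)
class QpcrRecord:
    """Replicate Ct values of a target and the reference gene in one sample."""

    gene: str
    sample: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_target or not self.ct_reference:
            raise ValueError(f"{self.gene}/{self.sample}: missing Ct replicates")
        if min(self.ct_target + self.ct_reference) <= 0:
            raise ValueError(f"{self.gene}/{self.sample}: Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    libs = library_sizes.reindex(counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    lens = gene_lengths.reindex(counts.index)
    return counts.mul(1e9).div(libs, axis=1).div(lens, axis=0)


def log_expression(rpkm_value: float) -> float:
    """log10(RPKM + 1), with values at or below 1 RPKM floored to 0.

    The floor is a display/clustering rule for weakly expressed genes: an
    RPKM of exactly 1 maps to 0, not log10(2).
    """
    if rpkm_value < 0:
        raise ValueError("RPKM cannot be negative")
    if rpkm_value <= 1.0:
        return 0.0
    return math.log10(rpkm_value + 1.0)


def stage_fold_change(
    matrix: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene fold change (mean_b + pseudo) / (mean_a + pseudo), replicates
    averaged on the RPKM scale, ranked descending."""
    mean_a = matrix.stage_mean_rpkm(stage_a)
    mean_b = matrix.stage_mean_rpkm(stage_b)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    return fold.sort_values(ascending=False, kind="stable")


def row_zscore(log_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scores: (x - row mean) / row sd (ddof=0).

    Constant rows come back as all zeros with their flag set in the second
    return value.
    """
    if log_matrix.shape[1] < 2:
        raise ValueError("row z-scores need at least two samples")
    mean = log_matrix.mean(axis=1)
    sd = log_matrix.std(axis=1, ddof=0)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = log_matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z, constant


def ddct(
    record: QpcrRecord, calibrator_sample: str, records: Sequence[QpcrRecord]
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = mean target Ct - mean reference Ct per sample; ddCt subtracts the
    calibrator sample's dCt for the same gene; returns 2^-ddCt.
    """
    calibrator = next(
        (
            r
            for r in records
            if r.gene == record.gene and r.sample == calibrator_sample
        ),
        None,
    )
    if calibrator is None:
        raise ValueError(
            f"no calibrator record for gene {record.gene!r} in sample {calibrator_sample!r}"
        )
    return 2.0 ** -(record.delta_ct - calibrator.delta_ct)


def relative_expression(
    records: Sequence[QpcrRecord], calibrator_sample: str
) -> Mapping[tuple[str, str], float]:
    """2^-ddCt for every (gene, sample), normalised to the calibrator."""
    return {
        (r.gene, r.sample): ddct(r, calibrator_sample, records) for r in records
    }
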