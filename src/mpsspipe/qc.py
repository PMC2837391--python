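"""Signature reliability filters and TPM normalization.

MPSS signatures are short fixed-length tags whose per-library counts proxy
transcript abundance.  Before any statistics are computed the raw tag table
is cleaned in three steps:

1. drop signatures containing anything but A/C/G/T (ambiguity codes cannot
   be counted reliably);
2. drop signatures containing a homopolymer run longer than a configurable
   limit (default 7 nt), a classic MPSS sequencing artifact;
3. normalize the surviving counts to tags per million (TPM) and drop
   signatures below a minimum abundance (default 4 TPM) in every library.

The TPM denominator is the post-sequence-QC library total, so before the
abundance filter each library column sums to the TPM scale exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for signature reliability filtering.

    max_homopolymer_run: longest tolerated single-nucleotide run; runs
        strictly longer are discarded.
    min_tpm: a signature must reach this TPM in at least one library.
    tpm_scale: tags-per-million scale factor.
    """

    max_homopolymer_run: int = 7
    min_tpm: float = 4.0
    tpm_scale: float = 1_000_000.0

    def __post_init__(self):
        if self.max_homopolymer_run <= 0 or self.min_tpm <= 0 or self.tpm_scale <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class ExpressionMatrix:
    """Retained signatures x libraries in TPM, plus the raw library totals
    used as the normalization denominator."""

    tpm: pd.DataFrame
    totals: pd.Series = field(default=None)

    @property
    def libraries(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def signatures(self) -> pd.Index:
        return self.tpm.index

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.tpm.copy(), self.totals.copy())


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[1] < 1:
        raise ValueError("count table must have at least one library column")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")


def filter_deterministic(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep only signatures whose sequence is pure A/C/G/T.

    Any IUPAC ambiguity code (N, R, Y, ...) disqualifies the signature.
    Row order is preserved.
    """
    _check_counts(counts)
    keep = counts.index.to_series().str.fullmatch(_VALID_SEQ.pattern)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_deterministic removed %d ambiguous signature(s)", removed)
    return counts.loc[keep.to_numpy()]


def filter_homopolymer(counts: pd.DataFrame,
                       config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Drop signatures containing a single-nucleotide run longer than
    ``config.max_homopolymer_run`` (a run of exactly the limit is kept)."""
    _check_counts(counts)
    run = re.compile("|".join(f"{b}{{{config.max_homopolymer_run + 1},}}"
                              for b in "ACGT"))
    keep = ~counts.index.to_series().str.contains(run)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_homopolymer removed %d signature(s) with runs > %d",
                    removed, config.max_homopolymer_run)
    return counts.loc[keep.to_numpy()]


def filter_sequences(counts: pd.DataFrame,
                     config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Both sequence-level filters; the two commute, order is conventional."""
    return filter_homopolymer(filter_deterministic(counts), config)


def normalize_tpm(counts: pd.DataFrame,
                  config: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Tags-per-million normalization.

    TPM(i, lib) = count(i, lib) / total(lib) * tpm_scale, with total(lib)
    the column sum of the (already sequence-filtered) table.
    """
    _check_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            "library with zero total count cannot be normalized: "
            + ", ".join(map(str, zero.index)))
    tpm = counts.div(totals, axis=1) * config.tpm_scale
    return ExpressionMatrix(tpm=tpm, totals=totals.astype(np.int64))


def filter_min_abundance(matrix: ExpressionMatrix,
                         config: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Keep signatures with TPM >= min_tpm in at least one library.

    Library totals are carried over unchanged: normalization is not
    recomputed after the abundance filter.
    """
    keep = (matrix.tpm >= config.min_tpm).any(axis=1)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_min_abundance removed %d signature(s) below %g TPM "
                    "in all libraries", removed, config.min_tpm)
    return ExpressionMatrix(tpm=matrix.tpm.loc[keep], totals=matrix.totals)


def run_qc(counts: pd.DataFrame,
           config: QCConfig = QCConfig()) -> ExpressionMatrix:
    """Full QC chain: sequence filters -> TPM normalization -> abundance filter."""
    return filter_min_abundance(normalize_tpm(filter_sequences(counts, config),
                                              config), config)


def summarize_libraries(matrix: ExpressionMatrix,
                        bins: tuple[float, ...] = (10.0, 100.0, 1000.0)
                        ) -> pd.DataFrame:
    """Per-library expression summary.

    For each library: ``unique`` (signatures with TPM > 0), ``specific``
    (expressed in that library only), ``common`` (unique - specific) and the
    number of signatures at or above each TPM bin threshold.  An ``Average``
    row (rounded mean over libraries) and a ``Total`` row (union across
    libraries; bins count signatures reaching the threshold in any library)
    are appended.
    """
    tpm = matrix.tpm
    expressed = tpm > 0
    n_expressed_in = expressed.sum(axis=1)
    rows = {}
    for lib in tpm.columns:
        unique = int(expressed[lib].sum())
        specific = int((expressed[lib] & (n_expressed_in == 1)).sum())
        row = {"common": unique - specific, "specific": specific, "unique": unique}
        for b in bins:
            row[f">={b:g}"] = int((tpm[lib] >= b).sum())
        rows[lib] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.loc["Average"] = summary.mean(axis=0).round().astype(int)
    total_unique = int(expressed.any(axis=1).sum())
    total_specific = int((n_expressed_in == 1).sum())
    total = {"common": total_unique - total_specific,
             "specific": total_specific, "unique": total_unique}
    for b in bins:
        total[f">={b:g}"] = int((tpm >= b).any(axis=1).sum())
    summary.loc["Total"] = pd.Series(total)
    summary.index.name = "library"
    return summary.astype(int)
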