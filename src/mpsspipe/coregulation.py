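"""Within-family expression co-regulation across culture conditions.

Members of a recently expanded gene family often retain shared regulation:
their TPM profiles over the culture conditions rise and fall together.  The
family score here is the mean pairwise Pearson correlation of member
profiles, squared (for the two-member families that dominate such screens
this reduces to the familiar pairwise r^2).  Two significance conventions
are reported side by side:

* ``p_convention`` = 1 - r^2, the convention under which published
  family-correlation tables of this kind are internally consistent; it is
  not a calibrated test and is reported for comparability only.
* ``perm_p``, a seeded permutation p-value obtained by shuffling each
  member's condition labels independently and counting shuffles whose mean
  pairwise correlation reaches the observed one.

With only four conditions each pairwise correlation rests on n = 4 points;
the permutation null is coarse and both p-values should be read as
descriptive screening scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when no member pair has a defined correlation."""


@dataclass
class FamilyCorrelation:
    family: str
    size: int
    mean_r: float
    r_squared: float
    p_convention: float
    perm_p: float
    n_pairs: int


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True, ddof=1)
    return (x - mu) / sd


def _pairwise_r(z: np.ndarray) -> np.ndarray:
    """Off-diagonal pairwise Pearson r from row-standardized profiles.

    Accepts (..., m, n) stacks and returns (..., m*(m-1)/2) pair values.
    """
    n = z.shape[-1]
    corr = z @ np.swapaxes(z, -1, -2) / (n - 1)
    m = z.shape[-2]
    iu = np.triu_indices(m, k=1)
    return corr[..., iu[0], iu[1]]


def family_correlation(profiles: pd.DataFrame, family: str = "",
                       n_permutations: int = 10_000,
                       seed: int | None = 0,
                       statistic: str = "mean_r",
                       log_transform: bool = False) -> FamilyCorrelation:
    """Co-regulation score for one family.

    ``profiles`` holds one row per member (TPM per condition column).
    Members with a constant profile have no defined correlation and are
    dropped with a warning; if fewer than two members remain the result is
    undefined and :class:`UndefinedCorrelationError` is raised.

    ``statistic`` selects the family summary: ``"mean_r"`` (mean pairwise
    r, then squared — the default) or ``"mean_r2"`` (mean of squared
    pairwise r).
    """
    if profiles.shape[0] < 2:
        raise ValueError("a family needs at least two members")
    if profiles.shape[1] < 3:
        raise ValueError("need at least three conditions for a correlation")
    x = profiles.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    variable = x.std(axis=1, ddof=1) > 0
    if not variable.all():
        dropped = profiles.index[~variable].tolist()
        logger.warning("family %s: constant profile member(s) excluded: %s",
                       family or "<unnamed>", dropped)
    x = x[variable]
    m = x.shape[0]
    if m < 2:
        raise UndefinedCorrelationError(
            f"family {family or '<unnamed>'}: no member pair with variable "
            "profiles; correlation undefined")
    z = _standardize_rows(x)
    pair_r = _pairwise_r(z)
    if statistic == "mean_r":
        summarize = lambda r: r.mean(axis=-1)
        r_squared = float(pair_r.mean()) ** 2
    elif statistic == "mean_r2":
        summarize = lambda r: (r ** 2).mean(axis=-1)
        r_squared = float((pair_r ** 2).mean())
    else:
        raise ValueError("statistic must be 'mean_r' or 'mean_r2'")

    rng = np.random.default_rng(seed)
    perm = np.broadcast_to(x, (n_permutations,) + x.shape).copy()
    perm = rng.permuted(perm, axis=2)          # each member's labels shuffled
    null_stat = summarize(_pairwise_r(_standardize_rows(perm)))
    observed = float(summarize(pair_r[None, :])[0])
    hits = int((null_stat >= observed - 1e-12).sum())
    perm_p = (hits + 1) / (n_permutations + 1)

    return FamilyCorrelation(
        family=family, size=int(profiles.shape[0]), mean_r=float(pair_r.mean()),
        r_squared=float(r_squared), p_convention=float(1.0 - r_squared),
        perm_p=float(perm_p), n_pairs=len(pair_r))


def coregulation_screen(matrix, assignment, min_size: int = 2,
                        n_permutations: int = 10_000, seed: int | None = 0,
                        statistic: str = "mean_r",
                        log_transform: bool = False) -> pd.DataFrame:
    """Score every family of size >= min_size, sorted by r^2 descending.

    ``matrix`` is an :class:`~mpsspipe.qc.ExpressionMatrix`; ``assignment``
    a :class:`~mpsspipe.families.FamilyAssignment` sharing signature ids.
    """
    tpm = matrix.tpm
    groups: dict[str, list] = {}
    for sig, fam in assignment.families.items():
        if sig in tpm.index:
            groups.setdefault(fam, []).append(sig)
    rows = []
    for fam in sorted(groups):
        members = sorted(groups[fam])
        if len(members) < min_size:
            continue
        try:
            fc = family_correlation(tpm.loc[members], family=fam,
                                    n_permutations=n_permutations, seed=seed,
                                    statistic=statistic,
                                    log_transform=log_transform)
        except UndefinedCorrelationError:
            continue
        rows.append(fc.__dict__)
    frame = pd.DataFrame(rows, columns=["family", "size", "mean_r",
                                        "r_squared", "p_convention",
                                        "perm_p", "n_pairs"])
    return frame.sort_values("r_squared", ascending=False,
                             kind="mergesort").reset_index(drop=True)


def family_profile_table(matrix, assignment, family: str) -> pd.DataFrame:
    """Per-member TPM sub-table for one family (heatmap-ready)."""
    members = sorted(s for s, f in assignment.families.items() if f == family)
    return matrix.tpm.loc[[m for m in members if m in matrix.tpm.index]]
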