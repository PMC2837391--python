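"""Per-signature differential expression between tag libraries.

Digital tag counts from two libraries are compared one signature at a time
with Fisher's exact test on the 2x2 table

    [[x_treatment, scale - x_treatment],
     [x_control,   scale - x_control]]

where ``scale`` is the per-library TPM total (10^6), so the second column is
"all other tags in the library".  P-values are adjusted per library pair
with the Benjamini-Hochberg step-up procedure and signatures are classified
as differentially expressed at a strict adjusted-p threshold (default
1E-10).  Signatures expressed in exactly one library are reported separately
as condition-exclusive rather than through a fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

#: relative tolerance used when deciding whether a table's point probability
#: ties with the observed table (standard exact-test convention)
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class DEConfig:
    """Thresholds and conventions for the pairwise exact tests."""

    strict_alpha: float = 1e-10
    permissive_alpha: float = 0.05
    control_label: str = "F"
    tpm_scale: int = 1_000_000

    def __post_init__(self):
        if not (0 < self.strict_alpha < self.permissive_alpha < 1):
            raise ValueError("need 0 < strict_alpha < permissive_alpha < 1")
        if self.tpm_scale <= 0:
            raise ValueError("tpm_scale must be positive")


@dataclass
class DESummary:
    """Per-treatment up/down counts and the three-set Venn regions of the
    differentially expressed signature sets."""

    per_treatment: pd.DataFrame
    venn_regions: dict[frozenset, int]
    de_sets: dict[str, set]
    exclusive: dict[str, list] = field(default_factory=dict)


def fisher_2x2(x_treatment: int, x_control: int, scale: int = 1_000_000) -> float:
    """Two-sided Fisher's exact p for the table
    ``[[x_t, scale-x_t], [x_c, scale-x_c]]``.

    The p-value is the sum of hypergeometric point probabilities, over all
    tables with the observed margins, that do not exceed the observed
    table's point probability (minimum-likelihood two-sided convention,
    with a small relative tolerance for ties).  Equal counts give exactly 1.
    """
    x_t, x_c = int(x_treatment), int(x_control)
    if x_t < 0 or x_c < 0 or x_t > scale or x_c > scale:
        raise ValueError(
            f"counts must lie in [0, scale={scale}]; got {x_t}, {x_c}")
    if x_t == x_c:
        return 1.0
    colsum = x_t + x_c
    lo = max(0, colsum - scale)
    hi = min(colsum, scale)
    k = np.arange(lo, hi + 1)

    def _lchoose(n, kk):
        return gammaln(n + 1) - gammaln(kk + 1) - gammaln(n - kk + 1)

    logpmf = (_lchoose(scale, k) + _lchoose(scale, colsum - k)
              - _lchoose(2 * scale, colsum))
    logpmf -= logpmf.max()          # stabilise before exponentiating
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[x_t - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    # extreme tables underflow double precision; report the representable floor
    return min(max(p, np.finfo(float).tiny), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(x_a: float, x_b: float) -> float:
    """log2(x_a / x_b); zeros are an exclusivity case, not a fold change."""
    if x_a <= 0 or x_b <= 0:
        raise ValueError(
            "fold change is undefined for zero expression; "
            "use find_exclusive for condition-exclusive signatures")
    return float(np.log2(x_a / x_b))


def integerize_tpm(tpm) -> np.ndarray:
    """Round TPM to integers, half away from zero (TPM is non-negative here)."""
    return np.floor(np.asarray(tpm, dtype=float) + 0.5).astype(np.int64)


def run_pairwise_de(matrix, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Fisher tests of every treatment library against the control.

    Returns one row per (signature, treatment): integerized TPM counts,
    raw p, BH-adjusted p (adjusted within the library pair), signed log2
    fold change (NaN when either side is 0) and direction.  Significance is
    the adjusted p compared with ``config.strict_alpha``.
    """
    tpm = matrix.tpm
    if config.control_label not in tpm.columns:
        raise ValueError(f"control library {config.control_label!r} not in "
                         f"matrix columns {list(tpm.columns)}")
    treatments = [c for c in tpm.columns if c != config.control_label]
    if not treatments:
        raise ValueError("need at least one treatment library besides control")
    scale = config.tpm_scale
    control = integerize_tpm(tpm[config.control_label])
    frames = []
    for treat in treatments:
        a = integerize_tpm(tpm[treat])
        c = control
        raw = np.array([fisher_2x2(ai, ci, scale) for ai, ci in zip(a, c)])
        adj = bh_adjust(raw)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.where((a > 0) & (c > 0), np.log2(np.maximum(a, 1) /
                                                      np.maximum(c, 1)), np.nan)
        direction = np.where(a > c, "up", np.where(a < c, "down", "none"))
        frames.append(pd.DataFrame({
            "signature": tpm.index,
            "treatment": treat,
            "control": config.control_label,
            "a": a, "c": c,
            "raw_p": raw, "adj_p": adj,
            "log2fc": lfc,
            "direction": direction,
            "significant": adj < config.strict_alpha,
        }))
    return pd.concat(frames, ignore_index=True)


def find_exclusive(matrix) -> dict[str, list]:
    """Signatures with TPM > 0 in exactly one library, keyed by library."""
    tpm = matrix.tpm
    expressed = tpm > 0
    single = expressed.sum(axis=1) == 1
    return {lib: sorted(tpm.index[single & expressed[lib]].tolist())
            for lib in tpm.columns}


def summarize_de(results: pd.DataFrame,
                 config: DEConfig = DEConfig(),
                 matrix=None) -> DESummary:
    """Up/down counts per treatment and the 7 Venn regions of the DE sets."""
    sig = results[results["significant"]]
    treatments = sorted(results["treatment"].unique())
    per = {}
    de_sets = {}
    for treat in treatments:
        sub = sig[sig["treatment"] == treat]
        up = int((sub["direction"] == "up").sum())
        down = int((sub["direction"] == "down").sum())
        per[treat] = {"up": up, "down": down, "total": up + down}
        de_sets[treat] = set(sub["signature"])
    per_treatment = pd.DataFrame.from_dict(per, orient="index")
    per_treatment.index.name = "treatment"

    venn: dict[frozenset, int] = {}
    for r in range(1, len(treatments) + 1):
        for combo in combinations(treatments, r):
            inside = set.intersection(*(de_sets[t] for t in combo))
            outside = set.union(*(de_sets[t] for t in treatments
                                  if t not in combo), set())
            venn[frozenset(combo)] = len(inside - outside)

    exclusive = find_exclusive(matrix) if matrix is not None else {}
    return DESummary(per_treatment=per_treatment, venn_regions=venn,
                     de_sets=de_sets, exclusive=exclusive)
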