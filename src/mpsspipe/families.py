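"""Gene-family inference from signature mismatch structure.

Paralogous genes in tandem-expanded families carry near-identical 3' tags:
family members typically differ by a handful of substitutions while tags of
unrelated genes are much farther apart.  Given a functionally annotated
subset (e.g. KO-labelled unigenes), the within-family and between-family
pairwise Hamming-distance distributions are compared to calibrate a
mismatch threshold ``t`` that separates the two; families are then inferred
genome-wide as single-linkage components of the graph joining signature
pairs at distance <= t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import fisher_exact as _scipy_fisher

logger = logging.getLogger(__name__)

_BASE_CODE = {b: i for i, b in enumerate("ACGTN")}


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of differing positions between two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences differ in length: "
                         f"{len(seq_a)} vs {len(seq_b)}")
    return sum(1 for x, y in zip(seq_a, seq_b) if x != y)


def sequences_to_array(sequences) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) uint8 array."""
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all sequences must have equal length")
    flat = "".join(seqs).encode("ascii")
    return np.frombuffer(flat, dtype=np.uint8).reshape(len(seqs), L)


def pairwise_hamming_matrix(sequences, chunk: int = 512) -> np.ndarray:
    """Full (n, n) Hamming distance matrix, computed in chunks."""
    arr = sequences_to_array(sequences)
    n = arr.shape[0]
    out = np.empty((n, n), dtype=np.uint16)
    for start in range(0, n, chunk):
        block = arr[start:start + chunk]
        out[start:start + chunk] = (block[:, None, :] != arr[None, :, :]).sum(
            axis=2, dtype=np.uint16)
    return out


@dataclass
class MismatchDistribution:
    """Counts of pairwise mismatch values, split by family co-membership.

    ``within[d]`` / ``between[d]`` is the number of same-family /
    different-family signature pairs at Hamming distance d.
    """

    within: np.ndarray
    between: np.ndarray

    @property
    def n_within(self) -> int:
        return int(self.within.sum())

    @property
    def n_between(self) -> int:
        return int(self.between.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mismatches": np.arange(len(self.within)),
                             "within": self.within, "between": self.between})


def mismatch_distributions(sequences, families) -> MismatchDistribution:
    """All-pairs Hamming distances on an annotated signature subset, split
    into same-family and different-family pairs.

    ``families`` maps each sequence (by position) to its family label; only
    sequences with a label participate.
    """
    seqs = list(sequences)
    labels = list(families)
    if len(seqs) != len(labels):
        raise ValueError("sequences and family labels differ in length")
    if len(seqs) < 2:
        raise ValueError("need at least two annotated signatures")
    L = len(seqs[0])
    dist = pairwise_hamming_matrix(seqs)
    lab = np.asarray(labels, dtype=object)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(len(seqs), k=1)
    d = dist[iu]
    s = same[iu]
    within = np.bincount(d[s], minlength=L + 1)
    between = np.bincount(d[~s], minlength=L + 1)
    if between.sum() == 0:
        logger.warning("single family in annotated subset: "
                       "between-family distribution is empty")
    return MismatchDistribution(within=within, between=between)


@dataclass
class ThresholdCalibration:
    """Per-threshold classification tables and the chosen mismatch cutoff.

    For every candidate threshold t the 2x2 table (pairs at distance <= t
    vs > t, crossed with within- vs between-family) is scored with a
    one-sided Fisher exact test for enrichment of within-family pairs at
    <= t.  The chosen t is the largest significant threshold among those
    minimizing total misclassification (within pairs above t plus between
    pairs at or below t).
    """

    table: pd.DataFrame
    chosen: int
    alpha: float


def calibrate_threshold(dist: MismatchDistribution,
                        alpha: float = 1e-10) -> ThresholdCalibration:
    if dist.n_within == 0 or dist.n_between == 0:
        raise ValueError("both within- and between-family pair sets must be "
                         "non-empty to calibrate a threshold")
    L = len(dist.within) - 1
    w_cum = np.cumsum(dist.within)
    b_cum = np.cumsum(dist.between)
    rows = []
    for t in range(L):
        a = int(w_cum[t])                       # within pairs <= t
        b = dist.n_within - a                   # within pairs > t
        c = int(b_cum[t])                       # between pairs <= t
        d = dist.n_between - c
        p = _scipy_fisher([[a, b], [c, d]], alternative="greater")[1]
        rows.append({"t": t, "within_le": a, "within_gt": b,
                     "between_le": c, "between_gt": d,
                     "misclassified": b + c, "p": p})
    table = pd.DataFrame(rows)
    significant = table[table["p"] < alpha]
    if significant.empty:
        raise ValueError(
            f"no threshold separates the two mismatch distributions at "
            f"alpha={alpha:g}; within n={dist.n_within}, "
            f"between n={dist.n_between}")
    best = significant["misclassified"].min()
    chosen = int(significant.loc[significant["misclassified"] == best, "t"].max())
    return ThresholdCalibration(table=table, chosen=chosen, alpha=alpha)


@dataclass
class FamilyAssignment:
    """A partition of signatures into families.

    ``families`` maps signature -> family id; the family id is its
    lexicographically smallest member, which makes ids deterministic and
    input-order independent.
    """

    families: dict[str, str]
    threshold: int

    @property
    def sizes(self) -> pd.Series:
        return (pd.Series(self.families, name="family")
                .value_counts().sort_index())

    def partition(self) -> set[frozenset]:
        groups: dict[str, set] = {}
        for sig, fam in self.families.items():
            groups.setdefault(fam, set()).add(sig)
        return {frozenset(v) for v in groups.values()}


def cluster_families(sequences, t: int) -> FamilyAssignment:
    """Single-linkage clustering at Hamming distance <= t.

    Components of the graph joining pairs at distance <= t; linkage is
    transitive, so chained pairs merge even when their endpoints are
    farther apart than t.
    """
    seqs = sorted(set(sequences))
    if not seqs:
        return FamilyAssignment(families={}, threshold=t)
    dist = pairwise_hamming_matrix(seqs)
    adj = csr_matrix(dist <= t)
    n_comp, labels = connected_components(adj, directed=False)
    families: dict[str, str] = {}
    rep: dict[int, str] = {}
    for sig, comp in zip(seqs, labels):        # seqs sorted => first is smallest
        rep.setdefault(comp, sig)
    for sig, comp in zip(seqs, labels):
        families[sig] = rep[comp]
    return FamilyAssignment(families=families, threshold=t)


def family_size_histogram(assignment: FamilyAssignment,
                          large_cutoff: int = 100) -> pd.DataFrame:
    """Histogram of family sizes, with the largest size and the number of
    families above ``large_cutoff`` attached as frame attributes."""
    sizes = assignment.sizes
    hist = sizes.value_counts().sort_index()
    frame = pd.DataFrame({"family_size": hist.index.astype(int),
                          "n_families": hist.to_numpy()})
    frame.attrs["largest_family"] = int(sizes.max()) if len(sizes) else 0
    frame.attrs["n_above_cutoff"] = int((sizes > large_cutoff).sum())
    return frame
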