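"""DpnII-anchored matching of MPSS signatures to unigene/EST sequences.

MPSS tags begin at a DpnII restriction site (GATC), so a candidate match
must place the four anchor nucleotides exactly on a GATC occurrence in the
unigene (either strand); the remaining tag tail is then compared by Hamming
distance, with a configurable mismatch budget (default 3).  This exhaustive
anchored scan is exact and deterministic for fixed-length tags.  Hits are
ranked by identity, then unigene id, then 3'-most anchor position (tags
derive from the 3'-most DpnII site of a transcript).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

UNKNOWN_LABEL = "unknown"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchConfig:
    """Validation rules for signature-to-unigene hits."""

    max_mismatches: int = 3
    anchor: str = "GATC"
    search_strands: str = "both"        # "both" or "forward"
    signature_length: int = 21

    def __post_init__(self):
        if self.max_mismatches >= self.signature_length - len(self.anchor):
            raise ValueError("max_mismatches must be smaller than the tag tail")
        if self.search_strands not in ("both", "forward"):
            raise ValueError("search_strands must be 'both' or 'forward'")


@dataclass(frozen=True)
class SignatureMatch:
    """One validated hit of a signature on a unigene.

    ``offset`` is the 0-based anchor position in the coordinates of the
    reported strand (i.e. in the reverse complement for '-' hits).
    """

    signature: str
    unigene: str
    strand: str
    offset: int
    mismatches: int
    identity: float
    rank: int = 0


def find_anchor_sites(unigene: str, anchor: str = "GATC",
                      search_strands: str = "both") -> list[tuple[str, int]]:
    """All anchor occurrences, as (strand, offset) with offsets 0-based in
    the reported strand's coordinates."""
    sites = []
    for strand in ("+", "-"):
        if strand == "-" and search_strands != "both":
            break
        seq = unigene if strand == "+" else reverse_complement(unigene)
        start = seq.find(anchor)
        while start != -1:
            sites.append((strand, start))
            start = seq.find(anchor, start + 1)
    return sites


def _scan_one(signature: str, unigene_id: str, unigene: str,
              config: MatchConfig) -> list[SignatureMatch]:
    tail = signature[len(config.anchor):]
    L = len(signature)
    hits = []
    for strand, offset in find_anchor_sites(unigene, config.anchor,
                                            config.search_strands):
        seq = unigene if strand == "+" else reverse_complement(unigene)
        window = seq[offset + len(config.anchor): offset + L]
        if len(window) < len(tail):
            continue
        mm = sum(1 for x, y in zip(tail, window) if x != y)
        if mm <= config.max_mismatches:
            hits.append(SignatureMatch(
                signature=signature, unigene=unigene_id, strand=strand,
                offset=offset, mismatches=mm, identity=(L - mm) / L))
    return hits


def match_signature(signature: str, unigenes: dict[str, str],
                    config: MatchConfig = MatchConfig()) -> list[SignatureMatch]:
    """All validated hits of one signature across a unigene set, ranked.

    Ranking: identity descending, then unigene id (lexicographic), then the
    3'-most anchor offset on the hit strand.  ``rank`` 1 is the best hit.
    """
    signature = signature.upper()
    if not signature.startswith(config.anchor):
        raise ValueError(
            f"signature {signature!r} does not start with the "
            f"{config.anchor} anchor")
    if not unigenes:
        raise ValueError("unigene set is empty")
    hits = []
    for uid, seq in unigenes.items():
        hits.extend(_scan_one(signature, uid, seq.upper(), config))
    hits.sort(key=lambda h: (h.mismatches, h.unigene, -h.offset))
    return [SignatureMatch(h.signature, h.unigene, h.strand, h.offset,
                           h.mismatches, h.identity, rank=i + 1)
            for i, h in enumerate(hits)]


def _anchor_windows(unigenes: dict[str, str], config: MatchConfig):
    """All anchor-site tail windows across a unigene set, encoded for
    vectorized comparison: (uint8 array of windows, list of (uid, strand,
    offset))."""
    tail_len = config.signature_length - len(config.anchor)
    windows, where = [], []
    for uid in unigenes:
        seq = unigenes[uid].upper()
        for strand, offset in find_anchor_sites(seq, config.anchor,
                                                config.search_strands):
            s = seq if strand == "+" else reverse_complement(seq)
            window = s[offset + len(config.anchor): offset +
                       config.signature_length]
            if len(window) < tail_len:
                continue
            windows.append(window)
            where.append((uid, strand, offset))
    if not windows:
        arr = np.empty((0, tail_len), dtype=np.uint8)
    else:
        arr = np.frombuffer("".join(windows).encode("ascii"),
                            dtype=np.uint8).reshape(len(windows), tail_len)
    return arr, where


def match_all(signatures, unigenes: dict[str, str],
              config: MatchConfig = MatchConfig()) -> pd.DataFrame:
    """Match table for many signatures (one row per validated hit).

    Vectorized over all anchor sites of the unigene set; hit-for-hit
    identical to running :func:`match_signature` per signature.
    """
    sig_list = [s.upper() for s in signatures]
    for s in sig_list:
        if not s.startswith(config.anchor):
            raise ValueError(f"signature {s!r} does not start with the "
                             f"{config.anchor} anchor")
    if not unigenes:
        raise ValueError("unigene set is empty")
    win_arr, where = _anchor_windows(unigenes, config)
    tail_len = config.signature_length - len(config.anchor)
    L = config.signature_length
    rows = []
    if len(win_arr):
        chunk = max(1, 2_000_000 // max(1, len(win_arr)))
        tails = np.frombuffer(
            "".join(s[len(config.anchor):] for s in sig_list).encode("ascii"),
            dtype=np.uint8).reshape(len(sig_list), tail_len)
        for start in range(0, len(sig_list), chunk):
            block = tails[start:start + chunk]
            mm = (block[:, None, :] != win_arr[None, :, :]).sum(
                axis=2, dtype=np.int32)
            si, wi = np.nonzero(mm <= config.max_mismatches)
            for i, j in zip(si.tolist(), wi.tolist()):
                uid, strand, offset = where[j]
                m = int(mm[i, j])
                rows.append((sig_list[start + i], uid, strand, offset, m,
                             (L - m) / L))
    frame = pd.DataFrame(rows, columns=["signature", "unigene", "strand",
                                        "offset", "mismatches", "identity"])
    frame = frame.sort_values(
        ["signature", "mismatches", "unigene", "offset"],
        ascending=[True, True, True, False], kind="mergesort")
    frame["rank"] = frame.groupby("signature").cumcount() + 1
    # restore caller's signature order
    order = {s: i for i, s in enumerate(sig_list)}
    frame["_o"] = frame["signature"].map(order)
    frame = (frame.sort_values(["_o", "rank"], kind="mergesort")
             .drop(columns="_o").reset_index(drop=True))
    return frame


def transfer_annotations(matches: pd.DataFrame,
                         annotations: dict[str, str],
                         signatures=None) -> dict[str, str]:
    """Each signature inherits the annotation of its rank-1 hit.

    Signatures without hits (or whose best unigene is unannotated) are
    labelled :data:`UNKNOWN_LABEL`.
    """
    labels: dict[str, str] = {}
    if len(matches):
        best = matches[matches["rank"] == 1]
        for sig, uid in zip(best["signature"], best["unigene"]):
            if uid in annotations:
                labels[sig] = annotations[uid]
            else:
                logger.warning("unigene %s matched by %s has no annotation",
                               uid, sig)
                labels[sig] = UNKNOWN_LABEL
    if signatures is not None:
        for sig in signatures:
            labels.setdefault(sig, UNKNOWN_LABEL)
    return labels
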