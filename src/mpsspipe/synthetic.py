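"""Ground-truthed synthetic MPSS datasets.

The generator emulates the statistical structure of a four-condition MPSS
experiment on a gene-family-rich transcriptome: fixed-depth libraries of
21-nt DpnII-anchored tags (GATC + 17-nt tail), a heavy-tailed (log-normal)
abundance distribution, gene families whose member tags differ by a small
controlled number of co-segregating substitutions, condition-exclusive
transcripts, planted differential expression against a control condition,
and the sequencing artifacts the QC stage is meant to remove (ambiguous
bases, long homopolymer runs, sub-threshold background tags).

Counts are one multinomial draw per library over all tags, so per-library
count sums equal the configured depth exactly.  Every quantity the
downstream analysis is supposed to recover is recorded in a ground-truth
table.  All randomness flows from a single seed through named sub-streams,
and a fixed configuration reproduces a byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMBIGUITY = "NRYSWKM"


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic MPSS experiment.

    Distance geometry note: member tags of one family differ only at a
    family-private set of ``within_family_max_mm`` tail positions, so
    within-family pairwise Hamming distances never exceed that bound;
    tags of different families (and background tags) are kept at least
    ``between_family_min_mm`` apart by construction.  The default minimum
    separation of 6 is one more than the within-family maximum, which makes
    the planted partition unambiguous for single-linkage clustering at the
    calibrated threshold of 5; demanding much larger separations for
    thousands of 17-nt tails is a sphere-packing problem that real tag sets
    do not satisfy either.
    """

    seed: int
    n_genes: int = 2000
    n_families: int = 250
    family_size_law: tuple = ("geometric", 2.0)
    signature_length: int = 21
    anchor: str = "GATC"
    within_family_max_mm: int = 5
    between_family_min_mm: int = 6
    condition_labels: tuple = ("F", "N", "P", "X")
    control_label: str = "F"
    library_depth: int = 1_000_000
    de_fraction: float = 0.05
    log2fc_law: tuple = ("exponential", 1.0, 0.5)   # (kind, scale, minimum)
    baseline_law: tuple = ("lognormal", 5.0, 1.4)   # (kind, mean_log, sigma_log)
    exclusive_counts: dict = field(
        default_factory=lambda: {"F": 18, "N": 2, "P": 12, "X": 487})
    exclusive_min_tpm: float = 25.0
    ambiguous_rate: float = 0.01
    homopolymer_rate: float = 0.01
    background_rate: float = 0.10
    background_tpm_range: tuple = (2.5, 3.9)
    artifact_tpm_range: tuple = (4.0, 50.0)
    max_homopolymer_run: int = 7
    utr_length: int = 80
    body_length: int = 150
    annotated_fraction: float = 1.0

    def __post_init__(self):
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.within_family_max_mm >= self.between_family_min_mm:
            raise ValueError("within_family_max_mm must be smaller than "
                             "between_family_min_mm")
        if self.signature_length <= len(self.anchor):
            raise ValueError("signature_length must exceed the anchor length")
        if self.control_label not in self.condition_labels:
            raise ValueError("control_label must be one of condition_labels")
        if self.n_genes < 0 or self.n_families < 0:
            raise ValueError("n_genes and n_families must be non-negative")
        if self.n_genes and self.n_families > self.n_genes:
            raise ValueError("n_families cannot exceed n_genes")
        bad = set(self.exclusive_counts) - set(self.condition_labels)
        if bad:
            raise ValueError(f"exclusive_counts names unknown conditions: {bad}")
        if sum(self.exclusive_counts.values()) > self.n_genes:
            raise ValueError("n_genes is smaller than the total number of "
                             "requested condition-exclusive genes")
        if self.utr_length < self.signature_length + 6:
            raise ValueError("utr_length too short to embed a signature")

    @property
    def tail_length(self) -> int:
        return self.signature_length - len(self.anchor)

    @property
    def treatments(self) -> tuple:
        return tuple(c for c in self.condition_labels
                     if c != self.control_label)


@dataclass
class SyntheticDataset:
    """A complete simulated experiment plus its ground truth."""

    counts: pd.DataFrame            # signature x condition, raw tag counts
    unigenes: dict                  # unigene id -> sequence
    annotations: pd.DataFrame       # unigene, family
    truth: pd.DataFrame             # one row per gene, see generate_dataset
    config: SimulationConfig


# ---------------------------------------------------------------------------
# tag geometry

class TagPacker:
    """Greedy packing of tag tails at a minimum pairwise Hamming distance.

    Accepted tails are kept as a uint8 matrix; a candidate block is admitted
    only if every candidate is at least ``min_distance`` from every accepted
    tail (candidates within one block are the caller's responsibility, e.g.
    one family whose internal distances are bounded above instead).
    """

    def __init__(self, tail_length: int, min_distance: int):
        self.tail_length = tail_length
        self.min_distance = min_distance
        self._rows = np.empty((0, tail_length), dtype=np.uint8)

    def __len__(self):
        return len(self._rows)

    def conflicts(self, block: np.ndarray) -> bool:
        if not len(self._rows) or not len(block):
            return False
        d = (block[:, None, :] != self._rows[None, :, :]).sum(axis=2)
        return bool((d < self.min_distance).any())

    def admit(self, block: np.ndarray) -> None:
        self._rows = np.vstack([self._rows, block])


def _longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _tag_ok(tag: str, anchor: str, max_run: int) -> bool:
    """A gene/background tag must survive sequence QC (no artifact-length
    homopolymer run) and contain the anchor only as its prefix."""
    return anchor not in tag[1:] and _longest_run(tag) <= max_run


def _random_tail(rng: np.random.Generator, length: int, anchor: str,
                 max_run: int = 7) -> np.ndarray:
    """A random ACGT tail producing a QC-clean tag."""
    while True:
        tail = rng.choice(_BASES, size=length)
        if _tag_ok(anchor + tail.tobytes().decode("ascii"), anchor, max_run):
            return tail


def _mutate(rng: np.random.Generator, tail: np.ndarray,
            positions: np.ndarray, n_mut: int) -> np.ndarray:
    out = tail.copy()
    idx = rng.choice(positions, size=n_mut, replace=False)
    for i in idx:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _build_family(rng: np.random.Generator, size: int,
                  config: SimulationConfig) -> np.ndarray:
    """One family of ``size`` distinct tails with pairwise distance bounded
    by ``within_family_max_mm`` (members differ only within a family-private
    position set of that cardinality)."""
    tail_len = config.tail_length
    w = min(config.within_family_max_mm, tail_len)
    if size > 4 ** w:
        raise ValueError(
            f"family of size {size} is infeasible: at most {4 ** w} distinct "
            f"tags exist within {w} mutable positions")
    founder = _random_tail(rng, tail_len, config.anchor,
                           config.max_homopolymer_run)
    members = [founder]
    if size > 1:
        private = rng.choice(tail_len, size=w, replace=False)
        seen = {founder.tobytes()}
        tries = 0
        while len(members) < size:
            tries += 1
            if tries > 200 * size:
                raise ValueError("family construction did not converge; "
                                 "geometry too tight")
            n_mut = int(rng.integers(1, w + 1))
            cand = _mutate(rng, founder, private, n_mut)
            key = cand.tobytes()
            tag = config.anchor + cand.tobytes().decode("ascii")
            if key not in seen and _tag_ok(tag, config.anchor,
                                           config.max_homopolymer_run):
                seen.add(key)
                members.append(cand)
    return np.stack(members)


def _tails_to_signatures(block: np.ndarray, anchor: str) -> list[str]:
    return [anchor + row.tobytes().decode("ascii") for row in block]


def plant_family_signatures(family_sizes, config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            packer: TagPacker | None = None) -> list[list[str]]:
    """Plant one signature set per requested family size.

    Within each set all pairwise Hamming distances are at most
    ``config.within_family_max_mm``; across sets (and against anything
    already admitted to ``packer``) they are at least
    ``config.between_family_min_mm``.  Raises ``ValueError`` when the
    requested geometry is infeasible.
    """
    sizes = list(family_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("family sizes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if packer is None:
        packer = TagPacker(config.tail_length, config.between_family_min_mm)
    out = []
    for size in sizes:
        for attempt in range(5000):
            block = _build_family(rng, size, config)
            if not packer.conflicts(block):
                packer.admit(block)
                out.append(_tails_to_signatures(block, config.anchor))
                break
        else:
            raise ValueError(
                f"could not place a family of size {size} at minimum "
                f"between-family distance {config.between_family_min_mm}; "
                f"tag space too crowded ({len(packer)} tags placed)")
    return out


# ---------------------------------------------------------------------------
# noise tags

def _background_tags(rng: np.random.Generator, n: int,
                     config: SimulationConfig, packer: TagPacker) -> list[str]:
    tags = []
    for _ in range(n):
        for attempt in range(5000):
            tail = _random_tail(rng, config.tail_length, config.anchor,
                                config.max_homopolymer_run)[None, :]
            if not packer.conflicts(tail):
                packer.admit(tail)
                tags.append(_tails_to_signatures(tail, config.anchor)[0])
                break
        else:
            raise ValueError("could not place background tag; tag space too "
                             "crowded")
    return tags


def _ambiguous_tags(rng: np.random.Generator, n: int,
                    config: SimulationConfig, taken: set) -> list[str]:
    tags = []
    while len(tags) < n:
        tail = list(_random_tail(rng, config.tail_length,
                                 config.anchor).tobytes().decode("ascii"))
        for i in rng.choice(len(tail), size=int(rng.integers(1, 3)),
                            replace=False):
            tail[i] = _AMBIGUITY[int(rng.integers(len(_AMBIGUITY)))]
        tag = config.anchor + "".join(tail)
        if tag not in taken:
            taken.add(tag)
            tags.append(tag)
    return tags


def _homopolymer_tags(rng: np.random.Generator, n: int,
                      config: SimulationConfig, taken: set) -> list[str]:
    tags = []
    run_min = config.max_homopolymer_run + 1
    while len(tags) < n:
        tail = _random_tail(rng, config.tail_length,
                            config.anchor).tobytes().decode("ascii")
        run_len = int(rng.integers(run_min, min(run_min + 3,
                                                config.tail_length) + 1))
        base = "ACGT"[int(rng.integers(4))]
        start = int(rng.integers(0, config.tail_length - run_len + 1))
        tail = tail[:start] + base * run_len + tail[start + run_len:]
        tag = config.anchor + tail
        if config.anchor in tag[1:]:
            continue
        if tag not in taken:
            taken.add(tag)
            tags.append(tag)
    return tags


# ---------------------------------------------------------------------------
# expression model

def _draw_family_sizes(rng: np.random.Generator,
                       config: SimulationConfig) -> list[int]:
    """Family sizes under the configured law, padded with singletons (or
    trimmed) so that the total equals n_genes."""
    kind, *params = config.family_size_law
    if kind == "geometric":
        mean = float(params[0])
        sizes = rng.geometric(p=min(1.0, 1.0 / mean),
                              size=config.n_families).tolist()
    elif kind == "fixed":
        sizes = [int(params[0])] * config.n_families
    else:
        raise ValueError(f"unknown family_size_law kind {kind!r}")
    total = sum(sizes)
    while total > config.n_genes:
        i = int(np.argmax(sizes))
        if sizes[i] == 1:
            sizes.pop()
            total -= 1
        else:
            sizes[i] -= 1
            total -= 1
    sizes.extend([1] * (config.n_genes - total))
    return sizes


def _draw_magnitudes(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind, *params = law
    if kind == "exponential":
        scale, minimum = float(params[0]), float(params[1])
        return minimum + rng.exponential(scale, size=n)
    if kind == "fixed":
        return np.full(n, float(params[0]))
    raise ValueError(f"unknown log2fc_law kind {kind!r}")


def _draw_baselines(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    kind, *params = law
    if kind == "lognormal":
        return rng.lognormal(mean=float(params[0]), sigma=float(params[1]),
                             size=n)
    if kind == "fixed":
        return np.full(n, float(params[0]))
    raise ValueError(f"unknown baseline_law kind {kind!r}")


# ---------------------------------------------------------------------------
# unigene construction

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _seq_without_anchor(rng: np.random.Generator, length: int,
                        anchor: str, prefix_context: str = "") -> str:
    """Random sequence such that ``prefix_context + seq`` contains no anchor
    within the newly generated part (including the junction)."""
    while True:
        seq = _random_seq(rng, length)
        if anchor not in (prefix_context + seq)[max(0, len(prefix_context)
                                                    - len(anchor) + 1):]:
            return seq


def _make_unigene(rng: np.random.Generator, signature: str,
                  config: SimulationConfig) -> str:
    """A unigene embedding its gene's tag in the 3' UTR so that the tag's
    GATC is the 3'-most DpnII site (the MPSS tag position)."""
    L = config.signature_length
    u_pre = (config.utr_length - L) // 2
    u_post = config.utr_length - L - u_pre
    body = _random_seq(rng, config.body_length)
    pre = _seq_without_anchor(rng, u_pre, config.anchor)
    post = _seq_without_anchor(rng, u_post, config.anchor,
                               prefix_context=signature[-3:])
    return body + pre + signature + post


# ---------------------------------------------------------------------------
# generation

def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one complete synthetic MPSS experiment.

    The ground-truth table has one row per gene with columns: ``gene``,
    ``signature``, ``family``, ``unigene``, ``exclusive_to`` ('' when the
    gene is expressed everywhere), and per condition ``expected_tpm_<c>``
    (exact post-normalization expectation), plus per treatment
    ``de_status_<c>`` (up/down/none vs the control) and ``log2fc_<c>``
    (planted signed log2 fold change on the underlying weights).
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_struct, rng_tags, rng_expr, rng_noise, rng_counts, rng_seq = (
        np.random.default_rng(s) for s in streams)

    conditions = list(config.condition_labels)
    n_cond = len(conditions)

    if config.n_genes == 0:
        counts = pd.DataFrame(columns=conditions, dtype=np.int64)
        counts.index.name = "signature"
        truth = pd.DataFrame(columns=["gene", "signature", "family",
                                      "unigene", "exclusive_to"])
        annotations = pd.DataFrame(columns=["unigene", "family"])
        return SyntheticDataset(counts=counts, unigenes={},
                                annotations=annotations, truth=truth,
                                config=config)

    # --- tag structure -----------------------------------------------------
    sizes = _draw_family_sizes(rng_struct, config)
    packer = TagPacker(config.tail_length, config.between_family_min_mm)
    family_tags = plant_family_signatures(sizes, config, rng_tags, packer)

    genes, signatures, families = [], [], []
    for fi, tags in enumerate(family_tags):
        fam = f"FAM{fi + 1:05d}"
        for tag in tags:
            genes.append(f"G{len(genes) + 1:05d}")
            signatures.append(tag)
            families.append(fam)
    n_genes = len(genes)
    fam_sizes = pd.Series(families).value_counts()

    n_bg = int(round(config.background_rate * n_genes))
    n_amb = int(round(config.ambiguous_rate * n_genes))
    n_hp = int(round(config.homopolymer_rate * n_genes))
    bg_tags = _background_tags(rng_noise, n_bg, config, packer)
    taken = set(signatures) | set(bg_tags)
    amb_tags = _ambiguous_tags(rng_noise, n_amb, config, taken)
    hp_tags = _homopolymer_tags(rng_noise, n_hp, config, taken)

    # --- expression weights (nominal TPM units) ----------------------------
    bg_w = rng_noise.uniform(*config.background_tpm_range, size=n_bg)
    amb_w = rng_noise.uniform(*config.artifact_tpm_range, size=n_amb)
    hp_w = rng_noise.uniform(*config.artifact_tpm_range, size=n_hp)

    baseline = _draw_baselines(rng_expr, config.baseline_law, n_genes)
    tpm_scale = 1e6
    baseline *= (tpm_scale - bg_w.sum()) / baseline.sum()

    # exclusive genes come from singleton families for clean semantics
    singleton = np.array([fam_sizes[f] == 1 for f in families])
    n_excl = sum(config.exclusive_counts.values())
    if n_excl > singleton.sum():
        raise ValueError(
            f"requested {n_excl} condition-exclusive genes but only "
            f"{int(singleton.sum())} singleton-family genes are available")
    excl_pool = rng_expr.permutation(np.flatnonzero(singleton))
    exclusive_to = np.array([""] * n_genes, dtype=object)
    pos = 0
    for cond in conditions:
        k = config.exclusive_counts.get(cond, 0)
        exclusive_to[excl_pool[pos:pos + k]] = cond
        pos += k
    is_excl = exclusive_to != ""
    baseline[is_excl] = np.maximum(baseline[is_excl],
                                   config.exclusive_min_tpm * 1.25)

    W = np.tile(baseline[:, None], (1, n_cond)).astype(float)
    for ci, cond in enumerate(conditions):
        off = is_excl & (exclusive_to != cond)
        W[off, ci] = 0.0

    de_status = {t: np.array(["none"] * n_genes, dtype=object)
                 for t in config.treatments}
    log2fc = {t: np.zeros(n_genes) for t in config.treatments}
    eligible = np.flatnonzero(~is_excl)
    for t in config.treatments:
        ci = conditions.index(t)
        k = int(round(config.de_fraction * len(eligible)))
        chosen = rng_expr.choice(eligible, size=k, replace=False)
        mags = _draw_magnitudes(rng_expr, config.log2fc_law, k)
        signs = rng_expr.choice([-1.0, 1.0], size=k)
        lfc = signs * mags
        W[chosen, ci] = baseline[chosen] * np.power(2.0, lfc)
        de_status[t][chosen] = np.where(lfc > 0, "up", "down")
        log2fc[t][chosen] = lfc

    # --- counts: one multinomial per library over all tags ------------------
    all_tags = signatures + bg_tags + amb_tags + hp_tags
    W_all = np.vstack([W,
                       np.tile(bg_w[:, None], (1, n_cond)),
                       np.tile(amb_w[:, None], (1, n_cond)),
                       np.tile(hp_w[:, None], (1, n_cond))])
    counts = np.empty((len(all_tags), n_cond), dtype=np.int64)
    for ci in range(n_cond):
        p = W_all[:, ci] / W_all[:, ci].sum()
        counts[:, ci] = rng_counts.multinomial(config.library_depth, p)

    order = rng_counts.permutation(len(all_tags))
    counts_df = pd.DataFrame(counts[order], columns=conditions,
                             index=pd.Index(np.array(all_tags)[order],
                                            name="signature"))

    # --- exact expected TPM on the post-sequence-QC denominator -------------
    det = np.r_[np.ones(n_genes + n_bg, bool), np.zeros(n_amb + n_hp, bool)]
    expected_tpm = np.empty((n_genes, n_cond))
    for ci in range(n_cond):
        s_det = W_all[det, ci].sum()
        expected_tpm[:, ci] = tpm_scale * W[:, ci] / s_det

    # --- unigenes and annotations ------------------------------------------
    unigenes = {}
    unigene_ids = []
    for gi, sig in enumerate(signatures):
        uid = f"UG{gi + 1:05d}"
        unigene_ids.append(uid)
        unigenes[uid] = _make_unigene(rng_seq, sig, config)

    if config.annotated_fraction >= 1.0:
        annotated = np.ones(n_genes, bool)
    else:
        annotated = np.zeros(n_genes, bool)
        k = int(round(config.annotated_fraction * n_genes))
        annotated[rng_seq.choice(n_genes, size=k, replace=False)] = True
    annotations = pd.DataFrame({
        "unigene": np.array(unigene_ids)[annotated],
        "family": np.array(families)[annotated]})

    # --- ground truth -------------------------------------------------------
    truth = pd.DataFrame({"gene": genes, "signature": signatures,
                          "family": families, "unigene": unigene_ids,
                          "exclusive_to": exclusive_to})
    for ci, cond in enumerate(conditions):
        truth[f"expected_tpm_{cond}"] = expected_tpm[:, ci]
    for t in config.treatments:
        truth[f"de_status_{t}"] = de_status[t]
        truth[f"log2fc_{t}"] = log2fc[t]

    return SyntheticDataset(counts=counts_df, unigenes=unigenes,
                            annotations=annotations, truth=truth,
                            config=config)


# ---------------------------------------------------------------------------
# persistence

DATASET_FILES = {"counts": "counts.tsv", "unigenes": "unigenes.fasta",
                 "annotations": "annotations.tsv", "truth": "ground_truth.tsv"}


def write_dataset(dataset: SyntheticDataset, directory: str | Path,
                  meta: dict | None = None) -> dict:
    """Write the dataset as counts TSV + unigene FASTA + annotation TSV +
    ground-truth TSV; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in DATASET_FILES.items()}
    pio.write_counts(dataset.counts, paths["counts"], meta=meta)
    pio.write_fasta(dataset.unigenes, paths["unigenes"])
    pio.write_annotations(dataset.annotations, paths["annotations"], meta=meta)
    pio.write_tsv(dataset.truth, paths["truth"], meta=meta)
    return paths


def read_dataset(directory: str | Path) -> dict:
    """Read back the four dataset files (no config; returns raw tables)."""
    directory = Path(directory)
    return {
        "counts": pio.read_counts(directory / DATASET_FILES["counts"]),
        "unigenes": pio.read_fasta(directory / DATASET_FILES["unigenes"]),
        "annotations": pio.read_annotations(
            directory / DATASET_FILES["annotations"]),
        "truth": pio.read_tsv(directory / DATASET_FILES["truth"])[0],
    }


def config_summary(config: SimulationConfig) -> dict:
    """JSON-serializable view of a configuration (for provenance hashing)."""
    d = asdict(config)
    d["condition_labels"] = list(config.condition_labels)
    return d
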