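"""1:1 orthologous mature miRNAs from precursor(+flank) sequences.

Candidate precursor pairs are found by all-against-all local alignment and
reciprocal best hits; pairs are kept only when the mature seed regions
(nucleotides 2-7, the primary target-recognition determinant) are identical.
Precursor pairs are then expanded to mature-arm pairs, again requiring seed
identity per arm, and resolved to a 1:1 map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .errors import ConfigurationError, DataError, LookupFailure

log = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 11  # microprocessor cleaves ~11 bp into the lower stem


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval, as in annotation tables."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(
                f"invalid interval [{self.start},{self.end}]: need 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class OrthologyMap:
    """1:1 links between two species' miRNA IDs.

    ``pairs`` lists (species1 ID, species2 ID); ``provenance`` optionally maps
    each pair to its alignment score and shared seed; ``usable`` flags pairs
    whose both members have expression measurements.
    """

    pairs: list[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)
    usable: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self):
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise DataError("orthology map is not 1:1: an ID appears in several pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def species1_ids(self) -> list[str]:
        return [a for a, _ in self.pairs]

    def species2_ids(self) -> list[str]:
        return [b for _, b in self.pairs]

    def usable_pairs(self) -> list[tuple[str, str]]:
        if not self.usable:
            return list(self.pairs)
        return [p for p in self.pairs if self.usable.get(p, True)]


def normalize_rna(seq: str) -> str:
    """Uppercase and fold the alphabet to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def flank_extract(
    interval: GenomicInterval,
    sequence_source: Mapping[str, str],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> str:
    """Precursor sequence extended by ``flank_bp`` on both sides.

    Coordinates are 1-based inclusive; the extension is clipped at record
    bounds, and minus-strand intervals are reverse-complemented.
    """
    if flank_bp < 0:
        raise ConfigurationError("flank_bp must be >= 0")
    try:
        record = sequence_source[interval.chrom]
    except KeyError as exc:
        raise LookupFailure(f"unknown chromosome/record {interval.chrom!r}") from exc
    start = max(1, interval.start - flank_bp)
    end = min(len(record), interval.end + flank_bp)
    sub = record[start - 1 : end]
    if interval.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return sub


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2  # a length-L gap costs 2 + (L - 1)
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _aligner()


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Symmetric local-alignment score (match +1, mismatch -1, gap open -2,
    gap extend -1); the empty alignment floors the score at 0."""
    if not seq_a or not seq_b:
        raise DataError("cannot align an empty sequence")
    a = normalize_rna(seq_a).replace("U", "T")
    b = normalize_rna(seq_b).replace("U", "T")
    bad = set(a + b) - set("ACGTN")
    if bad:
        raise DataError(f"unexpected characters in sequence: {sorted(bad)}")
    return max(0.0, float(_ALIGNER.score(a, b)))


def similarity_matrix(
    seqs_a: Mapping[str, str], seqs_b: Mapping[str, str]
) -> pd.DataFrame:
    """All-against-all local-alignment scores, species1 x species2."""
    ids_a = list(seqs_a)
    ids_b = list(seqs_b)
    out = np.empty((len(ids_a), len(ids_b)))
    for i, ia in enumerate(ids_a):
        for j, jb in enumerate(ids_b):
            out[i, j] = pairwise_similarity(seqs_a[ia], seqs_b[jb])
    return pd.DataFrame(out, index=ids_a, columns=ids_b)


def reciprocal_best_hits(scores: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs (i, j) where j is i's unique best hit and i is j's unique best
    hit.  A tied argmax disqualifies that row/column entirely: "best" is
    undefined under ties and silent tie-breaking is irreproducible."""
    x = scores.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise DataError("similarity scores must be finite")
    # a tied argmax disqualifies its row/column; disqualified sequences stop
    # competing, which can expose (or tie) new best hits, so iterate to a
    # fixpoint before pairing
    active_rows = np.ones(x.shape[0], dtype=bool)
    active_cols = np.ones(x.shape[1], dtype=bool)
    while True:
        # prune rows and columns from the same snapshot so the procedure is
        # symmetric under transposition
        rows_snapshot = active_rows.copy()
        cols_snapshot = active_cols.copy()
        changed = False
        for i in np.flatnonzero(rows_snapshot):
            row = x[i, cols_snapshot]
            if row.size == 0 or (row == row.max()).sum() > 1:
                active_rows[i] = False
                changed = True
        for j in np.flatnonzero(cols_snapshot):
            col = x[rows_snapshot, j]
            if col.size == 0 or (col == col.max()).sum() > 1:
                active_cols[j] = False
                changed = True
        if not changed:
            break
    pairs: list[tuple[str, str]] = []
    col_idx = np.flatnonzero(active_cols)
    row_idx = np.flatnonzero(active_rows)
    for i in row_idx:
        j = col_idx[int(np.argmax(x[i, active_cols]))]
        best_row = row_idx[int(np.argmax(x[active_rows, j]))]
        if best_row == i:
            pairs.append((str(scores.index[i]), str(scores.columns[j])))
    return pairs


def seed_of(mature_seq: str) -> str:
    """Seed region: nucleotides 2-7 (1-based) of a mature sequence, as RNA."""
    s = normalize_rna(mature_seq)
    if len(s) < 7:
        raise DataError(f"mature sequence shorter than 7 nt: {mature_seq!r}")
    return s[1:7]


def seed_filter(
    candidates: Iterable[tuple[str, str]],
    seeds1: Mapping[str, str],
    seeds2: Mapping[str, str],
    scores: Mapping[tuple[str, str], float] | None = None,
) -> OrthologyMap:
    """Keep candidate pairs with identical seeds (alphabet normalized to RNA
    before comparison) and attach provenance."""
    pairs = []
    provenance = {}
    for a, b in candidates:
        if a not in seeds1:
            raise LookupFailure(f"no seed record for {a!r}")
        if b not in seeds2:
            raise LookupFailure(f"no seed record for {b!r}")
        sa = normalize_rna(seeds1[a])
        sb = normalize_rna(seeds2[b])
        if sa == sb:
            pairs.append((a, b))
            provenance[(a, b)] = (float(scores[(a, b)]) if scores else float("nan"), sa)
    return OrthologyMap(pairs=pairs, provenance=provenance)


def precursor_to_mature(
    precursor_pairs: Iterable[tuple[str, str]],
    matures1: Mapping[str, Sequence[tuple[str, str | None]]],
    matures2: Mapping[str, Sequence[tuple[str, str | None]]],
    mature_seqs1: Mapping[str, str],
    mature_seqs2: Mapping[str, str],
    expressed1: set[str] | None = None,
    expressed2: set[str] | None = None,
    scores: Mapping[tuple[str, str], float] | None = None,
) -> OrthologyMap:
    """Expand precursor pairs into mature-arm pairs with identical seeds.

    ``matures{1,2}`` map a precursor ID to its mature arms as (mature ID, arm
    label or None).  Arms are matched by label; unlabeled arms are compared
    all-against-all within the precursor pair.  A mature ID ending up in more
    than one pair (miRNA families) is resolved greedily by precursor
    alignment score.  Pairs whose members lack expression measurements are
    flagged not usable rather than dropped.
    """
    candidates: list[tuple[float, str, str, str]] = []
    for pa, pb in precursor_pairs:
        if pa not in matures1 or pb not in matures2:
            raise LookupFailure(f"precursor pair ({pa!r}, {pb!r}) missing from mature tables")
        score = float(scores.get((pa, pb), 0.0)) if scores else 0.0
        for ma, arm_a in matures1[pa]:
            for mb, arm_b in matures2[pb]:
                if arm_a is not None and arm_b is not None and arm_a != arm_b:
                    continue
                sa = seed_of(mature_seqs1[ma])
                sb = seed_of(mature_seqs2[mb])
                if sa == sb:
                    candidates.append((score, ma, mb, sa))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used1: set[str] = set()
    used2: set[str] = set()
    pairs: list[tuple[str, str]] = []
    provenance: dict[tuple[str, str], tuple[float, str]] = {}
    usable: dict[tuple[str, str], bool] = {}
    for score, ma, mb, seed in candidates:
        if ma in used1 or mb in used2:
            continue
        used1.add(ma)
        used2.add(mb)
        pairs.append((ma, mb))
        provenance[(ma, mb)] = (score, seed)
        ok = True
        if expressed1 is not None and ma not in expressed1:
            ok = False
        if expressed2 is not None and mb not in expressed2:
            ok = False
        usable[(ma, mb)] = ok
    n_flagged = sum(1 for v in usable.values() if not v)
    if n_flagged:
        log.info("%d mature ortholog pairs lack expression in one species", n_flagged)
    return OrthologyMap(pairs=pairs, provenance=provenance, usable=usable)


def find_orthologs(
    precursors1: Mapping[str, str],
    precursors2: Mapping[str, str],
    matures1: Mapping[str, Sequence[tuple[str, str | None]]],
    matures2: Mapping[str, Sequence[tuple[str, str | None]]],
    mature_seqs1: Mapping[str, str],
    mature_seqs2: Mapping[str, str],
    expressed1: set[str] | None = None,
    expressed2: set[str] | None = None,
) -> OrthologyMap:
    """Full orthology stage: all-against-all alignment, reciprocal best hits,
    then per-arm seed-identity expansion to a 1:1 mature map."""
    sims = similarity_matrix(precursors1, precursors2)
    rbh = reciprocal_best_hits(sims)
    score_lookup = {(a, b): float(sims.at[a, b]) for a, b in rbh}
    return precursor_to_mature(
        rbh, matures1, matures2, mature_seqs1, mature_seqs2,
        expressed1=expressed1, expressed2=expressed2, scores=score_lookup,
    )
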