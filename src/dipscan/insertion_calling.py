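"""Insertion-site calling from junction reads.

A MuA-mediated domain insertion leaves a 5-bp target-site duplication: the
variant coding sequence is ``cds[:p+5] + cassette + cds[p:]`` for an insertion
at nucleotide position ``p`` (0-based; the duplicated 5-mer is ``cds[p:p+5]``
and is assigned to the reference, not the insert). A junction read therefore
matches the reference on one end and the cassette on the other. This module
locates that junction, converts it to an insertion call (position, orientation,
frame, productive status), reconciles mate pairs, and tallies per-residue
productive read counts.

Coordinates are 0-based half-open internally. ``aa_pos = nt_pos // 3`` is the
insertion slot: value ``k`` means "inserted after residue k" (0 = before
residue 1). Only forward, in-frame (``nt_pos % 3 == 0``) insertions are
productive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

DEFAULT_MIN_ANCHOR = 15

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Raised on a malformed FASTQ record; carries the record index."""

    def __init__(self, message: str, record_index: int):
        super().__init__(f"record {record_index}: {message}")
        self.record_index = record_index


class OutOfRangeError(ValueError):
    """Breakpoint too close to a reference end to recover the duplication."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionHit:
    """One read's junction match.

    ``cassette_side`` records which read end matched the cassette ('3p' when
    the read runs reference-then-cassette, '5p' when cassette-then-reference).
    ``breakpoint`` is the reference coordinate of the junction: the end of the
    reference anchor for 3p hits, its start for 5p hits.
    """

    read_id: str
    ref_anchor: tuple[int, int]
    cassette_side: Literal["3p", "5p"]
    orientation: Literal["forward", "reverse"]
    breakpoint: int


@dataclass(frozen=True)
class InsertionCall:
    """A called insertion: cassette inserted immediately before ``cds[nt_pos]``,
    duplicated 5-mer ``cds[nt_pos:nt_pos+5]``."""

    read_id: str
    nt_pos: int
    orientation: Literal["forward", "reverse"]
    frame: int
    productive: bool
    aa_pos: int | None

    def key(self) -> tuple[int, str]:
        return (self.nt_pos, self.orientation)


@dataclass
class InsertionCountTable:
    """Per-insertion-slot productive read counts for one sorted pool.

    ``counts[k]`` is the read count for insertions after residue ``k``
    (slots 0 .. n_residues). ``t`` is the pool total (= sum of counts).
    """

    counts: np.ndarray
    sample_id: str = ""
    pool: str = ""
    replicate: int = 0
    domain: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def t(self) -> int:
        return int(self.counts.sum())

    @property
    def n_positions(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# junction finding
# ---------------------------------------------------------------------------

class JunctionFinder:
    """Exact-substring junction finder with a hash-indexed reference.

    The reference is indexed by k-mers of length ``min_anchor``; a read (tried
    on both strands) must split into a reference anchor and an adjacent
    cassette anchor, each at least ``min_anchor`` long. Ambiguous reference
    anchors (seed k-mer at two or more loci) yield no call. ``max_mismatch``
    allows that many substitutions during anchor extension and in the cassette
    anchor for noisy reads (default 0 = exact).
    """

    def __init__(self, reference: str, cassette: str,
                 min_anchor: int = DEFAULT_MIN_ANCHOR, max_mismatch: int = 0):
        if min_anchor < 12:
            raise ValueError("min_anchor must be >= 12")
        self.reference = reference.upper()
        self.cassette = cassette.upper()
        self.cassette_rc = revcomp(self.cassette)
        self.min_anchor = min_anchor
        self.max_mismatch = max_mismatch
        k = min_anchor
        index: dict[str, list[int]] = {}
        for i in range(len(self.reference) - k + 1):
            index.setdefault(self.reference[i:i + k], []).append(i)
        self._index = index

    # -- helpers ----------------------------------------------------------
    def _extend_right(self, seq: str, ref_start: int) -> int:
        """Length of the match of ``seq`` against reference from ``ref_start``,
        tolerating up to max_mismatch substitutions (match ends at the last
        agreeing base)."""
        ref = self.reference
        budget = self.max_mismatch
        m = 0
        last_good = 0
        limit = min(len(seq), len(ref) - ref_start)
        while m < limit:
            if seq[m] == ref[ref_start + m]:
                m += 1
                last_good = m
            elif budget > 0:
                budget -= 1
                m += 1
            else:
                break
        return last_good

    def _extend_left(self, seq: str, ref_end: int) -> int:
        """Length of the match of ``seq``'s suffix against reference ending
        at ``ref_end`` (exclusive), tolerating up to max_mismatch
        substitutions."""
        ref = self.reference
        budget = self.max_mismatch
        m = 0
        last_good = 0
        limit = min(len(seq), ref_end)
        while m < limit:
            if seq[-1 - m] == ref[ref_end - 1 - m]:
                m += 1
                last_good = m
            elif budget > 0:
                budget -= 1
                m += 1
            else:
                break
        return last_good

    def _approx_eq(self, a: str, b: str) -> bool:
        if len(a) != len(b):
            return False
        if self.max_mismatch == 0:
            return a == b
        return sum(x != y for x, y in zip(a, b)) <= self.max_mismatch

    def _cassette_prefix(self, seg: str) -> str | None:
        """Orientation if ``seg`` equals the start of the (possibly
        reverse-complemented) cassette as inserted; None otherwise. A segment
        matching both strands is ambiguous."""
        fwd = self._approx_eq(seg, self.cassette[: len(seg)])
        rev = self._approx_eq(seg, self.cassette_rc[: len(seg)])
        if fwd == rev:
            return None
        return "forward" if fwd else "reverse"

    def _cassette_suffix(self, seg: str) -> str | None:
        fwd = self._approx_eq(seg, self.cassette[len(self.cassette) - len(seg):])
        rev = self._approx_eq(seg, self.cassette_rc[len(self.cassette_rc) - len(seg):])
        if fwd == rev:
            return None
        return "forward" if fwd else "reverse"

    def _find_oriented(self, read_id: str, seq: str) -> JunctionHit | None:
        k = self.min_anchor
        if len(seq) < 2 * k:
            return None
        # case A: reference prefix, cassette suffix (read crosses the
        # upstream junction left to right). The reference extension can
        # overrun into the cassette by chance, so the split point is pinned
        # by requiring the cassette segment to start at the cassette's first
        # base: scan split candidates from the maximal extension downwards.
        hits = self._index.get(seq[:k])
        if hits is not None:
            if len(hits) > 1:
                return None  # ambiguous reference locus
            start = hits[0]
            m = self._extend_right(seq, start)
            if m >= k:
                for split in range(m, k - 1, -1):
                    tail = seq[split:]
                    if len(tail) < k or len(tail) > len(self.cassette):
                        continue
                    orient = self._cassette_prefix(tail)
                    if orient is not None:
                        return JunctionHit(read_id, (start, start + split),
                                           "3p", orient,
                                           breakpoint=start + split)
        # case B: cassette prefix, reference suffix (downstream junction);
        # the cassette segment must end at the cassette's last base.
        hits = self._index.get(seq[-k:])
        if hits is not None:
            if len(hits) > 1:
                return None
            ref_end = hits[0] + k
            m = self._extend_left(seq, ref_end)
            if m >= k:
                for split in range(m, k - 1, -1):
                    head = seq[: len(seq) - split]
                    if len(head) < k or len(head) > len(self.cassette):
                        continue
                    orient = self._cassette_suffix(head)
                    if orient is not None:
                        ref_start = ref_end - split
                        return JunctionHit(read_id, (ref_start, ref_end),
                                           "5p", orient,
                                           breakpoint=ref_start)
        return None

    def find(self, read_id: str, seq: str) -> JunctionHit | None:
        """Locate the junction in a read, trying both strands.

        A hit found on the read's reverse complement is reported in reference
        coordinates with the cassette orientation flipped back accordingly
        (the canonicalisation already operates on reference-forward sequence,
        so no extra flip is needed)."""
        seq = seq.upper()
        hit = self._find_oriented(read_id, seq)
        if hit is not None:
            return hit
        return self._find_oriented(read_id, revcomp(seq))


def find_junction(read: tuple[str, str], reference: str, cassette: str,
                  min_anchor: int = DEFAULT_MIN_ANCHOR,
                  max_mismatch: int = 0) -> JunctionHit | None:
    """Convenience single-read wrapper around :class:`JunctionFinder`.

    ``read`` is a ``(read_id, sequence)`` pair. For bulk calling build one
    JunctionFinder and reuse it (the reference index is rebuilt here per call).
    """
    read_id, seq = read
    return JunctionFinder(reference, cassette, min_anchor, max_mismatch).find(
        read_id, seq)


# ---------------------------------------------------------------------------
# calling, pair reconciliation, tallying
# ---------------------------------------------------------------------------

def call_insertion(hit: JunctionHit, reference: str) -> InsertionCall:
    """Convert a junction hit to an insertion call.

    For a reference-then-cassette hit the reference anchor ends with the
    duplicated 5-mer, so ``nt_pos = breakpoint - 5``; for cassette-then-
    reference hits the downstream flank begins with the duplication at its
    original locus and ``nt_pos = breakpoint``.
    """
    if hit.cassette_side == "3p":
        nt_pos = hit.breakpoint - 5
    else:
        nt_pos = hit.breakpoint
    if not 0 <= nt_pos <= len(reference) - 5:
        raise OutOfRangeError(
            f"breakpoint {hit.breakpoint} leaves no room for the 5-bp "
            f"duplication on reference of length {len(reference)}")
    frame = nt_pos % 3
    productive = hit.orientation == "forward" and frame == 0
    aa_pos = nt_pos // 3 if frame == 0 else None
    return InsertionCall(hit.read_id, nt_pos, hit.orientation, frame,
                         productive, aa_pos)


def reconcile_pair(call_r1: InsertionCall | None,
                   call_r2: InsertionCall | None,
                   policy: Literal["dedupe", "drop"] = "dedupe",
                   ) -> InsertionCall | None:
    """Reconcile mate calls: agreeing duplicates collapse to one call
    (policy 'dedupe') or discard the pair (policy 'drop'); conflicting calls
    are always discarded; a single-mate call passes through."""
    if call_r1 is None:
        return call_r2
    if call_r2 is None:
        return call_r1
    if call_r1.key() == call_r2.key():
        return None if policy == "drop" else call_r1
    return None


def tally(calls: Iterable[InsertionCall], n_residues: int,
          productive_only: bool = True, sample_id: str = "", pool: str = "",
          replicate: int = 0, domain: str = "") -> InsertionCountTable:
    """Tally calls into per-slot counts (slots 0..n_residues)."""
    counts = np.zeros(n_residues + 1, dtype=np.int64)
    for c in calls:
        if productive_only and not c.productive:
            continue
        if c.aa_pos is None:
            continue
        counts[c.aa_pos] += 1
    return InsertionCountTable(counts, sample_id=sample_id, pool=pool,
                               replicate=replicate, domain=domain)


def call_read_pairs(pairs: Iterable[tuple[tuple[str, str], tuple[str, str]]],
                    reference: str, cassette: str,
                    min_anchor: int = DEFAULT_MIN_ANCHOR,
                    max_mismatch: int = 0,
                    pair_policy: Literal["dedupe", "drop"] = "dedupe",
                    ) -> list[InsertionCall]:
    """Call junctions for an iterable of read pairs and reconcile each pair."""
    finder = JunctionFinder(reference, cassette, min_anchor, max_mismatch)
    calls: list[InsertionCall] = []
    for (id1, seq1), (id2, seq2) in pairs:
        out: list[InsertionCall | None] = []
        for rid, seq in ((id1, seq1), (id2, seq2)):
            hit = finder.find(rid, seq)
            if hit is None:
                out.append(None)
                continue
            try:
                out.append(call_insertion(hit, reference))
            except OutOfRangeError:
                out.append(None)
        merged = reconcile_pair(out[0], out[1], policy=pair_policy)
        if merged is not None:
            calls.append(merged)
    return calls


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path,
                     ) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
    """Iterate (id, seq) pairs from two FASTQ files (plain or gzip)."""
    for (rec1, rec2) in zip(_iter_fastq(r1_path), _iter_fastq(r2_path)):
        yield rec1, rec2


def _iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqParseError("malformed 4-line record", idx)
            seq = seq.strip()
            if len(seq) != len(qual.strip()):
                raise FastqParseError("sequence/quality length mismatch", idx)
            yield header[1:].split()[0], seq
            idx += 1


def write_calls_tsv(calls: Sequence[InsertionCall], path: str | Path) -> None:
    """Plaintext call table: read_id, nt_pos (0-based), orientation, frame,
    productive, aa_pos (insertion slot; 0 = before residue 1)."""
    with open(path, "w") as fh:
        fh.write("# nt_pos 0-based; aa_pos = nt_pos/3, slot after residue aa_pos\n")
        fh.write("read_id\tnt_pos\torientation\tframe\tproductive\taa_pos\n")
        for c in calls:
            aa = "" if c.aa_pos is None else str(c.aa_pos)
            fh.write(f"{c.read_id}\t{c.nt_pos}\t{c.orientation}\t{c.frame}\t"
                     f"{int(c.productive)}\t{aa}\n")


def write_counts_tsv(table: InsertionCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# aa_pos = insertion slot (0 = before residue 1)\n")
        fh.write("aa_pos\tcount\tsample\tpool\treplicate\tdomain\n")
        for k, n in enumerate(table.counts):
            fh.write(f"{k}\t{int(n)}\t{table.sample_id}\t{table.pool}\t"
                     f"{table.replicate}\t{table.domain}\n")


def read_counts_tsv(path: str | Path) -> InsertionCountTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.sort_values("aa_pos")
    counts = np.zeros(int(df["aa_pos"].max()) + 1, dtype=np.int64)
    counts[df["aa_pos"].to_numpy()] = df["count"].to_numpy()
    first = df.iloc[0]
    return InsertionCountTable(
        counts, sample_id=str(first.get("sample", "")),
        pool=str(first.get("pool", "")), replicate=int(first.get("replicate", 0)),
        domain=str(first.get("domain", "")))
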