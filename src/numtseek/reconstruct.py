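"""Consensus reconstruction of NUMT sequences in mtDNA coordinates.

Supporting reads of one insertion cluster are re-placed on a circularly
padded mitochondrial reference with a seed-and-extend mapper, piled up, and
collapsed into >=5x consensus fragments that are concatenated in circular
order.  Length / depth QC mirrors the discovery filters: fragments shorter
than 20 bp or below 5x mean depth carry too little signal to classify and
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PaddedMtReference:
    """Circular mtDNA reference linearised by appending its first `pad` bases."""

    sequence: str
    original_length: int
    pad: int

    def unwrap(self, position: int) -> int:
        """Map a 1-based padded coordinate back onto [1, original_length]."""
        if not 1 <= position <= self.original_length + self.pad:
            raise ValueError(f"position {position} outside padded reference")
        return position if position <= self.original_length else position - self.original_length


def pad_circular_reference(mt_sequence: str, pad: int = 1000) -> PaddedMtReference:
    """Append positions 1..pad after the end so reads spanning the origin map."""
    if pad >= len(mt_sequence):
        raise ValueError("pad must be smaller than the mtDNA length")
    return PaddedMtReference(
        sequence=mt_sequence + mt_sequence[:pad],
        original_length=len(mt_sequence),
        pad=pad,
    )


@dataclass
class MtFragment:
    """One maximal >=min_depth run of consensus, in 1-based mtDNA coordinates."""

    start: int
    end: int
    sequence: str
    depth: np.ndarray
    mean_depth: float

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class NumtSequence:
    numt_id: str
    fragments: list[MtFragment]
    total_length: int
    mean_depth: float
    gc_content: float

    @property
    def sequence(self) -> str:
        return "".join(f.sequence for f in self.fragments)


class SeedIndex:
    """Exact k-mer index of the padded reference for read anchoring."""

    def __init__(self, ref: PaddedMtReference, k: int = 25):
        self.ref = ref
        self.k = k
        self._arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        seq = ref.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self._index = index

    def candidate_offsets(self, read: str, stride: int = 8) -> set[int]:
        """0-based padded positions where the read start could sit.

        Seeds are probed on a stride first; if none hits (e.g. a diverged
        archaic read whose mutations break the sampled k-mers), every
        offset is tried before giving up.
        """
        k = self.k
        for step in (stride, 1):
            out: set[int] = set()
            positions = list(range(0, max(len(read) - k, 0) + 1, step))
            if positions and positions[-1] != len(read) - k:
                positions.append(len(read) - k)
            for off in positions:
                for hit in self._index.get(read[off : off + k], ()):
                    out.add(hit - off)
            if out:
                return out
        return set()

    def mismatches(self, read: str, start: int) -> int:
        """Hamming mismatches of the read placed at 0-based padded `start`.

        Bases hanging over either end of the padded reference count as
        mismatches (ungapped extension only).
        """
        r = np.frombuffer(read.encode(), dtype=np.uint8)
        lo, hi = max(start, 0), min(start + len(r), len(self._arr))
        if hi <= lo:
            return len(r)
        inside = int((r[lo - start : hi - start] != self._arr[lo:hi]).sum())
        return inside + (lo - start) + (start + len(r) - hi)


@dataclass
class MtPileup:
    """Per-position base counts on the unpadded mtDNA reference."""

    counts: np.ndarray  # shape (4, L), A/C/G/T rows
    n_placed: int = 0
    n_skipped: int = 0
    placements: list[tuple[str, int, bool]] = field(default_factory=list)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def map_supports_to_mt(
    reads,
    ref: PaddedMtReference,
    k: int = 25,
    max_mismatch_frac: float = 0.10,
    seed_index: SeedIndex | None = None,
    qualities=None,
    min_baseq: int = 0,
) -> MtPileup:
    """Place reads on the padded reference by exact-seed anchoring + ungapped extension.

    Reads shorter than k are skipped.  A read is placed at the candidate
    position with the fewest mismatches, provided the mismatch fraction does
    not exceed `max_mismatch_frac`; the reverse complement is tried when the
    forward orientation finds no acceptable anchor.  Padded placements are
    unwrapped onto [1, L].  When per-base qualities are supplied, bases below
    `min_baseq` are withheld from the pileup (the placement itself uses the
    full read).
    """
    index = seed_index if seed_index is not None else SeedIndex(ref, k=k)
    L = ref.original_length
    counts = np.zeros((4, L), dtype=np.int32)
    pile = MtPileup(counts=counts)
    pairs = zip(reads, qualities) if qualities is not None else ((r, None) for r in reads)
    for read, qual in pairs:
        if len(read) < index.k:
            pile.n_skipped += 1
            continue
        placed = _best_placement(read, index, max_mismatch_frac)
        reverse = False
        if placed is None:
            placed = _best_placement(revcomp(read), index, max_mismatch_frac)
            reverse = True
        if placed is None:
            pile.n_skipped += 1
            continue
        start, _ = placed
        seq = revcomp(read) if reverse else read
        q = qual
        if reverse and q is not None:
            q = q[::-1]
        for i, base in enumerate(seq):
            p = start + i
            if not 0 <= p < L + ref.pad:
                continue
            if q is not None and q[i] < min_baseq:
                continue
            bi = _BASE_INDEX.get(base)
            if bi is None:
                continue
            counts[bi, p % L] += 1
        pile.n_placed += 1
        pile.placements.append((seq, start, reverse))
    return pile


def _best_placement(read: str, index: SeedIndex, max_mismatch_frac: float):
    best = None
    for start in index.candidate_offsets(read):
        mm = index.mismatches(read, start)
        if best is None or mm < best[1]:
            best = (start, mm)
    if best is None or best[1] > max_mismatch_frac * len(read):
        return None
    return best


def call_consensus(
    pileup: MtPileup, min_depth: int = 5, majority_frac: float = 0.8
) -> list[MtFragment]:
    """Collapse the pileup into maximal runs of >=min_depth consensus.

    The consensus base is the per-position majority (ties broken A<C<G<T by
    argmax); a position where the majority base holds less than
    `majority_frac` of the reads is reported as N rather than inventing a
    confident call.
    """
    depth = pileup.depth
    ok = depth >= min_depth
    if not ok.any():
        return []
    major = pileup.counts.argmax(axis=0)
    frags: list[MtFragment] = []
    boundaries = np.flatnonzero(np.diff(ok.astype(np.int8)))
    starts = [0] if ok[0] else []
    starts += [int(b) + 1 for b in boundaries if ok[b + 1]]
    ends = [int(b) for b in boundaries if ok[b]]
    if ok[-1]:
        ends.append(len(ok) - 1)
    for s, e in zip(starts, ends):
        bases = []
        for p in range(s, e + 1):
            top = pileup.counts[major[p], p]
            if top < majority_frac * depth[p]:
                bases.append("N")
            else:
                bases.append(_BASES[major[p]])
        d = depth[s : e + 1].astype(float)
        frags.append(
            MtFragment(
                start=s + 1,
                end=e + 1,
                sequence="".join(bases),
                depth=depth[s : e + 1].copy(),
                mean_depth=float(d.mean()),
            )
        )
    return frags


def concatenate_fragments(
    numt_id: str, fragments: list[MtFragment], mt_length: int | None = None
) -> NumtSequence:
    """Join fragments in mtDNA order, honouring circularity.

    Fragments are ordered by start coordinate; when the set wraps the origin
    (one fragment ends at position L while another starts at position 1) the
    origin-spanning tail is placed first so the concatenation follows the
    molecule rather than the linearised reference.
    """
    frags = sorted(fragments, key=lambda f: f.start)
    for a, b in zip(frags, frags[1:]):
        if b.start <= a.end:
            raise ValueError(f"overlapping fragments {a.start}-{a.end} and {b.start}-{b.end}")
    if (
        len(frags) >= 2
        and frags[0].start == 1
        and mt_length is not None
        and frags[-1].end == mt_length
    ):
        # wrap: put the fragment reaching the end of the reference first
        frags = frags[-1:] + frags[:-1]
    total = sum(len(f) for f in frags)
    seq = "".join(f.sequence for f in frags)
    gc = (seq.count("G") + seq.count("C")) / total if total else 0.0
    mean_depth = (
        sum(f.mean_depth * len(f) for f in frags) / total if total else 0.0
    )
    return NumtSequence(
        numt_id=numt_id,
        fragments=frags,
        total_length=total,
        mean_depth=mean_depth,
        gc_content=gc,
    )


@dataclass
class QcDecision:
    keep: bool
    reason: str | None = None


def qc_filter(
    seq: NumtSequence, min_len: int = 20, min_mean_depth: float = 5.0
) -> QcDecision:
    """Discard reconstructions too short or too shallow to classify.

    GC content is reported on the NumtSequence but never filtered on.
    """
    if seq.total_length < min_len:
        return QcDecision(False, "length")
    if seq.mean_depth < min_mean_depth:
        return QcDecision(False, "depth")
    return QcDecision(True, None)


def max_reconstructable_length(read_length: int, insert_size: int) -> int:
    """Two-sided bound on a fragment reconstructable from split read pairs.

    From each side of an insertion a split pair can reach one mitochondrial
    read length plus the insert size plus the clipped half of the chromosomal
    read into the NUMT; both sides together bound the fragment at
    2 * (read_length + insert_size + read_length / 2).
    """
    return int(2 * (read_length + insert_size + read_length / 2))
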