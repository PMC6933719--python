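"""Phylogenetic classification of reconstructed NUMT sequences.

Each NUMT consensus is dropped into the matching region of an aligned
hominin mtDNA panel (modern humans, Neanderthals, Denisovans, Sima de los
Huesos, an outgroup and the RSRS reference row), identical rows are
collapsed, a neighbor-joining tree on Jukes-Cantor distances is built and
bootstrapped by column resampling, and the NUMT's lineage of origin is read
off the monophyletic clade it joins.  Clades below the bootstrap gate
(default 50) are not trusted, mirroring how only well-supported clades are
annotated on published trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

MODERN_LABELS = frozenset({"modern_human", "ancient_modern", "reference"})
DENISOVAN_LABELS = frozenset({"denisovan", "sima"})
NEANDERTHAL_LABELS = frozenset({"neanderthal"})
ARCHAIC_LABELS = DENISOVAN_LABELS | NEANDERTHAL_LABELS

GAP = "-"


@dataclass
class HomininPanel:
    """Aligned hominin mtDNA sequences with lineage labels.

    `rsrs_column_map[p - 1]` is the 0-based alignment column of RSRS
    position `p`; for a gap-free alignment it is the identity.  Exactly one
    row must carry the `outgroup` label (used for rooting).
    """

    names: list[str]
    labels: list[str]
    sequences: list[str]
    rsrs_column_map: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("panel sequences must be aligned to equal length")
        if self.labels.count("outgroup") != 1:
            raise ValueError("exactly one outgroup row is required for rooting")
        if len(self.rsrs_column_map) and not np.all(np.diff(self.rsrs_column_map) > 0):
            raise ValueError("rsrs_column_map must be strictly increasing")
        if len(self.rsrs_column_map) and self.rsrs_column_map[-1] >= len(self.sequences[0]):
            raise ValueError("rsrs_column_map exceeds the alignment width")

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    @property
    def mt_length(self) -> int:
        return len(self.rsrs_column_map)

    @property
    def outgroup_name(self) -> str:
        return self.names[self.labels.index("outgroup")]

    def rows_by_label(self, label: str) -> list[str]:
        return [s for s, l in zip(self.sequences, self.labels) if l == label]

    @classmethod
    def from_alignment(cls, names, labels, sequences, reference_label="reference"):
        """Build the RSRS coordinate map from the gaps of the reference row."""
        ref_row = sequences[labels.index(reference_label)]
        cols = np.flatnonzero(np.frombuffer(ref_row.encode(), dtype=np.uint8) != ord(GAP))
        return cls(list(names), list(labels), list(sequences), cols)


@dataclass
class AlignedRows:
    """A (sub-)alignment where each row carries the multiset of labels it represents."""

    names: list[str]
    labels: list[list[str]]
    sequences: list[str]

    def __len__(self) -> int:
        return len(self.sequences)


def extract_region(panel: HomininPanel, rsrs_start: int, rsrs_end: int) -> AlignedRows:
    """Columns of the panel covering RSRS positions [rsrs_start, rsrs_end].

    Coordinates are 1-based inclusive and must not wrap; the caller splits a
    wrapped interval into two extractions (see extract_region_circular).
    """
    if rsrs_start < 1 or rsrs_end < rsrs_start:
        raise ValueError("invalid RSRS interval")
    if rsrs_end > panel.mt_length:
        raise ValueError(f"RSRS position {rsrs_end} beyond mapped range {panel.mt_length}")
    c0 = int(panel.rsrs_column_map[rsrs_start - 1])
    c1 = int(panel.rsrs_column_map[rsrs_end - 1])
    return AlignedRows(
        names=list(panel.names),
        labels=[[l] for l in panel.labels],
        sequences=[s[c0 : c1 + 1] for s in panel.sequences],
    )


def extract_region_circular(
    panel: HomininPanel, rsrs_start: int, rsrs_end: int
) -> AlignedRows:
    """Like extract_region but a start > end interval wraps through the origin."""
    if rsrs_start <= rsrs_end:
        return extract_region(panel, rsrs_start, rsrs_end)
    head = extract_region(panel, rsrs_start, panel.mt_length)
    tail = extract_region(panel, 1, rsrs_end)
    return AlignedRows(
        names=head.names,
        labels=head.labels,
        sequences=[a + b for a, b in zip(head.sequences, tail.sequences)],
    )


def add_numt_row(rows: AlignedRows, numt_name: str, numt_sequence: str) -> AlignedRows:
    """Append the NUMT consensus as an extra row of the sub-alignment.

    The row must already be laid out on the extraction's columns (uncovered
    positions as gaps); for the default gap-free panel this is direct
    coordinate placement.
    """
    if len(numt_sequence) != len(rows.sequences[0]):
        raise ValueError("NUMT row length does not match the sub-alignment")
    return AlignedRows(
        names=rows.names + [numt_name],
        labels=rows.labels + [["numt"]],
        sequences=rows.sequences + [numt_sequence],
    )


def dedupe_alignment(rows: AlignedRows) -> AlignedRows:
    """Collapse identical sequences, pooling their labels; keeps first names."""
    seen: dict[str, int] = {}
    names: list[str] = []
    labels: list[list[str]] = []
    seqs: list[str] = []
    for name, labs, seq in zip(rows.names, rows.labels, rows.sequences):
        if seq in seen:
            labels[seen[seq]].extend(labs)
        else:
            seen[seq] = len(seqs)
            names.append(name)
            labels.append(list(labs))
            seqs.append(seq)
    return AlignedRows(names=names, labels=labels, sequences=seqs)


# ---------------------------------------------------------------------------
# Pairwise distances


@dataclass
class DistanceSummary:
    """Within/between-group pairwise difference counts (Hamming, non-gap columns)."""

    counts: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def get(self, g1: str, g2: str) -> list[int]:
        return self.counts.get((g1, g2)) or self.counts.get((g2, g1)) or []

    def mean(self, g1: str, g2: str) -> float:
        vals = self.get(g1, g2)
        return float(np.mean(vals)) if vals else float("nan")


def hamming_nongap(a: str, b: str) -> int:
    """Sites where two aligned sequences differ, over columns non-gap in both."""
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    ok = (x != ord(GAP)) & (y != ord(GAP))
    return int(((x != y) & ok).sum())


_SUMMARY_GROUPS = ("modern_human", "neanderthal", "denisovan", "numt")


def pairwise_distances(rows: AlignedRows, groups=_SUMMARY_GROUPS) -> DistanceSummary:
    """All pairwise difference counts, grouped within/between lineages.

    Rows that represent several collapsed sequences contribute once per
    represented label, matching counts computed on the un-deduped alignment.
    """
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    summary = DistanceSummary()
    n = len(rows)
    for i in range(n):
        for j in range(i, n):
            d = None
            for gi in rows.labels[i]:
                for gj in rows.labels[j]:
                    if gi not in groups or gj not in groups:
                        continue
                    if i == j and gi == gj:
                        continue  # a row paired with itself within one label
                    if d is None:
                        d = hamming_nongap(rows.sequences[i], rows.sequences[j])
                    key = (gi, gj) if (gi, gj) in summary.counts or gi <= gj else (gj, gi)
                    summary.counts.setdefault(key, []).append(d)
    return summary


# ---------------------------------------------------------------------------
# Tree building and classification


@dataclass
class TreeResult:
    newick: str
    clades: dict[frozenset, float]  # rooted clade (tip-name set) -> bootstrap %
    n_distinct: int
    tip_names: frozenset


@dataclass
class LineageCall:
    numt_id: str
    category: str
    tree: str | None
    bootstrap_support: float
    n_diagnostic: int
    reason: str | None = None


def _encode(rows: AlignedRows) -> np.ndarray:
    return np.vstack(
        [np.frombuffer(s.encode(), dtype=np.uint8) for s in rows.sequences]
    )


def _jc_matrix(mat: np.ndarray) -> np.ndarray:
    """Jukes-Cantor distances over pairwise non-gap (and non-N) columns."""
    valid = (mat != ord(GAP)) & (mat != ord("N"))
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        ok = valid[i] & valid
        diff = (mat[i] != mat) & ok
        nv = ok.sum(axis=1).astype(float)
        p = np.divide(diff.sum(axis=1), nv, out=np.zeros(n), where=nv > 0)
        p_safe = np.minimum(p, 0.7449)
        dist = np.where(p < 0.745, -0.75 * np.log1p(-4.0 * p_safe / 3.0), 5.0)
        dist = np.where(nv > 0, dist, 5.0)
        d[i] = dist
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _rooted_clades(tree, names: list[str], outgroup: str) -> set[frozenset]:
    """Clades of the tree rooted on the outgroup, as tip-name sets."""
    allnames = frozenset(names)
    clades: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if outgroup in side:
            side = allnames - side
        if 1 < len(side) < len(allnames) - 1:
            clades.add(side)
    return clades


def build_tree(
    rows: AlignedRows,
    outgroup_name: str,
    n_bootstrap: int = 100,
    rng: np.random.Generator | None = None,
) -> TreeResult | None:
    """Neighbor-joining tree (Jukes-Cantor) rooted on the outgroup, with
    nonparametric bootstrap support from column resampling.

    Returns None when fewer than four distinct sequences are available: such
    alignments cannot produce an informative tree.
    """
    if len(rows) < 4:
        return None
    if outgroup_name not in rows.names:
        raise ValueError("outgroup row missing from alignment")
    rng = rng if rng is not None else np.random.default_rng(0)
    mat = _encode(rows)
    names = list(rows.names)
    dm = DistanceMatrix(_jc_matrix(mat), names)
    tree = nj(dm)
    main_clades = _rooted_clades(tree, names, outgroup_name)
    counts = {c: 0 for c in main_clades}
    L = mat.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        bmat = mat[:, cols]
        btree = nj(DistanceMatrix(_jc_matrix(bmat), names))
        bclades = _rooted_clades(btree, names, outgroup_name)
        for c in main_clades:
            if c in bclades:
                counts[c] += 1
    support = {c: 100.0 * counts[c] / n_bootstrap for c in main_clades}
    return TreeResult(
        newick=str(tree).strip(),
        clades=support,
        n_distinct=len(rows),
        tip_names=frozenset(names),
    )


def _diagnostic_count(rows: AlignedRows, numt_name: str, lineage_labels: frozenset) -> int:
    """Columns where the NUMT shares the allele of every tip of the assigned
    lineage while every modern-human tip carries a different allele."""
    idx = rows.names.index(numt_name)
    numt = rows.sequences[idx]
    lineage_rows = [
        s for s, labs in zip(rows.sequences, rows.labels)
        if any(l in lineage_labels for l in labs) and s is not numt
    ]
    modern_rows = [
        s for s, labs in zip(rows.sequences, rows.labels)
        if any(l in MODERN_LABELS for l in labs)
    ]
    if not lineage_rows or not modern_rows:
        return 0
    n = 0
    for col in range(len(numt)):
        a = numt[col]
        if a in (GAP, "N"):
            continue
        lin = [s[col] for s in lineage_rows if s[col] not in (GAP, "N")]
        mod = [s[col] for s in modern_rows if s[col] not in (GAP, "N")]
        if not lin or not mod:
            continue
        if all(b == a for b in lin) and all(b != a for b in mod):
            n += 1
    return n


def classify(
    tree_result: TreeResult | None,
    rows: AlignedRows,
    numt_name: str,
    bootstrap_gate: float = 50.0,
    numt_id: str | None = None,
) -> LineageCall:
    """Assign the NUMT's lineage of origin from the rooted tree.

    The smallest supported clade containing the NUMT decides: companions all
    Denisovan/Sima -> denisovan; all Neanderthal -> neanderthal; all modern
    human -> modern_human; Neanderthal+Denisovan -> the shared archaic
    ancestral state.  A NUMT attached outside the clade of all humans is
    ancestral to all humans.  Anything else — mixed companions, no supported
    clade, or fewer than four distinct sequences — is unclassifiable.
    """
    numt_id = numt_id or numt_name
    if tree_result is None:
        return LineageCall(numt_id, "unclassifiable", None, 0.0, 0, reason="fewer than 4 distinct sequences")

    labels_by_name = dict(zip(rows.names, rows.labels))

    def category_for(companions: set):
        if companions <= DENISOVAN_LABELS:
            return "denisovan", DENISOVAN_LABELS
        if companions <= NEANDERTHAL_LABELS:
            return "neanderthal", NEANDERTHAL_LABELS
        if companions <= MODERN_LABELS:
            return "modern_human", MODERN_LABELS
        if companions <= ARCHAIC_LABELS:
            return "neanderthal_denisovan_ancestral", ARCHAIC_LABELS
        return None, None

    # A NUMT whose sequence collapsed onto identical panel rows is classified
    # by those rows directly: identity is stronger evidence than any clade.
    own = set(labels_by_name[numt_name]) - {"numt"}
    if own:
        cat, core = category_for(own)
        if cat is not None:
            n_diag = _diagnostic_count(rows, numt_name, core) if cat != "modern_human" else 0
            return LineageCall(numt_id, cat, tree_result.newick, 100.0, n_diag)
        return LineageCall(
            numt_id, "unclassifiable", tree_result.newick, 0.0, 0,
            reason="identical to rows of conflicting lineages",
        )

    # Pure tips of each archaic lineage: an archaic call requires the clade to
    # hold the complete lineage (the group must be monophyletic with the NUMT
    # inside), not just a few stray tips.
    def pure_tips(core: frozenset):
        return {
            n
            for n, labs in labels_by_name.items()
            if n != numt_name and set(labs) and set(labs) <= core
        }

    informative = [
        (clade, support)
        for clade, support in tree_result.clades.items()
        if numt_name in clade and support >= bootstrap_gate
    ]
    informative.sort(key=lambda cs: len(cs[0]))
    for clade, support in informative:
        companions = set()
        for name in clade:
            if name == numt_name:
                continue
            companions.update(labels_by_name[name])
        companions.discard("numt")
        if not companions:
            continue
        cat, core = category_for(companions)
        if cat is None:
            continue  # mixed modern/archaic companions: not an admissible clade
        if cat != "modern_human" and not pure_tips(core) <= clade:
            continue  # incomplete archaic group: the lineage is not monophyletic here
        n_diag = _diagnostic_count(rows, numt_name, core) if cat != "modern_human" else 0
        return LineageCall(numt_id, cat, tree_result.newick, support, n_diag)

    # No supported clade groups the NUMT with any lineage: check whether all
    # humans (modern + archaic) form a clade excluding it -> ancestral.
    outgroup = next(
        n for n, labs in labels_by_name.items() if "outgroup" in labs
    )
    humans = frozenset(
        n for n in tree_result.tip_names if n not in (numt_name, outgroup)
    )
    support = tree_result.clades.get(humans, 0.0)
    if support >= bootstrap_gate:
        n_diag = _diagnostic_count(
            rows, numt_name, ARCHAIC_LABELS | frozenset({"outgroup"})
        )
        return LineageCall(numt_id, "ancestral_all", tree_result.newick, support, n_diag)
    return LineageCall(
        numt_id, "unclassifiable", tree_result.newick, 0.0, 0, reason="no admissible supported clade"
    )
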