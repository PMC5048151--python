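"""Distance- and character-based DNA barcode analysis.

Implements uncorrected p-distances and Kimura two-parameter (K2P)
distances with pairwise deletion of ambiguous sites, haplotype
collapsing, intra/interspecific distance summaries, the barcode gap,
canonical neighbour-joining with column-bootstrap branch support, and
extraction of pure (species-fixed) diagnostic characters.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    InsufficientDataError,
    SaturationError,
    UndefinedDistanceError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_DECODE = np.array(list("ACGTN-"))
NUCLEOTIDES = "ACGT"


# ---------------------------------------------------------------------------
# containers

@dataclass
class AlignedSequences:
    """A fixed-length alignment of uppercase DNA sequences over {A,C,G,T,N,-}."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("sequence ids are not unique")
        self.seqs = [s.upper() for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - set(_CODE)
            if bad:
                raise ValidationError(f"sequence {sid!r} has invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.seqs[0]) if self.seqs else 0

    def encoded(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, length)."""
        lut = np.full(128, 255, dtype=np.uint8)
        for base, code in _CODE.items():
            lut[ord(base)] = code
        flat = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        return lut[flat].reshape(len(self.seqs), self.length)

    @classmethod
    def from_encoded(cls, ids: list[str], enc: np.ndarray) -> "AlignedSequences":
        return cls(list(ids), ["".join(_DECODE[row]) for row in enc])

    @classmethod
    def from_fasta(cls, path) -> "AlignedSequences":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path, partition: dict[str, str] | None = None) -> None:
        """Write FASTA; with a partition, headers become ``id|species``."""
        records = []
        for sid, s in zip(self.ids, self.seqs):
            name = f"{sid}|{partition[sid]}" if partition else sid
            records.append(SeqRecord(Seq(s), id=name, description=""))
        SeqIO.write(records, str(path), "fasta")


def partition_from_headers(aln: AlignedSequences) -> tuple[AlignedSequences, dict[str, str]]:
    """Split ``id|species`` FASTA headers into plain ids and a partition map."""
    ids, partition = [], {}
    for sid in aln.ids:
        if "|" not in sid:
            raise ValidationError(f"header {sid!r} lacks an '|species' suffix")
        plain, species = sid.rsplit("|", 1)
        ids.append(plain)
        partition[plain] = species
    return AlignedSequences(ids, list(aln.seqs)), partition


def read_partition(path) -> dict[str, str]:
    """Read a two-column ``specimen_id,species`` CSV into a dict."""
    df = pd.read_csv(path)
    if not {"specimen_id", "species"} <= set(df.columns):
        raise ValidationError("partition CSV needs columns specimen_id, species")
    return dict(zip(df["specimen_id"].astype(str), df["species"].astype(str)))


def write_partition(partition: dict[str, str], path) -> None:
    pd.DataFrame(
        {"specimen_id": list(partition), "species": list(partition.values())}
    ).to_csv(path, index=False)


def check_partition(aln: AlignedSequences, partition: dict[str, str]) -> None:
    missing = [i for i in aln.ids if i not in partition]
    if missing:
        raise ValidationError(f"partition does not cover sequence ids: {missing[:5]}")


def species_in(partition: dict[str, str]) -> list[str]:
    """Species labels in order of first appearance."""
    seen: dict[str, None] = {}
    for sp in partition.values():
        seen.setdefault(sp, None)
    return list(seen)


# ---------------------------------------------------------------------------
# pairwise distances

def _encode_one(seq: str) -> np.ndarray:
    return AlignedSequences(["x"], [seq]).encoded()[0]


def _site_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable, transitions, transversions) under pairwise deletion."""
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    transition = diff & ((a & 1) == (b & 1))  # A<->G, C<->T share parity
    n_diff = int(diff.sum())
    n_ts = int(transition.sum())
    return int(comparable.sum()), n_ts, n_diff - n_ts


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion of N/-."""
    ea, eb = _encode_one(a), _encode_one(b)
    if ea.shape != eb.shape:
        raise ValidationError("sequences have unequal lengths")
    comp, ts, tv = _site_counts(ea, eb)
    if comp == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    return (ts + tv) / comp


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance with pairwise deletion.

    With transition proportion P and transversion proportion Q over the
    comparable sites: ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)``.
    """
    ea, eb = _encode_one(a), _encode_one(b)
    if ea.shape != eb.shape:
        raise ValidationError("sequences have unequal lengths")
    comp, ts, tv = _site_counts(ea, eb)
    if comp == 0:
        raise UndefinedDistanceError("no comparable sites between sequences")
    P, Q = ts / comp, tv / comp
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


METRICS = {"p": p_distance, "k2p": k2p_distance}


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with taxon labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def _pairwise_encoded(enc: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs distances on an encoded alignment (vectorised)."""
    a = enc[:, None, :]
    b = enc[None, :, :]
    comparable = (a < 4) & (b < 4)
    diff = comparable & (a != b)
    comp = comparable.sum(axis=2).astype(float)
    if (comp == 0).any():
        raise UndefinedDistanceError("a sequence pair has no comparable sites")
    n_diff = diff.sum(axis=2)
    if metric == "p":
        d = n_diff / comp
    elif metric == "k2p":
        ts = (diff & ((a & 1) == (b & 1))).sum(axis=2)
        P = ts / comp
        Q = (n_diff - ts) / comp
        w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if (w1 <= 0).any() or (w2 <= 0).any():
            raise SaturationError("K2P undefined for at least one pair (saturation)")
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    else:
        raise ValidationError(f"unknown metric {metric!r}; expected 'p' or 'k2p'")
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # exact symmetry


def distance_matrix(aln: AlignedSequences, metric: str = "k2p") -> DistanceMatrix:
    """Pairwise distance matrix over all sequences in the alignment."""
    return DistanceMatrix(list(aln.ids), _pairwise_encoded(aln.encoded(), metric))


# ---------------------------------------------------------------------------
# haplotypes and summaries

def collapse_haplotypes(
    aln: AlignedSequences, partition: dict[str, str]
) -> tuple[AlignedSequences, dict[str, int], dict[str, str]]:
    """Collapse identical sequences within each species to one haplotype.

    Two sequences collapse when they agree at every site where both carry
    an unambiguous base (so N/- never separate haplotypes).  The first
    sequence in input order names the haplotype.  Sequences identical
    across species are never merged.

    Returns the collapsed alignment, a map haplotype id -> multiplicity,
    and the remapped partition.
    """
    check_partition(aln, partition)
    enc = aln.encoded()
    reps: list[int] = []
    multiplicity: dict[str, int] = {}
    for idx, sid in enumerate(aln.ids):
        match = None
        for r in reps:
            if partition[aln.ids[r]] != partition[sid]:
                continue
            both = (enc[r] < 4) & (enc[idx] < 4)
            if (enc[r][both] == enc[idx][both]).all():
                match = r
                break
        if match is None:
            reps.append(idx)
            multiplicity[sid] = 1
        else:
            multiplicity[aln.ids[match]] += 1
    collapsed = AlignedSequences([aln.ids[r] for r in reps], [aln.seqs[r] for r in reps])
    new_partition = {i: partition[i] for i in collapsed.ids}
    return collapsed, multiplicity, new_partition


@dataclass
class DistanceSummary:
    """Intra- and interspecific pairwise distance statistics."""

    metric: str
    intra: pd.DataFrame   # species, n_pairs, mean, se, min, max
    inter: pd.DataFrame   # species_a, species_b, n_pairs, mean, se, min, max
    n_excluded: int = 0


def _stats(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return {
        "n_pairs": arr.size,
        "mean": float(arr.mean()),
        "se": se,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def _pair_values(
    aln: AlignedSequences, partition: dict[str, str], metric: str
) -> tuple[dict[str, list[float]], dict[tuple[str, str], list[float]], int]:
    check_partition(aln, partition)
    fn = METRICS[metric] if metric in METRICS else None
    if fn is None:
        raise ValidationError(f"unknown metric {metric!r}")
    enc = aln.encoded()
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    order = species_in({i: partition[i] for i in aln.ids})
    rank = {sp: k for k, sp in enumerate(order)}
    excluded = 0
    for i, j in itertools.combinations(range(len(aln)), 2):
        comp, ts, tv = _site_counts(enc[i], enc[j])
        try:
            if comp == 0:
                raise UndefinedDistanceError("no comparable sites")
            if metric == "p":
                d = (ts + tv) / comp
            else:
                P, Q = ts / comp, tv / comp
                if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
                    raise SaturationError("saturated pair")
                d = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        except (UndefinedDistanceError, SaturationError):
            excluded += 1
            logger.warning("excluding undefined %s distance for pair (%s, %s)",
                           metric, aln.ids[i], aln.ids[j])
            continue
        sa, sb = partition[aln.ids[i]], partition[aln.ids[j]]
        if sa == sb:
            intra.setdefault(sa, []).append(float(d))
        else:
            key = (sa, sb) if rank[sa] < rank[sb] else (sb, sa)
            inter.setdefault(key, []).append(float(d))
    return intra, inter, excluded


def distance_summary(
    aln: AlignedSequences, partition: dict[str, str], metric: str = "k2p"
) -> DistanceSummary:
    """Mean/SE/min/max of within- and between-species pairwise distances.

    SE is the sample standard deviation of the pairwise values divided by
    the square root of the number of pairs.  Species with fewer than two
    members contribute no intra row (noted in the log).
    """
    intra, inter, excluded = _pair_values(aln, partition, metric)
    order = species_in({i: partition[i] for i in aln.ids})
    for sp in order:
        if sp not in intra:
            logger.info("species %r has <2 members; intraspecific stats omitted", sp)
    intra_df = pd.DataFrame(
        [{"species": sp, **_stats(v)} for sp, v in intra.items()]
    )
    inter_df = pd.DataFrame(
        [{"species_a": a, "species_b": b, **_stats(v)} for (a, b), v in inter.items()]
    )
    return DistanceSummary(metric=metric, intra=intra_df, inter=inter_df, n_excluded=excluded)


@dataclass
class BarcodeGap:
    """Extremes of the intra/inter distance distributions."""

    metric: str
    max_intra: float
    max_intra_pair: tuple[str, str]
    min_inter: float
    min_inter_pair: tuple[str, str]
    gap: bool


def barcode_gap(
    aln: AlignedSequences, partition: dict[str, str], metric: str = "k2p"
) -> BarcodeGap:
    """Maximum intraspecific vs minimum interspecific pairwise distance."""
    if len(species_in({i: partition[i] for i in aln.ids if i in partition})) < 2:
        raise InsufficientDataError("barcode gap needs at least two species")
    check_partition(aln, partition)
    enc = aln.encoded()
    d = _pairwise_encoded(enc, metric)
    sp = np.array([partition[i] for i in aln.ids])
    iu = np.triu_indices(len(aln), k=1)
    same = sp[iu[0]] == sp[iu[1]]
    vals = d[iu]
    if not same.any():
        raise InsufficientDataError("no intraspecific pairs")
    intra_idx = np.flatnonzero(same)[np.argmax(vals[same])]
    inter_idx = np.flatnonzero(~same)[np.argmin(vals[~same])]
    max_intra = float(vals[intra_idx])
    min_inter = float(vals[inter_idx])
    return BarcodeGap(
        metric=metric,
        max_intra=max_intra,
        max_intra_pair=(aln.ids[iu[0][intra_idx]], aln.ids[iu[1][intra_idx]]),
        min_inter=min_inter,
        min_inter_pair=(aln.ids[iu[0][inter_idx]], aln.ids[iu[1][inter_idx]]),
        gap=bool(max_intra < min_inter),
    )


# ---------------------------------------------------------------------------
# neighbour joining

@dataclass
class TreeNode:
    name: str | None = None
    support: float | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out


@dataclass
class Tree:
    """Unrooted tree, represented with a trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset, float]:
        """Map canonical non-trivial splits to their branch lengths."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> None:
            for child, length in node.children:
                if not child.is_leaf():
                    side = frozenset(child.leaf_names())
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[_canonical_split(side, all_leaves)] = length
                walk(child)

        walk(self.root)
        return out

    def supports(self) -> dict[frozenset, float]:
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                if not child.is_leaf() and child.support is not None:
                    side = frozenset(child.leaf_names())
                    if 1 < len(side) < len(all_leaves) - 1:
                        out[_canonical_split(side, all_leaves)] = child.support
                walk(child)

        walk(self.root)
        return out

    def to_newick(self, support_threshold: float | None = None) -> str:
        """Newick string; internal-node labels carry bootstrap supports.

        Supports below ``support_threshold`` (percent) are omitted from
        the output, matching the common reporting convention.
        """

        def fmt(node: TreeNode, length: float | None) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                if node.support is not None and (
                    support_threshold is None or node.support >= support_threshold
                ):
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.10g}"

        return fmt(self.root, None) + ";"


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representative of a bipartition: the side not holding min(leaf)."""
    anchor = min(all_leaves)
    return all_leaves - side if anchor in side else side


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical neighbour joining (Saitou–Nei with Studier–Keppler Q).

    Ties in the Q criterion break towards the smallest index pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise InsufficientDataError("neighbour joining requires at least 3 taxa")
    D = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = dij / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        dnew = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            dnew[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(dnew) - 1] = dnew[:-1]
        D[: len(dnew) - 1, -1] = dnew[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    i, j, k = active
    a_len = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    b_len = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    c_len = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    root = TreeNode(
        children=[
            (nodes[i], max(a_len, 0.0)),
            (nodes[j], max(b_len, 0.0)),
            (nodes[k], max(c_len, 0.0)),
        ]
    )
    return Tree(root)


def nj_from_alignment(
    aln: AlignedSequences, metric: str = "k2p"
) -> Tree:
    """Convenience: distance matrix + NJ in one step."""
    return nj_tree(distance_matrix(aln, metric))


@dataclass
class BootstrapResult:
    tree: Tree
    n_reps: int
    n_dropped: int
    supports: dict[frozenset, float]


def bootstrap_support(
    aln: AlignedSequences,
    metric: str = "k2p",
    n_reps: int = 1000,
    seed: int = 0,
    *,
    partition: dict[str, str] | None = None,
    collapse: bool = False,
    support_threshold: float = 75.0,
) -> BootstrapResult:
    """Column-bootstrap branch support for the NJ tree.

    Alignment columns are resampled with replacement ``n_reps`` times; an
    internal edge's support is the percentage of replicates whose NJ tree
    contains the same bipartition.  Replicates with undefined distances
    are dropped and counted; more than 10% dropped raises a saturation
    warning.  With ``collapse=True`` sequences are first collapsed to
    within-species haplotypes (requires ``partition``).
    """
    if aln.length < 2:
        raise ValidationError("alignment too short to bootstrap")
    if collapse:
        if partition is None:
            raise ValidationError("collapse=True requires a partition")
        aln, _, partition = collapse_haplotypes(aln, partition)
    if len(aln) < 3:
        raise InsufficientDataError("bootstrap requires at least 3 sequences")
    enc = aln.encoded()
    base = nj_tree(DistanceMatrix(list(aln.ids), _pairwise_encoded(enc, metric)))
    counts: dict[frozenset, int] = {split: 0 for split in base.bipartitions()}
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, aln.length)
        try:
            d = _pairwise_encoded(enc[:, cols], metric)
        except (SaturationError, UndefinedDistanceError):
            dropped += 1
            continue
        rep = nj_tree(DistanceMatrix(list(aln.ids), d))
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    n_ok = n_reps - dropped
    if dropped > 0.1 * n_reps:
        warnings.warn(
            f"{dropped}/{n_reps} bootstrap replicates dropped (saturation)",
            RuntimeWarning,
            stacklevel=2,
        )
    supports = {s: 100.0 * c / n_ok if n_ok else 0.0 for s, c in counts.items()}

    all_leaves = frozenset(aln.ids)

    def attach(node: TreeNode) -> None:
        for child, _ in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    child.support = supports[_canonical_split(side, all_leaves)]
            attach(child)

    attach(base.root)
    return BootstrapResult(tree=base, n_reps=n_reps, n_dropped=dropped, supports=supports)


# ---------------------------------------------------------------------------
# character-based diagnostics

@dataclass
class DiagnosticTable:
    """Pure (species-fixed, exclusive) diagnostic characters.

    ``pure`` maps species -> {1-based position: nucleotide}; ``table``
    gives the full species-by-state context for every position at which
    at least one species is pure.
    """

    pure: dict[str, dict[int, str]]
    table: pd.DataFrame  # position, species, states, is_pure, pure_state

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def pure_diagnostic_characters(
    aln: AlignedSequences, partition: dict[str, str]
) -> DiagnosticTable:
    """Scan the alignment for pure diagnostic positions.

    A position/state pair is pure for a species when every member of the
    species carries that state and no specimen of any other species does.
    Ambiguous symbols (N, -) do not count as states; all-gap columns are
    skipped and logged.  Positions are reported 1-based.
    """
    check_partition(aln, partition)
    order = species_in({i: partition[i] for i in aln.ids})
    if not order:
        raise InsufficientDataError("empty alignment")
    enc = aln.encoded()
    sp = np.array([partition[i] for i in aln.ids])
    pure: dict[str, dict[int, str]] = {s: {} for s in order}
    rows = []
    for col in range(aln.length):
        column = enc[:, col]
        if (column >= 4).all():
            logger.warning("column %d is all-ambiguous; skipped", col + 1)
            continue
        states = {
            s: {str(b) for b in _DECODE[column[(sp == s) & (column < 4)]]}
            for s in order
        }
        col_rows = []
        any_pure = False
        for s in order:
            own = states[s]
            others = set().union(*(states[t] for t in order if t != s))
            is_pure = len(own) == 1 and not (own & others)
            if is_pure:
                pure[s][col + 1] = next(iter(own))
                any_pure = True
            col_rows.append(
                {
                    "position": col + 1,
                    "species": s,
                    "states": "/".join(sorted(own)) if own else "",
                    "is_pure": is_pure,
                    "pure_state": next(iter(own)) if is_pure else "",
                }
            )
        if any_pure:
            rows.extend(col_rows)
    table = pd.DataFrame(
        rows, columns=["position", "species", "states", "is_pure", "pure_state"]
    )
    return DiagnosticTable(pure=pure, table=table)
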