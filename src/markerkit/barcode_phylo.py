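"""DNA-barcode alignment diagnostics and distance-based phylogeny.

Implements the alignment summaries used to compare candidate barcode loci
(conserved / variable / parsimony-informative / singleton sites, indel
columns, transition:transversion ratio R = si/sv) and distance trees:
pairwise distances under the p-distance, Kimura 2-parameter (K2P) and
Tamura 3-parameter (T3P) substitution models, with neighbor-joining
(Saitou-Nei) tree construction.

Gap handling follows the complete-deletion convention by default: any
column containing a gap (or an ambiguous residue) is excluded from site
classes, si/sv counts and distances; ``gaps="pairwise"`` switches the
pairwise statistics to per-pair deletion.

Model formulas, with P and Q the transition and transversion proportions
of the compared pair and theta the mean GC content:

* K2P:  d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
* T3P:  d = -h ln(1 - P/h - Q) - 1/2 (1 - h) ln(1 - 2Q),  h = 2 theta (1 - theta)

T3P reduces to K2P at theta = 0.5 (h = 1/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import SaturationError, ValidationError
from .io import SequenceSet

__all__ = [
    "SiteSummary",
    "classify_sites",
    "count_si_sv",
    "pairwise_distance",
    "distance_matrix",
    "nj_tree",
    "tree_report",
    "TreeReport",
]

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


@dataclass(frozen=True)
class SiteSummary:
    """Alignment-wide site-class counts and substitution-pair totals."""

    n_sites: int
    n_conserved: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_indel_sites: int
    n_excluded: int  # columns dropped (gap or ambiguous residue)
    si: int
    sv: int

    @property
    def r(self) -> float | None:
        """Transition:transversion ratio; None when no transversions."""
        return self.si / self.sv if self.sv else None


def _check_aligned(alignment: SequenceSet) -> list[str]:
    if not alignment.aligned:
        raise ValidationError("input must be an alignment (aligned flag set)")
    if len(alignment) < 2:
        raise ValidationError("alignment needs at least 2 sequences")
    return alignment.seqs


def _column_classes(seqs: list[str]):
    """Yield (column_residues, has_gap, has_ambiguous) per alignment site."""
    for col in zip(*seqs):
        has_gap = "-" in col
        has_amb = any(c not in _BASES and c != "-" for c in col)
        yield col, has_gap, has_amb


def classify_sites(alignment: SequenceSet) -> SiteSummary:
    """Classify every alignment column and count pairwise si/sv.

    Gap-free, unambiguous columns are conserved (a single state),
    singleton (variable, but at most one state seen in >= 2 sequences) or
    parsimony-informative (>= 2 states each in >= 2 sequences).  Columns
    with any gap count as indel sites; together with ambiguous columns
    they are excluded from the substitution classes, so
    ``n_conserved + n_variable + n_excluded = n_sites``.
    """
    seqs = _check_aligned(alignment)
    n_cons = n_pi = n_single = n_indel = n_excl = 0
    si = sv = 0
    for col, has_gap, has_amb in _column_classes(seqs):
        if has_gap:
            n_indel += 1
        if has_gap or has_amb:
            n_excl += 1
            continue
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) == 1:
            n_cons += 1
        else:
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pi += 1
            else:
                n_single += 1
        for a, b in combinations(col, 2):
            if a != b:
                if _is_transition(a, b):
                    si += 1
                else:
                    sv += 1
    return SiteSummary(
        n_sites=alignment.n_sites,
        n_conserved=n_cons,
        n_variable=n_pi + n_single,
        n_parsimony_informative=n_pi,
        n_singleton=n_single,
        n_indel_sites=n_indel,
        n_excluded=n_excl,
        si=si,
        sv=sv,
    )


def count_si_sv(alignment: SequenceSet, gaps: str = "complete") -> tuple[int, int, float | None]:
    """Total transition/transversion pair counts and their ratio R.

    Sums over all sequence pairs and retained columns.  R is ``None``
    (undefined) when no transversions are observed.
    """
    seqs = _check_aligned(alignment)
    si = sv = 0
    if gaps == "complete":
        cols = [
            col
            for col, has_gap, has_amb in _column_classes(seqs)
            if not (has_gap or has_amb)
        ]
        for col in cols:
            for a, b in combinations(col, 2):
                if a != b:
                    if _is_transition(a, b):
                        si += 1
                    else:
                        sv += 1
    elif gaps == "pairwise":
        for s1, s2 in combinations(seqs, 2):
            for a, b in zip(s1, s2):
                if a in _BASES and b in _BASES and a != b:
                    if _is_transition(a, b):
                        si += 1
                    else:
                        sv += 1
    else:
        raise ValidationError(f"unknown gap mode {gaps!r}")
    return si, sv, (si / sv if sv else None)


def _pair_counts(s1: str, s2: str, exclude: set[int] | None):
    """(n, transitions, transversions, mean GC) over retained columns."""
    n = ts = tv = gc = tot_bases = 0
    for i, (a, b) in enumerate(zip(s1, s2)):
        if exclude is not None and i in exclude:
            continue
        if a not in _BASES or b not in _BASES:
            if exclude is None:
                continue  # pairwise deletion
            raise ValidationError("unexpected non-ACGT residue in retained column")
        n += 1
        gc += (a in "GC") + (b in "GC")
        tot_bases += 2
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    theta = gc / tot_bases if tot_bases else 0.0
    return n, ts, tv, theta


def _excluded_columns(seqs: list[str]) -> set[int]:
    return {
        i
        for i, (_, has_gap, has_amb) in enumerate(_column_classes(seqs))
        if has_gap or has_amb
    }


def _safe_log(x: float, context: str) -> float:
    if x <= 0.0:
        raise SaturationError(
            f"substitution saturation: log argument {x:.6g} <= 0 ({context})"
        )
    return math.log(x)


def pairwise_distance(
    s1: str,
    s2: str,
    model: str = "k2p",
    gaps: str = "pairwise",
    exclude: set[int] | None = None,
) -> float:
    """Model-corrected distance between two aligned sequences.

    ``model`` is one of ``"p"`` (uncorrected proportion of differing
    sites), ``"k2p"`` or ``"t3p"``; theta for T3P is the mean GC content
    of the two sequences over retained columns.  ``exclude`` (column
    indices) implements complete deletion when distances are computed
    matrix-wide.
    """
    if len(s1) != len(s2):
        raise ValidationError("sequences must be aligned to equal length")
    if exclude is None and gaps == "complete":
        exclude = _excluded_columns([s1, s2])
    n, ts, tv, theta = _pair_counts(s1, s2, exclude)
    if n == 0:
        raise ValidationError("no comparable columns after gap removal")
    p = ts / n
    q = tv / n
    model = model.lower()
    if model in ("p", "p-distance"):
        return p + q
    if model == "k2p":
        return -0.5 * _safe_log(1.0 - 2.0 * p - q, "K2P") - 0.25 * _safe_log(
            1.0 - 2.0 * q, "K2P"
        )
    if model == "t3p":
        h = 2.0 * theta * (1.0 - theta)
        if h == 0.0:
            raise SaturationError("T3P undefined at GC content 0 or 1 (h = 0)")
        return -h * _safe_log(1.0 - p / h - q, "T3P") - 0.5 * (1.0 - h) * _safe_log(
            1.0 - 2.0 * q, "T3P"
        )
    raise ValidationError(f"unknown distance model {model!r}")


def distance_matrix(
    alignment: SequenceSet, model: str = "k2p", gaps: str = "complete"
) -> DistanceMatrix:
    """All pairwise model distances; complete deletion drops any column
    with a gap or ambiguity across the whole alignment before comparing."""
    seqs = _check_aligned(alignment)
    exclude = _excluded_columns(seqs) if gaps == "complete" else None
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_distance(
            seqs[i], seqs[j], model=model, gaps=gaps, exclude=exclude
        )
    return DistanceMatrix(d, ids=alignment.ids)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix | np.ndarray) -> TreeNode:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Standard Q-criterion agglomeration; the final three clusters are
    resolved with the three-point formulas, so additive matrices are
    reproduced exactly by the tree's path lengths.  Negative branch
    lengths are clamped to zero with a warning.  For two taxa the trivial
    two-leaf tree is returned with the full distance split across the
    root.  Leaf order in the output follows the input ids.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValidationError("distance matrix is not symmetric")
        dm = DistanceMatrix(arr, ids=[f"t{i}" for i in range(arr.shape[0])])
    ids = list(dm.ids)
    n = len(ids)

    def _clamp(x: float, what: str) -> float:
        if x < 0.0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:.4g} for {what}; clamped to 0")
            return 0.0
        return x

    if n < 2:
        raise ValidationError("need at least 2 taxa")
    if n == 2:
        d = dm[0, 1]
        return TreeNode(
            children=[
                TreeNode(name=ids[0], length=d / 2.0),
                TreeNode(name=ids[1], length=d / 2.0),
            ]
        )

    nodes: dict[int, TreeNode] = {i: TreeNode(name=lab) for i, lab in enumerate(ids)}
    dist: dict[tuple[int, int], float] = {
        (i, j): dm[i, j] for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    next_id = n

    def d_of(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d_of(i, k) for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d_of(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best, best_q = (i, j), q
        i, j = best
        dij = d_of(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = _clamp(li, f"node {i}")
        nodes[j].length = _clamp(lj, f"node {j}")
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            dist[(min(next_id, k), max(next_id, k))] = 0.5 * (
                d_of(i, k) + d_of(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        nodes[next_id] = parent
        next_id += 1

    i, j, k = active
    dij, dik, djk = d_of(i, j), d_of(i, k), d_of(j, k)
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    nodes[i].length = _clamp(li, "3-point")
    nodes[j].length = _clamp(lj, "3-point")
    nodes[k].length = _clamp(lk, "3-point")
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


@dataclass(frozen=True)
class TreeReport:
    """Patristic distances plus the tip partition under the root."""

    patristic: DistanceMatrix
    clades: tuple[frozenset, ...]

    def distance(self, a: str, b: str) -> float:
        return float(self.patristic[a, b])

    def same_clade(self, a: str, b: str) -> bool:
        return any(a in c and b in c for c in self.clades)


def tree_report(tree: TreeNode) -> TreeReport:
    """Patristic distance matrix and root-level clade memberships."""
    dm = tree.tip_tip_distances()
    clades = []
    for child in tree.children:
        tips = frozenset(t.name for t in child.tips()) or frozenset({child.name})
        clades.append(tips)
    if not clades:
        clades = [frozenset(t.name for t in tree.tips())]
    return TreeReport(patristic=dm, clades=tuple(clades))
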