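"""Deterministic synthetic-data generators.

The generators emulate the three kinds of raw input the analysis modules
consume, so the full pipeline is testable without lab data:

* band matrices with *exactly* prescribed per-band presence counts over a
  small number of taxa, optionally expanded to replicate population rows
  with a per-cell flip noise rate (emulating scoring variation across
  replicate gel lanes);
* small sequence families evolved down a taxon tree under a Kimura-type
  two-class substitution process with controllable transition:transversion
  ratio, GC content and single-column indels;
* PCR template sequences embedding primer binding sites at prescribed
  separations, plus optional near-match decoy sites.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .errors import ValidationError
from .io import BandMatrix, Locus, SequenceSet
from .scar import PrimerPair, reverse_complement

__all__ = [
    "BandProfileSpec",
    "SeqSimSpec",
    "TemplateLayout",
    "DecoySpec",
    "gen_band_matrix",
    "gen_alignment",
    "gen_pcr_template",
]


# ---------------------------------------------------------------------------
# band matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandProfileSpec:
    """Recipe for a band matrix.

    ``profiles`` maps primer name -> list of ``(presence_count, multiplicity)``
    pairs: "``multiplicity`` bands present in exactly ``presence_count`` of
    the ``n_taxa`` taxa".  ``replicates`` expands each taxon into that many
    ``taxon/rep`` rows copying the taxon's pattern; ``noise_rate`` then
    flips each replicate cell independently.
    """

    profiles: Mapping[str, Sequence[tuple[int, int]]]
    n_taxa: int = 4
    taxa: Sequence[str] | None = None
    replicates: int = 1
    noise_rate: float = 0.0

    def taxon_labels(self) -> list[str]:
        if self.taxa is not None:
            if len(self.taxa) != self.n_taxa:
                raise ValidationError("len(taxa) != n_taxa")
            return list(self.taxa)
        return [f"T{i + 1}" for i in range(self.n_taxa)]


def gen_band_matrix(spec: BandProfileSpec, seed: int = 0) -> BandMatrix:
    """Realize a :class:`BandProfileSpec` exactly.

    Presence counts are met exactly (taxa carrying each band are chosen
    pseudo-randomly from the seed), not just in expectation.  With
    replicates and a positive noise rate, flipped cells may not preserve
    the counts; a column that noise zeroes out entirely is repaired by
    restoring one carrier cell, since a never-observed band is unscorable.
    """
    rng = np.random.default_rng(seed)
    taxa = spec.taxon_labels()
    n = spec.n_taxa
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    for primer, bands in spec.profiles.items():
        b = 0
        for k, mult in bands:
            if not 1 <= k <= n:
                raise ValidationError(
                    f"presence count {k} outside [1, {n}] for primer {primer!r} "
                    "(a band absent everywhere is unobservable)"
                )
            if mult < 1:
                raise ValidationError("band multiplicity must be >= 1")
            for _ in range(mult):
                b += 1
                col = np.zeros(n, dtype=np.int8)
                col[rng.choice(n, size=k, replace=False)] = 1
                loci.append(Locus(primer, f"b{b}"))
                cols.append(col)
    values = np.column_stack(cols)
    if spec.replicates <= 1:
        return BandMatrix(taxa=taxa, loci=loci, values=values)

    rep_taxa: list[str] = []
    rep_rows: list[np.ndarray] = []
    for i, t in enumerate(taxa):
        for r in range(spec.replicates):
            rep_taxa.append(f"{t}/P{r + 1}")
            row = values[i].copy()
            if spec.noise_rate > 0:
                flips = rng.random(row.size) < spec.noise_rate
                row = np.where(flips, 1 - row, row).astype(np.int8)
            rep_rows.append(row)
    rep_values = np.array(rep_rows)
    dead = ~rep_values.any(axis=0)
    for j in np.nonzero(dead)[0]:
        carrier = int(np.argmax(values[:, j]))  # first original carrier
        rep_values[carrier * spec.replicates, j] = 1
    return BandMatrix(taxa=rep_taxa, loci=loci, values=rep_values)


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqSimSpec:
    """Recipe for a small aligned sequence family.

    ``tree`` is a Newick string with branch lengths in expected
    substitutions per site.  ``kappa`` is the nominal transition:
    transversion *ratio* of substitution events (each event is a
    transition with probability kappa/(1+kappa)), so the counted si/sv
    ratio of the output converges to ``kappa`` at low divergence.
    ``indel_rate`` is the expected number of single-column deletion
    events per site over each branch.
    """

    tree: str
    root_length: int
    gc: float = 0.5
    kappa: float = 4.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValidationError("root sequence length must be >= 1")
        if not 0.0 < self.gc < 1.0:
            raise ValidationError("GC content must lie in (0, 1)")
        if self.kappa < 0 or self.indel_rate < 0:
            raise ValidationError("rates must be >= 0")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _evolve(seq: list[str], gaps: set[int], branch: float, spec: SeqSimSpec, rng) -> tuple[list[str], set[int]]:
    L = len(seq)
    seq = seq.copy()
    gaps = set(gaps)
    n_sub = rng.poisson(branch * L)
    p_ti = 1.0 if np.isinf(spec.kappa) else spec.kappa / (1.0 + spec.kappa)
    for _ in range(n_sub):
        i = int(rng.integers(L))
        if i in gaps:
            continue
        base = seq[i]
        if rng.random() < p_ti:
            seq[i] = _TRANSITION[base]
        else:
            seq[i] = _TRANSVERSIONS[base][int(rng.integers(2))]
    n_indel = rng.poisson(spec.indel_rate * branch * L)
    for _ in range(n_indel):
        gaps.add(int(rng.integers(L)))
    return seq, gaps


def gen_alignment(spec: SeqSimSpec, seed: int = 0) -> SequenceSet:
    """Evolve a root sequence down ``spec.tree``; returns an aligned set.

    The root is drawn i.i.d. with the requested GC content; substitution
    events per branch are Poisson with mean ``branch_length * L`` (sites
    hit with replacement, so multiple hits occur as in a real process);
    deletion events turn single sites into ``-`` for the subtree below
    the branch.  Leaf order follows the Newick tip order.
    """
    rng = np.random.default_rng(seed)
    tree = TreeNode.read([spec.tree])
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    alphabet = np.array(list("ACGT"))
    root_seq = list(rng.choice(alphabet, size=spec.root_length, p=p))

    ids: list[str] = []
    seqs: list[str] = []

    def descend(node, seq, gaps):
        for child in node.children:
            bl = child.length or 0.0
            cseq, cgaps = _evolve(seq, gaps, bl, spec, rng)
            if child.is_tip():
                ids.append(child.name)
                seqs.append(
                    "".join("-" if i in cgaps else c for i, c in enumerate(cseq))
                )
            else:
                descend(child, cseq, cgaps)

    if tree.is_tip():
        raise ValidationError("tree must have at least one internal node")
    descend(tree, root_seq, set())
    return SequenceSet(ids=ids, seqs=seqs, aligned=True)


# ---------------------------------------------------------------------------
# PCR templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoySpec:
    """A near-match site: a copy of ``primer`` with ``n_mismatches``
    substitutions placed in its 5' half (so the 3' end stays matched and
    rejection is down to the mismatch budget alone)."""

    template_id: str
    primer: str
    n_mismatches: int


@dataclass(frozen=True)
class TemplateLayout:
    """Per-template spacer lengths (between the embedded forward site and
    reverse-complement reverse site), flank length and background GC."""

    spacers: Mapping[str, int]
    flank: int = 60
    gc: float = 0.5
    decoys: Sequence[DecoySpec] = field(default_factory=tuple)


def _random_seq(rng, length: int, gc: float) -> str:
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _avoid_sites(rng, background: str, primers: Sequence[str], gc: float) -> str:
    """Rerandomise the background until it contains no exact primer site
    on either strand (keeps constructed templates unambiguous)."""
    needles = [p.upper() for p in primers] + [reverse_complement(p) for p in primers]
    for _ in range(100):
        if not any(n in background for n in needles):
            return background
        background = _random_seq(rng, len(background), gc)
    raise ValidationError("could not build a background free of primer sites")


def _mutate(rng, site: str, n_mismatches: int) -> str:
    half = max(len(site) // 2, 1)
    if n_mismatches > half:
        raise ValidationError("too many decoy mismatches for the primer's 5' half")
    pos = rng.choice(half, size=n_mismatches, replace=False)
    out = list(site)
    for i in pos:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def gen_pcr_template(
    pairs: Mapping[str, PrimerPair],
    layout: TemplateLayout,
    seed: int = 0,
) -> SequenceSet:
    """One template per primer pair: flank + forward site + spacer +
    reverse-complemented reverse site + flank (plus any decoys appended
    after the trailing flank, separated by a neutral spacer).

    The spacer is the number of background bases between the two embedded
    sites, so the predicted product length is
    ``len(forward) + spacer + len(reverse)``.
    """
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    seqs: list[str] = []
    for name, pair in pairs.items():
        if name not in layout.spacers:
            raise ValidationError(f"no spacer length for template {name!r}")
        spacer_len = layout.spacers[name]
        if spacer_len < 0:
            raise ValidationError("spacer must be >= 0")
        all_primers = [pair.forward, pair.reverse]
        left = _avoid_sites(rng, _random_seq(rng, layout.flank, layout.gc), all_primers, layout.gc)
        spacer = _avoid_sites(rng, _random_seq(rng, spacer_len, layout.gc), all_primers, layout.gc)
        right = _avoid_sites(rng, _random_seq(rng, layout.flank, layout.gc), all_primers, layout.gc)
        template = left + pair.forward + spacer + reverse_complement(pair.reverse) + right
        for decoy in layout.decoys:
            if decoy.template_id != name:
                continue
            site = _mutate(rng, decoy.primer.upper(), decoy.n_mismatches)
            pad = _avoid_sites(rng, _random_seq(rng, 20, layout.gc), all_primers, layout.gc)
            template = template + pad + site
        ids.append(name)
        seqs.append(template)
    return SequenceSet(ids=ids, seqs=seqs, aligned=False)
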