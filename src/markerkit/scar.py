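"""In-silico SCAR workflow: primer-site search, amplicon prediction,
cross-species specificity and internal primer design.

A SCAR (sequence characterized amplified region) marker converts a
distinctive dominant-marker band into a single-locus assay: the cloned
fragment — which starts with the originating RAPD decamer and ends with
its reverse complement — is sequenced, and a longer, specific primer pair
is designed strictly inside the fragment, excluding the decamer regions.

Coordinates are 1-based inclusive on the supplied (plus) strand; the
predicted product length is measured between the outermost primer 5' ends,
inclusive, matching gel-estimated sizes.  Primer-site matching treats
IUPAC ambiguity codes in the primer as character classes, and by default
demands zero mismatches with an exact 3'-terminal zone, mirroring a binary
band / no-band readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import DesignError, ValidationError
from .io import IUPAC_DNA, SequenceSet

__all__ = [
    "PrimerPair",
    "PrimerSite",
    "AmpliconHit",
    "DesignConstraints",
    "find_primer_sites",
    "insilico_pcr",
    "specificity_matrix",
    "assess_specificity",
    "design_scar_primers",
    "estimate_tm",
    "reverse_complement",
]

_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with optional assay metadata."""

    name: str
    forward: str
    reverse: str
    product_length: int | None = None
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            s = seq.upper()
            object.__setattr__(self, label, s)
            bad = set(s) - IUPAC_DNA
            if not s or bad:
                raise ValidationError(
                    f"{self.name} {label} primer invalid (empty or non-IUPAC {sorted(bad)})"
                )

    def validate_scar(self) -> None:
        """SCAR primers must be specific: at least 15 nt each."""
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValidationError(
                f"{self.name}: SCAR primers must be >= 15 nt "
                f"(got {len(self.forward)}/{len(self.reverse)})"
            )


class PrimerSite(NamedTuple):
    start: int  # 1-based inclusive, plus strand
    end: int
    strand: str  # '+' : primer 3' end at `end`; '-' : primer 3' end at `start`
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product on a template's plus strand."""

    template_id: str
    start: int  # 5' end of the plus-strand primer site (1-based)
    end: int  # 3'-most base of the minus-strand primer site
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _matches(primer_char: str, template_char: str) -> bool:
    return template_char in _IUPAC_CLASS.get(primer_char, "")


def find_primer_sites(
    template: str,
    primer: str,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
) -> list[PrimerSite]:
    """All annealing sites of ``primer`` on both strands of ``template``.

    A site is rejected if it exceeds ``max_mismatch`` total mismatches or
    has any mismatch within the ``three_prime_exact`` 3'-terminal primer
    positions (extension requires a matched 3' end).  Returns sites in
    plus-strand coordinate order.
    """
    template = template.upper()
    primer = primer.upper()
    L, k = len(template), len(primer)
    if k == 0:
        raise ValidationError("empty primer")
    hits: list[PrimerSite] = []
    if k > L:
        return hits
    rc = reverse_complement(primer)
    for off in range(L - k + 1):
        window = template[off : off + k]
        # plus strand: primer left->right, 3' end rightmost
        mm = sum(1 for p, t in zip(primer, window) if not _matches(p, t))
        if mm <= max_mismatch:
            tail = sum(
                1
                for p, t in zip(primer[k - three_prime_exact :], window[k - three_prime_exact :])
                if not _matches(p, t)
            )
            if tail == 0:
                hits.append(PrimerSite(off + 1, off + k, "+", mm))
        # minus strand: the site appears as revcomp(primer); 3' end leftmost
        mm = sum(1 for p, t in zip(rc, window) if not _matches(p, t))
        if mm <= max_mismatch:
            tail = sum(
                1
                for p, t in zip(rc[:three_prime_exact], window[:three_prime_exact])
                if not _matches(p, t)
            )
            if tail == 0:
                hits.append(PrimerSite(off + 1, off + k, "-", mm))
    return hits


def insilico_pcr(
    template: str,
    pair: PrimerPair,
    template_id: str = "template",
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    max_product: int = 5000,
) -> list[AmpliconHit]:
    """Predict PCR products of ``pair`` on ``template``.

    A product requires one primer annealed on the plus strand and the
    other on the minus strand strictly downstream (either orientation of
    the pair), with the minus-strand site starting after the plus-strand
    site ends.  Products longer than ``max_product`` are discarded.  An
    empty list means no amplification.
    """
    combos = [(pair.forward, pair.reverse), (pair.reverse, pair.forward)]
    if pair.forward == pair.reverse:
        combos = combos[:1]
    products: dict[tuple[int, int], AmpliconHit] = {}
    for plus_primer, minus_primer in combos:
        plus_hits = [
            h for h in find_primer_sites(template, plus_primer, max_mismatch, three_prime_exact)
            if h.strand == "+"
        ]
        minus_hits = [
            h for h in find_primer_sites(template, minus_primer, max_mismatch, three_prime_exact)
            if h.strand == "-"
        ]
        for fh in plus_hits:
            for rh in minus_hits:
                if rh.start <= fh.end:
                    continue
                length = rh.end - fh.start + 1
                if length > max_product:
                    continue
                key = (fh.start, rh.end)
                if key not in products:
                    products[key] = AmpliconHit(
                        template_id=template_id,
                        start=fh.start,
                        end=rh.end,
                        fwd_mismatches=fh.mismatches,
                        rev_mismatches=rh.mismatches,
                    )
    return [products[k] for k in sorted(products)]


def specificity_matrix(
    pairs: Sequence[PrimerPair],
    templates: SequenceSet | Mapping[str, str],
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    max_product: int = 5000,
) -> pd.DataFrame:
    """Binary amplification matrix: one row per primer pair, one column
    per template (species); 1 = at least one predicted product."""
    if isinstance(templates, SequenceSet):
        templates = dict(zip(templates.ids, templates.seqs))
    data = {}
    for pair in pairs:
        row = {}
        for sid, seq in templates.items():
            hits = insilico_pcr(
                seq, pair, sid, max_mismatch, three_prime_exact, max_product
            )
            row[sid] = int(bool(hits))
        data[pair.name] = row
    return pd.DataFrame.from_dict(data, orient="index")


def assess_specificity(
    matrix: pd.DataFrame, pair_to_species: Mapping[str, str]
) -> dict[str, bool]:
    """A pair is specific when exactly its own species' template amplifies."""
    out = {}
    for pair_name, row in matrix.iterrows():
        target = pair_to_species[pair_name]
        out[pair_name] = bool(row.get(target, 0) == 1 and row.sum() == 1)
    return out


def estimate_tm(primer: str) -> float:
    """Wallace-rule melting temperature 2(A+T) + 4(G+C), in deg C.

    A quick screening heuristic for short (<= ~20 nt) oligos; rejects
    ambiguity codes, for which base composition is undefined.
    """
    primer = primer.upper()
    bad = set(primer) - set("ACGT")
    if not primer or bad:
        raise ValidationError(
            f"Wallace Tm needs a non-empty ACGT-only primer (got {sorted(bad)})"
        )
    gc = sum(primer.count(b) for b in "GC")
    return 2.0 * (len(primer) - gc) + 4.0 * gc


@dataclass(frozen=True)
class DesignConstraints:
    """Candidate filters for internal SCAR primer design.

    Lengths in nt, GC in percent, temperatures in deg C (Wallace rule).
    ``min_product``/``max_product`` bound the predicted amplicon; the
    default upper bound is the fragment length.
    """

    min_length: int = 18
    max_length: int = 20
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 45.0
    tm_max: float = 65.0
    max_tm_diff: float = 5.0
    min_product: int = 100
    max_product: int | None = None
    max_candidates_per_side: int = 80


def _gc_percent(seq: str) -> float:
    return 100.0 * sum(seq.count(b) for b in "GC") / len(seq)


def design_scar_primers(
    fragment: str,
    rapd_primer: str,
    constraints: DesignConstraints | None = None,
) -> list[PrimerPair]:
    """Design internal primer pairs for a cloned RAPD fragment.

    The fragment must begin with the RAPD decamer and end with its
    reverse complement (as cloned RAPD products do).  Candidate primers
    are drawn strictly inside the region between — never overlapping —
    the two terminal decamer copies, filtered on length, GC and Wallace
    Tm, and paired subject to the product-length window.  Pairs are
    ranked by Tm balance (|Tm_f - Tm_r|), then by longer product, then by
    position; returns an empty list when the filters admit no pair.
    """
    cons = constraints or DesignConstraints()
    fragment = fragment.upper()
    rapd_primer = rapd_primer.upper()
    k = len(rapd_primer)
    min_needed = 2 * k + max(cons.min_product, 2 * cons.min_length)
    if len(fragment) < min_needed:
        raise DesignError(
            f"fragment of {len(fragment)} nt too short to design internal primers"
        )
    if fragment[:k] != rapd_primer or fragment[-k:] != reverse_complement(rapd_primer):
        raise DesignError(
            "fragment does not start with the RAPD decamer and end with its "
            "reverse complement"
        )
    interior_start = k  # 0-based; first position after the leading decamer
    interior_end = len(fragment) - k  # exclusive; last position before trailing copy
    max_product = cons.max_product or len(fragment)

    fwd_cands: list[tuple[float, int, str, float]] = []  # (tm, start0, seq, gc)
    rev_cands: list[tuple[float, int, str, float]] = []  # start0 of site on + strand
    for length in range(cons.min_length, cons.max_length + 1):
        for s in range(interior_start, interior_end - length + 1):
            sub = fragment[s : s + length]
            if set(sub) - set("ACGT"):
                continue
            gc = _gc_percent(sub)
            if not cons.gc_min <= gc <= cons.gc_max:
                continue
            tm = estimate_tm(sub)
            if not cons.tm_min <= tm <= cons.tm_max:
                continue
            fwd_cands.append((tm, s, sub, gc))
            rev_cands.append((tm, s, reverse_complement(sub), gc))
    # keep the candidates closest to the Tm window centre, deterministically
    tm_centre = (cons.tm_min + cons.tm_max) / 2.0
    key = lambda c: (abs(c[0] - tm_centre), c[1], len(c[2]))
    fwd_cands = sorted(fwd_cands, key=key)[: cons.max_candidates_per_side]
    rev_cands = sorted(rev_cands, key=key)[: cons.max_candidates_per_side]

    scored: list[tuple[float, int, int, PrimerPair]] = []
    for tm_f, sf, fseq, _ in fwd_cands:
        for tm_r, sr, rseq, _ in rev_cands:
            site_start = sr  # 0-based start of the reverse-primer site
            site_end = sr + len(rseq) - 1
            if site_start <= sf + len(fseq) - 1:
                continue  # footprints must not overlap
            product = site_end - sf + 1
            if not cons.min_product <= product <= max_product:
                continue
            dtm = abs(tm_f - tm_r)
            if dtm > cons.max_tm_diff:
                continue
            pair = PrimerPair(
                name=f"scar_{sf + 1}_{site_end + 1}",
                forward=fseq,
                reverse=rseq,
                product_length=product,
            )
            scored.append((dtm, -product, sf, pair))
    scored.sort(key=lambda t: t[:3])
    return [p for *_, p in scored]
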