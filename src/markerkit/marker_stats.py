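"""Per-primer band classification and informativeness statistics.

For dominant (band present/absent) markers each scored band behaves as a
biallelic locus whose presence frequency ``f`` is the fraction of taxa
showing the band.  The per-primer summary statistics are the ones routinely
reported for ISSR/RAPD fingerprinting panels:

* ``PIC``  — polymorphic information content of a dominant band,
  ``2 f (1 - f)`` per band, averaged over the primer's bands (monomorphic
  bands contribute 0); maximal 0.5 at ``f = 0.5``.
* ``EMR``  — effective multiplex ratio, ``n_poly * (n_poly / n_total)``:
  the polymorphic-band yield of one assay weighted by its polymorphic
  fraction; equals ``n_poly`` at 100 % polymorphism.
* ``MI``   — marker index, ``PIC * EMR``.
* ``RP``   — resolving power, the sum of per-band informativeness
  ``I_b = 1 - 2 |0.5 - f|`` (1 at f = 0.5, 0 for fixed bands).

Frequencies are computed over distinct taxa by default (replicate rows are
collapsed to a per-species consensus first); pass ``level="replicate"`` to
compute them over all rows as scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ValidationError
from .io import BandMatrix

__all__ = [
    "PrimerStats",
    "BandClassification",
    "band_frequencies",
    "classify_bands",
    "pic_dominant",
    "emr",
    "marker_index",
    "resolving_power",
    "primer_stats",
    "primer_stats_table",
    "invert_band_profile",
]


class BandClassification(NamedTuple):
    n_total: int
    n_mono: int
    n_poly: int
    pct_poly: float


@dataclass(frozen=True)
class PrimerStats:
    """All Table-style summary columns for one primer (exact, unrounded)."""

    primer: str
    n_total: int
    n_mono: int
    n_poly: int
    pct_poly: float
    pic: float
    emr: float
    mi: float
    rp: float


def _effective_matrix(matrix: BandMatrix, level: str) -> BandMatrix:
    if level == "species":
        return matrix.collapse()
    if level == "replicate":
        return matrix
    raise ValueError(f"unknown level {level!r}; use 'species' or 'replicate'")


def band_frequencies(matrix: BandMatrix, level: str = "species") -> np.ndarray:
    """Per-locus presence frequency f = (taxa with band) / (taxa), in locus order."""
    m = _effective_matrix(matrix, level)
    return m.values.sum(axis=0) / m.n_taxa


def classify_bands(matrix: BandMatrix, level: str = "species") -> BandClassification:
    """Count total/monomorphic/polymorphic bands and percent polymorphism.

    A band is monomorphic iff present in every taxon (f = 1).  All-zero
    loci are rejected by the BandMatrix validator upstream; the guard here
    covers consensus collapses that may zero a column.
    """
    freqs = band_frequencies(matrix, level)
    if (freqs == 0).any():
        j = int(np.argmax(freqs == 0))
        raise ValidationError(
            f"locus {matrix.loci[j].label!r} absent from every taxon at "
            f"level {level!r}: a never-observed band cannot be scored"
        )
    n_total = len(freqs)
    n_mono = int((freqs == 1).sum())
    n_poly = n_total - n_mono
    return BandClassification(n_total, n_mono, n_poly, 100.0 * n_poly / n_total)


def pic_dominant(freqs: Sequence[float]) -> float:
    """Mean dominant-marker PIC, 2f(1-f) averaged over the primer's bands."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValidationError("PIC needs at least one band")
    return float(np.mean(2.0 * freqs * (1.0 - freqs)))


def emr(n_poly: int, n_total: int) -> float:
    """Effective multiplex ratio n_poly * (n_poly / n_total)."""
    if n_total < 1:
        raise ValidationError("EMR needs n_total >= 1")
    if not 0 <= n_poly <= n_total:
        raise ValidationError(f"n_poly={n_poly} outside [0, {n_total}]")
    return n_poly * n_poly / n_total


def marker_index(pic: float, emr_value: float) -> float:
    """Marker index MI = PIC * EMR (exact product; rounding is formatting)."""
    return pic * emr_value


def resolving_power(freqs: Sequence[float]) -> float:
    """Sum of band informativeness I_b = 1 - 2|0.5 - f| over all bands."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValidationError("RP needs at least one band")
    return float(np.sum(1.0 - 2.0 * np.abs(0.5 - freqs)))


def primer_stats(
    matrix: BandMatrix, primer: str | None = None, level: str = "species"
) -> PrimerStats:
    """Summary statistics for a single-primer matrix."""
    if primer is None:
        primers = matrix.primers
        if len(primers) != 1:
            raise ValidationError(
                f"matrix covers primers {primers}; pass one matrix per primer"
            )
        primer = primers[0]
    freqs = band_frequencies(matrix, level)
    cls = classify_bands(matrix, level)
    pic = pic_dominant(freqs)
    e = emr(cls.n_poly, cls.n_total)
    return PrimerStats(
        primer=primer,
        n_total=cls.n_total,
        n_mono=cls.n_mono,
        n_poly=cls.n_poly,
        pct_poly=cls.pct_poly,
        pic=pic,
        emr=e,
        mi=marker_index(pic, e),
        rp=resolving_power(freqs),
    )


_COLUMNS = [
    "total_bands",
    "monomorphic_bands",
    "polymorphic_bands",
    "pct_polymorphism",
    "PIC",
    "EMR",
    "MI",
    "RP",
]


def primer_stats_table(
    matrices: BandMatrix | Sequence[BandMatrix],
    level: str = "species",
    decimals: int | None = None,
) -> pd.DataFrame:
    """Per-primer statistics plus 'Total' and 'Mean' aggregate rows.

    Accepts a single multi-primer matrix (split on locus provenance) or a
    list of single-primer matrices.  ``decimals`` applies half-up rounding
    for presentation; values are exact otherwise.
    """
    if isinstance(matrices, BandMatrix):
        per_primer = list(matrices.by_primer().values())
    else:
        per_primer = list(matrices)
    stats = [primer_stats(m, level=level) for m in per_primer]
    if not stats:
        raise ValidationError("no primers to summarise")
    rows = {
        s.primer: [s.n_total, s.n_mono, s.n_poly, s.pct_poly, s.pic, s.emr, s.mi, s.rp]
        for s in stats
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=_COLUMNS)
    total_bands = int(df["total_bands"].sum())
    total_poly = int(df["polymorphic_bands"].sum())
    total = [
        total_bands,
        int(df["monomorphic_bands"].sum()),
        total_poly,
        100.0 * total_poly / total_bands,
        np.nan,
        np.nan,
        np.nan,
        np.nan,
    ]
    mean = [df[c].mean() for c in _COLUMNS]
    df.loc["Total"] = total
    df.loc["Mean"] = mean
    if decimals is not None:
        for c in _COLUMNS[3:]:
            df[c] = df[c].map(
                lambda x: round_half_up(x, decimals) if np.isfinite(x) else x
            )
    return df


def invert_band_profile(
    n_total: int,
    n_mono: int,
    pic: float,
    n_taxa: int = 4,
    tol: float = 2e-3,
) -> list[tuple[int, int]]:
    """Recover a 4-taxon presence-count profile from (band counts, mean PIC).

    For ``n_taxa = 4`` a polymorphic band has f in {1/4, 1/2, 3/4}, so its
    PIC is 0.375 (f = 1/4 or 3/4) or 0.5 (f = 1/2), and the primer mean
    determines how many bands sit at each frequency.  Returns a profile as
    ``[(presence_count, multiplicity), ...]`` suitable for the synthetic
    band-matrix generator; raises ValidationError when no admissible
    profile reproduces ``pic`` within ``tol`` (covering 4-decimal rounding
    or truncation of a published mean).
    """
    if n_taxa != 4:
        raise NotImplementedError("profile inversion is defined for 4 taxa")
    n_poly = n_total - n_mono
    best_a, best_diff = None, float("inf")
    for a in range(n_poly + 1):  # a bands at f=0.5, rest at f=0.25
        mean = (0.5 * a + 0.375 * (n_poly - a)) / n_total
        diff = abs(mean - pic)
        if diff < best_diff:
            best_a, best_diff = a, diff
    if best_a is None or best_diff > tol:
        raise ValidationError(
            f"no 4-taxon frequency profile with {n_poly} polymorphic of "
            f"{n_total} bands has mean PIC {pic} (closest off by {best_diff:.4f})"
        )
    profile: list[tuple[int, int]] = []
    if best_a:
        profile.append((2, best_a))
    if n_poly - best_a:
        profile.append((1, n_poly - best_a))
    if n_mono:
        profile.append((n_taxa, n_mono))
    return profile
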