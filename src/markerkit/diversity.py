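"""POPGENE-style genetic-diversity estimates for dominant markers.

Dominant band data hide heterozygotes, so allele frequencies must be
inferred from band absence: under Hardy-Weinberg the null-allele frequency
at a locus with band frequency ``f`` is ``q = sqrt(1 - f)`` (the
square-root estimator, the classic default for dominant data), with
``p = 1 - q``.  Per-locus indices follow:

* ``Na`` — observed alleles: 2 when 0 < p < 1, else 1; under two-allele
  dominant coding the group mean obeys ``Na = 1 + PL / n_loci`` exactly.
* ``Ne`` — effective alleles, ``1 / (p^2 + q^2)``.
* ``H``  — Nei's gene diversity (expected heterozygosity), ``1 - p^2 - q^2``.
* ``I``  — Shannon's information index, ``-p ln p - q ln q``.

``group_diversity`` computes within-group band frequencies from replicate
rows (populations of a species), then averages the indices over all loci.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import BandMatrix

__all__ = [
    "DiversitySummary",
    "allele_freqs_dominant",
    "locus_diversity",
    "group_diversity",
]


@dataclass(frozen=True)
class DiversitySummary:
    group: str
    n_loci: int
    pl: int
    ppl: float
    na: float
    ne: float
    h: float
    i: float


class LocusDiversity(NamedTuple):
    na: int
    ne: float
    h: float
    i: float


def allele_freqs_dominant(
    f: float, method: str = "sqrt", n: int | None = None
) -> tuple[float, float]:
    """Dominant-band allele frequencies (p, q) from band frequency ``f``.

    ``method="sqrt"``: q = sqrt(1 - f) (Hardy-Weinberg).
    ``method="lynch-milligan"``: the Taylor bias correction
    q = sqrt(x) * (1 - Var(x) / (8 x^2))^-1 with x = 1 - f and
    Var(x) = x(1 - x)/n; requires the group sample size ``n`` and x > 0.
    """
    if not 0.0 <= f <= 1.0:
        raise ValidationError(f"band frequency {f} outside [0, 1]")
    x = 1.0 - f
    if method == "sqrt":
        q = math.sqrt(x)
    elif method == "lynch-milligan":
        if n is None:
            raise ValidationError("lynch-milligan correction needs sample size n")
        if x == 0.0:
            q = 0.0
        else:
            var = x * (1.0 - x) / n
            q = math.sqrt(x) / (1.0 - var / (8.0 * x * x))
            q = min(q, 1.0)
    else:
        raise ValidationError(f"unknown allele-frequency method {method!r}")
    return 1.0 - q, q


def locus_diversity(p: float, q: float) -> LocusDiversity:
    """Per-locus Na, Ne, H and I from allele frequencies (p + q = 1)."""
    if abs(p + q - 1.0) > 1e-9:
        raise ValidationError(f"allele frequencies must sum to 1 (got {p + q})")
    hom = p * p + q * q
    na = 2 if 0.0 < p < 1.0 else 1
    ne = 1.0 / hom
    h = 1.0 - hom
    i = 0.0
    for freq in (p, q):
        if freq > 0.0:
            i -= freq * math.log(freq)
    return LocusDiversity(na, ne, h, i)


def group_diversity(
    matrix: BandMatrix,
    groups: Mapping[str, str] | None = None,
    method: str = "sqrt",
) -> pd.DataFrame:
    """Per-group diversity summary (PL, PPL, Na, Ne, H, I) over all loci.

    ``groups`` maps each taxon row to its group; by default rows group by
    their ``species/replicate`` prefix.  A locus is polymorphic within a
    group when its within-group band frequency is strictly between 0 and 1.
    """
    if groups is None:
        groups = dict(zip(matrix.taxa, matrix.replicate_group))
    missing = [t for t in matrix.taxa if t not in groups]
    if missing:
        raise ValidationError(f"taxa without a group assignment: {missing}")
    order: list[str] = []
    for t in matrix.taxa:
        if groups[t] not in order:
            order.append(groups[t])
    rows = []
    for g in order:
        idx = [i for i, t in enumerate(matrix.taxa) if groups[t] == g]
        if not idx:
            raise ValidationError(f"group {g!r} is empty")
        if len(idx) < 2:
            warnings.warn(
                f"group {g!r} has a single row; within-group frequencies are degenerate"
            )
        sub = matrix.values[idx]
        freqs = sub.sum(axis=0) / len(idx)
        n_loci = matrix.n_loci
        pl = int(((freqs > 0) & (freqs < 1)).sum())
        per_locus = [
            locus_diversity(*allele_freqs_dominant(f, method=method, n=len(idx)))
            for f in freqs
        ]
        rows.append(
            DiversitySummary(
                group=g,
                n_loci=n_loci,
                pl=pl,
                ppl=100.0 * pl / n_loci,
                na=float(np.mean([d.na for d in per_locus])),
                ne=float(np.mean([d.ne for d in per_locus])),
                h=float(np.mean([d.h for d in per_locus])),
                i=float(np.mean([d.i for d in per_locus])),
            )
        )
    return pd.DataFrame(
        [
            [s.group, s.n_loci, s.pl, s.ppl, s.na, s.ne, s.h, s.i]
            for s in rows
        ],
        columns=["group", "n_loci", "PL", "PPL", "Na", "Ne", "H", "I"],
    ).set_index("group")
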