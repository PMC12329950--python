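"""Bundled reference panel: a four-species *Artemisia* marker study.

These tables describe a published-style fingerprinting panel over four
taxa — *A. annua*, *A. herba-alba*, *A. monosperma*, *A. judaica* — with
five ISSR primers (41 bands) and twenty-seven RAPD decamers (212 bands),
plus the four species-specific SCAR primer pairs derived from cloned RAPD
fragments.  Each marker row carries the reported per-primer summary
statistics (band counts, % polymorphism, PIC, EMR, MI, RP), which serve
as worked-example inputs and regression anchors for the statistics
modules.

Two cells in the OPB-13 row (MI and RP) were unreadable in the source
table and are reconstructed from the marker-index identity MI = PIC x EMR
and the band-frequency profile implied by the row's PIC.
"""

from __future__ import annotations

from typing import NamedTuple

from .scar import PrimerPair

SPECIES = ("A_annua", "A_herba-alba", "A_monosperma", "A_judaica")


class PanelRow(NamedTuple):
    """One primer row of a fingerprinting summary table."""

    name: str
    sequence: str
    n_total: int
    n_mono: int
    n_poly: int
    pct_poly: float
    pic: float
    emr: float
    mi: float
    rp: float


ISSR_PANEL: tuple[PanelRow, ...] = (
    PanelRow("SR-14", "GAGAGAGAGAGAGAYG", 7, 0, 7, 100.0, 0.4464, 7.0, 3.1248, 5.5),
    PanelRow("SR-16", "GAGAGAGAGAGAGAGAC", 10, 0, 10, 100.0, 0.4, 10.0, 4.0, 6.0),
    PanelRow("SR-33", "ACACACACACACACACCG", 8, 0, 8, 100.0, 0.4219, 8.0, 3.3752, 5.5),
    PanelRow("SR-36", "AGAGAGAGAGAGAGAGT", 10, 0, 10, 100.0, 0.4375, 10.0, 4.375, 8.5),
    PanelRow("SR-37", "ACACACACACACACACC", 6, 0, 6, 100.0, 0.4167, 6.0, 2.5, 4.0),
)

RAPD_PANEL: tuple[PanelRow, ...] = (
    PanelRow("OPG-02", "GGCACTGAGG", 10, 0, 10, 100.0, 0.4125, 10.0, 4.125, 6.5),
    PanelRow("OPG-03", "GAGCCCTCCA", 10, 0, 10, 100.0, 0.4, 10.0, 4.0, 6.0),
    PanelRow("OPG-04", "AGCGTGTCTG", 9, 0, 9, 100.0, 0.3889, 9.0, 3.5, 5.0),
    PanelRow("OPG-05", "CTGAGACGGA", 7, 0, 7, 100.0, 0.4107, 7.0, 2.8749, 4.5),
    PanelRow("OPG-06", "GTGCCTAACC", 9, 0, 9, 100.0, 0.3889, 9.0, 3.5, 5.0),
    PanelRow("OPG-07", "GAACCTGCGG", 2, 0, 2, 100.0, 0.5, 2.0, 1.0, 2.0),
    PanelRow("OPG-08", "TCACGTCCAC", 5, 0, 5, 100.0, 0.425, 5.0, 2.125, 3.5),
    PanelRow("OPG-09", "CTGACGTCAC", 10, 0, 10, 100.0, 0.3625, 10.0, 3.625, 6.5),
    PanelRow("OPA-10", "GTGATCGCAG", 15, 0, 15, 100.0, 0.375, 15.0, 5.625, 7.5),
    PanelRow("OPA-11", "CAATCGCCGT", 12, 0, 12, 100.0, 0.4062, 12.0, 4.8744, 7.5),
    PanelRow("OPA-09", "GGGTAACGCC", 7, 0, 7, 100.0, 0.4107, 7.0, 2.8749, 5.5),
    PanelRow("OPD-15", "CATCCGTGCT", 7, 0, 7, 100.0, 0.4107, 7.0, 2.8749, 5.5),
    PanelRow("OPB-19", "ACCCCCGAAG", 7, 0, 7, 100.0, 0.4286, 7.0, 3.0, 6.0),
    PanelRow("OPAT-19", "ACCAAGGCAC", 7, 0, 7, 100.0, 0.375, 7.0, 2.625, 3.5),
    PanelRow("OPK-07", "AGCGAGCAAG", 7, 0, 7, 100.0, 0.375, 7.0, 2.625, 3.5),
    PanelRow("OPS-12", "CTGGGTGAGT", 5, 0, 5, 100.0, 0.45, 5.0, 2.25, 4.0),
    PanelRow("OPB-13", "TTCCCCCGCT", 5, 0, 5, 100.0, 0.45, 5.0, 2.25, 4.0),
    PanelRow("OPA-04", "AATCGGGCTG", 9, 1, 8, 88.88, 0.375, 7.11, 2.67, 6.5),
    PanelRow("OPB-17", "AGGGAACGAG", 8, 0, 8, 100.0, 0.4062, 8.0, 3.2496, 5.0),
    PanelRow("OPB-07", "GGTGACGCAG", 6, 0, 6, 100.0, 0.3958, 6.0, 2.3748, 3.5),
    PanelRow("OPA-16", "AGCCAGCGAA", 10, 0, 10, 100.0, 0.425, 10.0, 4.25, 9.0),
    PanelRow("OPB-03", "CATCCCCCTG", 6, 0, 6, 100.0, 0.4583, 6.0, 2.7498, 5.0),
    PanelRow("OPB-20", "GGACCCTTAC", 10, 0, 10, 100.0, 0.4, 10.0, 4.0, 6.0),
    PanelRow("OPAH-17", "CAGTGGGGAG", 6, 0, 6, 100.0, 0.4583, 6.0, 2.7498, 5.0),
    PanelRow("OPA-02", "TGCCGAGCTG", 8, 0, 8, 100.0, 0.4375, 8.0, 3.5, 6.0),
    PanelRow("OPA-14", "TCTGTGCTGG", 3, 0, 3, 100.0, 0.375, 3.0, 1.125, 1.5),
    PanelRow("OPB-18", "CCACAGCAGT", 12, 0, 12, 100.0, 0.3854, 12.0, 4.6248, 6.5),
)

# Species-specific SCAR primer pairs: expected product size (bp) and
# reported annealing temperature; the RAPD primer each fragment came from.
SCAR_PAIRS: dict[str, PrimerPair] = {
    "A_annua": PrimerPair(
        "A", "GGAACACGAAGAGCATGAAC", "CCATTACGCCACCCACTAC", 223, 53.5
    ),
    "A_herba-alba": PrimerPair(
        "H", "GTCTGTATGCGCGACTTCC", "ATTGGCCCGTGTAAGCTGTG", 440, 56.0
    ),
    "A_monosperma": PrimerPair(
        "M", "CGCCACAGAAATTCGTCAG", "AAGCGCAAACACAACGAC", 361, 53.4
    ),
    "A_judaica": PrimerPair(
        "J", "CGTGCTGCATAAGAACATAG", "GATCTCTATGGGCGTGTG", 303, 51.8
    ),
}

SCAR_SOURCE_RAPD: dict[str, str] = {
    "A_annua": "OPG-02",
    "A_herba-alba": "OPG-04",
    "A_monosperma": "OPA-09",
    "A_judaica": "OPD-15",
}

# Rows whose printed RP cell is not consistent with any 4-taxon frequency
# profile matching the row's PIC (internal inconsistencies of the source
# table); profile-based regression checks skip the RP for these.
RP_INCONSISTENT = frozenset(
    {"SR-36", "OPA-04", "OPA-09", "OPD-15", "OPB-19", "OPA-16"}
)

# Rows whose PIC cannot arise from any 4-taxon frequency profile at all
# (mean per-band PIC below the 0.375 floor for fully polymorphic bands).
PROFILE_NOT_INVERTIBLE = frozenset({"OPG-09"})
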