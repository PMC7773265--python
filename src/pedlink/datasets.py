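"""Reported per-family candidate loci for primary focal hyperhidrosis.

Per-family candidate intervals from a nine-family genome-wide linkage study
of primary focal hyperhidrosis (GRCh37 coordinates), as inputs for the
interval-intersection workflow.  Genetic positions were published as
centimorgan x 1e6 integers; :func:`reported_family_loci` returns them on
the real centimorgan scale.

These are input data, not package results: the overlap coordinates and
genetic spans are recomputed from the per-family rows by
:func:`pedlink.locus_discovery.intersect_loci`.
"""

from __future__ import annotations

from .locus_discovery import CandidateLocus

__all__ = ["REPORTED_FAMILY_LOCI", "REPORTED_PENETRANCE_COUNTS", "reported_family_loci"]

# locus label -> list of (family, start_bp, end_bp, start_cM*1e6, end_cM*1e6,
#                          start snp, end snp)
_RAW = {
    "1q41-1q42.3": [
        ("F4", 200_366_091, 241_561_050, 196_250_000, 258_490_000, "rs12141206", "rs10802960"),
        ("F8", 219_001_663, 235_119_382, 224_764_300, 242_850_100, "rs6541234", "rs6586361"),
        ("F23", 210_527_418, 245_328_085, 213_910_500, 268_386_000, "rs10489388", "rs12039117"),
    ],
    "2q21.2-2q23.3": [
        ("F1", 127_868_435, 191_504_064, 140_090_400, 190_923_100, "rs6743470", "rs1558473"),
        ("F8", 133_639_374, 164_469_186, 146_047_200, 170_307_500, "rs10928436", "rs12692701"),
        ("F11", 128_516_543, 151_962_991, 140_750_500, 161_460_700, "rs7576459", "rs4664951"),
    ],
    "2p14-2p13.3": [
        ("F13", 66_815_660, 100_746_935, 89_114_600, 114_519_500, "rs12987658", "rs11885529"),
        ("F14", 52_264_332, 71_408_929, 77_289_720, 94_943_840, "rs7595947", "rs12478186"),
    ],
    "15q26.3": [
        ("F8", 101_939_918, 102_398_631, 132_705_300, 133_756_300, "rs1874274", "rs11247329"),
        ("F21", 93_807_754, 102_398_631, 105_201_600, 133_756_300, "rs11857333", "rs11247329"),
    ],
}

_CHROM = {
    "1q41-1q42.3": "1",
    "2q21.2-2q23.3": "2",
    "2p14-2p13.3": "2",
    "15q26.3": "15",
}

REPORTED_FAMILY_LOCI = _RAW

# locus-supporting individuals pooled across the significant loci:
# (affected carriers, all carriers)
REPORTED_PENETRANCE_COUNTS = (45, 58)


def reported_family_loci(locus: str) -> list[CandidateLocus]:
    """Per-family :class:`CandidateLocus` rows for one reported locus label,
    with genetic coordinates converted to centimorgan."""
    try:
        rows = _RAW[locus]
    except KeyError:
        raise KeyError(
            f"unknown locus {locus!r}; available: {sorted(_RAW)}"
        ) from None
    return [
        CandidateLocus(
            chromosome=_CHROM[locus],
            family_id=family,
            start_bp=sbp,
            end_bp=ebp,
            start_cm=scm / 1e6,
            end_cm=ecm / 1e6,
            boundary_snps=(s1, s2),
        )
        for family, sbp, ebp, scm, ecm, s1, s2 in rows
    ]
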