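"""Allele normalization and genomic HGVS construction.

Coordinates throughout the package are 1-based and fully closed, matching
the CIViC convention. Alleles are given VCF-style on ingest; :func:`trim`
removes shared anchor bases (common suffix first, then common prefix,
advancing the start) so each small variant has a unique representation:

* substitution: ``ref`` and ``alt`` both length >= 1, first bases differ
* pure deletion: ``alt`` empty, ``start..stop`` spans the deleted bases
* pure insertion: ``ref`` empty, the inserted sequence lies between
  ``start`` and ``stop`` = ``start`` + 1 (flanking-base convention)
"""

from __future__ import annotations

from .vocab import chromosome_accessions


class HgvsError(ValueError):
    """Raised for variants that cannot be rendered as genomic HGVS."""


class DegenerateVariantError(HgvsError):
    """Reference and alternate allele are identical: no variant."""


def trim(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix then prefix bases, adjusting ``start``."""
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    return start, ref, alt


def derived_coordinates(start: int, ref: str, alt: str) -> tuple[int, int]:
    """(start, stop) on the 1-based closed convention for trimmed alleles.

    Insertions use the flanking-base convention: start is the base before
    the insertion point, stop the base after.
    """
    if ref:
        return start, start + len(ref) - 1
    return start - 1, start


def format_genomic_hgvs(
    build: str, chromosome: str, start: int, stop: int, ref: str, alt: str
) -> str:
    """Render a trimmed small variant as a genomic HGVS string.

    ``start``/``stop`` follow :func:`derived_coordinates`. Substitutions
    render as ``g.POSREF>ALT``, deletions as ``g.START_STOPdel`` (or
    ``g.POSdel`` for a single base), insertions as ``g.START_STOPinsSEQ``
    with stop = start + 1, and other length changes as delins.
    """
    if ref == alt:
        raise DegenerateVariantError(
            f"reference and alternate alleles are identical ({ref!r}); not a variant"
        )
    try:
        accession = chromosome_accessions()[(build, chromosome)]
    except KeyError:
        raise HgvsError(
            f"no RefSeq accession for chromosome {chromosome!r} on build {build!r}"
        ) from None

    if len(ref) == 1 and len(alt) == 1:
        change = f"g.{start}{ref}>{alt}"
    elif not alt:  # pure deletion
        change = f"g.{start}del" if start == stop else f"g.{start}_{stop}del"
    elif not ref:  # pure insertion between flanking bases
        change = f"g.{start}_{stop}ins{alt}"
    else:  # multi-base replacement
        span = f"{start}" if start == stop else f"{start}_{stop}"
        change = f"g.{span}delins{alt}"
    return f"{accession}:{change}"
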