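"""Minimal WURCS 2.0 handling.

WURCS (Web 3.0 Unique Representation of Carbohydrate Structures) is a
linear text format for glycans.  Its header section,

    ``WURCS=<version>/<unique residues>,<residues>,<linkages>/...``

carries three integer counts.  This module parses only that header; the
residue (RES) and linkage (LIN) body is carried opaquely, because the
pathway model needs glycan identity and residue counts, nothing more.
The one piece of glycan arithmetic the model relies on is the
*single-extension rule*: each glycosyl transfer adds exactly one
monosaccharide, so a reaction product must have one residue more than
its acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import WurcsParseError

__all__ = [
    "WurcsDescriptor",
    "parse_wurcs_header",
    "residue_count",
    "is_single_extension",
]


@dataclass(frozen=True)
class WurcsDescriptor:
    """A WURCS string together with its parsed header counts.

    Attributes
    ----------
    raw_text:
        The full WURCS string, preserved verbatim (after stripping
        surrounding whitespace).
    version:
        The version token between ``WURCS=`` and the first ``/``.
    unique_residue_count, residue_count, linkage_count:
        The three comma-separated counts of the header section.
    """

    raw_text: str
    version: str
    unique_residue_count: int
    residue_count: int
    linkage_count: int


def parse_wurcs_header(
    wurcs: str,
    *,
    permissive_version: bool = False,
    strict_linear: bool = False,
) -> WurcsDescriptor:
    """Parse the WURCS header and return a :class:`WurcsDescriptor`.

    Parameters
    ----------
    wurcs:
        The WURCS string.  Leading/trailing whitespace is stripped
        (CSV cells commonly carry stray spaces); interior whitespace is
        left untouched.
    permissive_version:
        Accept any ``2.x`` version instead of exactly ``2.0``.
    strict_linear:
        Additionally require ``linkages == residues - 1``, which holds
        for connected single-chain glycans (branched or repeating
        structures may differ, so this is off by default).

    Raises
    ------
    WurcsParseError
        On a malformed prefix, unsupported version, or missing or
        non-integer count fields; the error names the offending field.
    """
    if not isinstance(wurcs, str) or not wurcs.strip():
        raise WurcsParseError("empty WURCS string", field="input")
    text = wurcs.strip()
    if not text.startswith("WURCS="):
        raise WurcsParseError(
            f"WURCS string must start with 'WURCS=': {text[:30]!r}", field="prefix"
        )
    body = text[len("WURCS="):]
    parts = body.split("/")
    if len(parts) < 2:
        raise WurcsParseError(
            "missing '/'-delimited count section after the version", field="counts"
        )
    version = parts[0]
    if permissive_version:
        ok = version == "2" or version.startswith("2.")
    else:
        ok = version == "2.0"
    if not ok:
        raise WurcsParseError(
            f"unsupported WURCS version {version!r} (expected 2.0)", field="version"
        )
    count_fields = parts[1].split(",")
    if len(count_fields) != 3:
        raise WurcsParseError(
            f"expected 3 comma-separated counts, got {len(count_fields)} "
            f"in {parts[1]!r}",
            field="counts",
        )
    names = ("unique residue count", "residue count", "linkage count")
    counts = []
    for name, field in zip(names, count_fields):
        try:
            value = int(field)
        except ValueError:
            raise WurcsParseError(
                f"non-integer {name}: {field!r}", field="counts"
            ) from None
        if value < 0:
            raise WurcsParseError(f"negative {name}: {value}", field="counts")
        counts.append(value)
    unique, residues, linkages = counts
    if unique > 0 and residues < unique:
        raise WurcsParseError(
            f"residue count {residues} is below unique residue count {unique}",
            field="counts",
        )
    if strict_linear and linkages != residues - 1:
        raise WurcsParseError(
            f"linkage count {linkages} != residue count {residues} - 1 "
            "for a linear chain",
            field="counts",
        )
    return WurcsDescriptor(
        raw_text=text,
        version=version,
        unique_residue_count=unique,
        residue_count=residues,
        linkage_count=linkages,
    )


def residue_count(wurcs: str) -> int:
    """Return the residue (monosaccharide) count from the WURCS header."""
    return parse_wurcs_header(wurcs).residue_count


def is_single_extension(acceptor_wurcs: str, product_wurcs: str) -> bool:
    """Check the single-extension rule between an acceptor and a product.

    A glycosyltransferase transfers one monosaccharide per reaction, so
    a valid product carries exactly one residue more than its acceptor.
    Returns ``True`` iff ``residues(product) == residues(acceptor) + 1``.

    Raises
    ------
    WurcsParseError
        If either argument fails to parse; the message states which one.
    """
    try:
        acceptor = parse_wurcs_header(acceptor_wurcs)
    except WurcsParseError as exc:
        raise WurcsParseError(f"acceptor: {exc}", field=exc.field) from exc
    try:
        product = parse_wurcs_header(product_wurcs)
    except WurcsParseError as exc:
        raise WurcsParseError(f"product: {exc}", field=exc.field) from exc
    return product.residue_count == acceptor.residue_count + 1
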