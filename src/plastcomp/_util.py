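"""Shared helpers: sequence arithmetic, validation, error types."""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC ambiguity codes (beyond ACGTN) are accepted on input and degraded to N.
IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
VALID_NUCS = set("ACGTN")


class PlastcompError(Exception):
    """Base class for all pipeline errors."""


class ParseError(PlastcompError):
    """A file could not be parsed in the named format."""


class ValidationError(PlastcompError):
    """Parsed content violates a structural invariant."""


class PartitionError(PlastcompError):
    """No quadripartite (LSC/IRb/SSC/IRa) structure could be found."""


class ParameterError(PlastcompError):
    """A user-supplied parameter is out of its allowed range."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def clean_sequence(seq: str, *, what: str = "sequence") -> tuple[str, int]:
    """Uppercase, validate against IUPAC codes, degrade ambiguity codes to N.

    Returns (cleaned, n_degraded). Raises ValidationError on non-IUPAC symbols.
    """
    seq = seq.upper()
    bad = set(seq) - VALID_NUCS - IUPAC_AMBIGUOUS
    if bad:
        raise ValidationError(
            f"{what} contains non-IUPAC symbols: {sorted(bad)!r}"
        )
    n_degraded = sum(seq.count(c) for c in IUPAC_AMBIGUOUS & set(seq))
    if n_degraded:
        table = str.maketrans({c: "N" for c in IUPAC_AMBIGUOUS})
        seq = seq.translate(table)
    return seq, n_degraded


def gc_content(seq: str) -> float:
    """GC fraction computed over unambiguous A/C/G/T only."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
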