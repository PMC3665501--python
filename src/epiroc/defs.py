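"""Shared constants and error types.

Genotype codes are minor-allele counts; ``MISSING`` marks an uncalled
genotype.  Phenotype coding follows the case-control convention
(0 = control, 1 = case).
"""

MISSING: int = -1

CONTROL: int = 0
CASE: int = 1

#: Direction labels for genotype-call subsets.  A subset enriched in cases
#: (odds ratio > 1) is *contributing* (high risk); one enriched in controls
#: is *protective*.  ``ANY`` means no direction restriction.
CONTRIBUTING = "contributing"
PROTECTIVE = "protective"
ANY = "any"


class EpirocError(Exception):
    """Base class for all package errors."""


class ParseError(EpirocError):
    """A genotype file could not be parsed."""


class StructuralError(EpirocError):
    """File contents are inconsistent (counts, magic bytes, truncation)."""


class DegenerateTableError(EpirocError):
    """A contingency table has no usable cases or controls."""
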