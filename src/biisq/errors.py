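"""Exception hierarchy shared across biisq modules."""


class BiisqError(Exception):
    """Base class for all biisq errors."""


class GeneNotFoundError(BiisqError, KeyError):
    """Requested gene id is absent from the annotation."""


class MalformedAnnotationError(BiisqError, ValueError):
    """Annotation records violate the expected structure (e.g. exon-less transcript)."""


class UnmappableReadError(BiisqError, ValueError):
    """A read start does not fall inside any exon of the gene model."""


class ReadTruncationError(BiisqError, ValueError):
    """A read overruns the 3'-most exon of the gene model."""


class MixedGeneError(BiisqError, ValueError):
    """Per-sample read terms refer to different gene models."""


class InvalidIsoformError(BiisqError, ValueError):
    """An isoform composition is empty or its code is out of range."""


class DegenerateDataError(BiisqError, ValueError):
    """The read-term count matrix carries no reads at all."""


class InvalidStateError(BiisqError, ValueError):
    """A model state violates its invariants (e.g. non-simplex proportions)."""
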