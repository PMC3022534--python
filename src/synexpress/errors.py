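"""Exception hierarchy.

All data-facing errors derive from :class:`SynexpressError` so callers (and
the CLI) can distinguish bad input from genuine bugs.
"""


class SynexpressError(Exception):
    """Base class for errors raised by synexpress."""


class OntologyError(SynexpressError):
    """Malformed or inconsistent ontology input (cycles, duplicate ids, ...)."""


class AnnotationError(SynexpressError):
    """Malformed annotation table or inconsistent annotation content."""


class ClusteringError(SynexpressError):
    """Invalid clustering input (zero-variance genes, asymmetric distances)."""


class EnrichmentError(SynexpressError):
    """Invalid enrichment input (bound violations, empty universe)."""


class ConfigError(SynexpressError):
    """Invalid pipeline or generator configuration."""
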