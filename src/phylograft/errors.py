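"""Exception hierarchy shared across the package."""


class PhylograftError(Exception):
    """Base class for all package errors."""


class FormatError(PhylograftError):
    """Malformed input file (bad columns, duplicate ids, ragged alignment...)."""


class TaxonomyCycleError(FormatError):
    """Parent pointers in the taxonomy form a cycle."""


class UnresolvedNameError(PhylograftError):
    def __init__(self, query: str):
        super().__init__(f"could not resolve taxon name: {query!r}")
        self.query = query


class AmbiguousNameError(PhylograftError):
    def __init__(self, query: str, candidates):
        self.query = query
        self.candidates = list(candidates)
        ids = ", ".join(r.taxon_id for r in self.candidates)
        super().__init__(f"name {query!r} matches {len(self.candidates)} records: {ids}")


class UnknownTaxonError(PhylograftError, KeyError):
    def __init__(self, taxon_id: str):
        Exception.__init__(self, f"unknown taxon id: {taxon_id!r}")
        self.taxon_id = taxon_id


class ReconcileError(PhylograftError):
    """No overlap between tree and alignment; at least one taxon and its
    corresponding sequence are required."""


class SearchError(PhylograftError):
    def __init__(self, query_label: str, message: str):
        super().__init__(f"search failed for query {query_label!r}: {message}")
        self.query_label = query_label


class UnresolvedSubjectError(PhylograftError):
    """Tabular hit refers to an accession absent from the database."""


class ConfigError(PhylograftError):
    """Invalid configuration value or missing required path."""


class IntegrityError(PhylograftError):
    """Extended alignment no longer reproduces its original template."""


class CapabilityError(PhylograftError):
    """A required external binary is not available."""


class ToolError(PhylograftError):
    """External tool exited nonzero."""

    def __init__(self, message: str, output: str = ""):
        super().__init__(message)
        self.output = output


class UndefinedMetricError(PhylograftError):
    """Tree comparison requested on fewer than 4 shared leaves."""
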