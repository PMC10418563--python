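"""Exception hierarchy shared by all taxomasst modules."""


class TaxomasstError(Exception):
    """Base class for all taxomasst-specific errors."""


class MgfFormatError(TaxomasstError):
    """A malformed MGF block (e.g. missing PEPMASS); message names the block."""


class UsiParseError(TaxomasstError):
    """A string that is not a valid mzspec: Universal Spectrum Identifier."""


class StoreLookupError(TaxomasstError):
    """USI resolution failed: unknown collection/run in the local store."""


class SpectrumNotFoundError(TaxomasstError):
    """USI resolution failed: scan/index absent from the resolved run."""


class UndefinedScoreError(TaxomasstError):
    """Similarity requested for two empty spectra."""


class EmptyQueryError(TaxomasstError):
    """A search was attempted with a peak-less query spectrum."""


class IndexBuildError(TaxomasstError):
    """Library index construction failed (e.g. duplicate provenance id)."""


class SchemaError(TaxomasstError):
    """A metadata/feature table is missing a required column."""


class MetadataValidationError(TaxomasstError):
    """A metadata row violates the file-record contract."""


class UnresolvableTaxonError(TaxomasstError):
    """No lineage could be assigned to a file record by any fallback path."""


class InconsistentLineageError(TaxomasstError):
    """Two lineages disagree on a taxon's parent (or rank/name)."""


class ConsistencyError(TaxomasstError):
    """A match references a file that is not attached to the taxonomic tree."""


class ParameterError(TaxomasstError):
    """An invalid user-facing parameter (unknown rank, condition label, ...)."""


class FixtureSpecError(TaxomasstError):
    """An infeasible synthetic-fixture specification."""
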