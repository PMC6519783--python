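"""Exception hierarchy shared across the package."""


class SuppsignalError(Exception):
    """Base class for all errors raised by suppsignal."""


class CorpusError(SuppsignalError):
    """Problems with a forum corpus file."""


class CorpusFormatError(CorpusError):
    """The corpus XML is not well formed."""


class CorpusSchemaError(CorpusError):
    """The corpus XML is well formed but violates the expected schema."""


class LexiconError(SuppsignalError):
    """A products or effects lexicon file is invalid."""


class ReportError(SuppsignalError):
    """A report cannot be produced from the given hits/corpus."""


class PipelineError(SuppsignalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
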