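"""Exception hierarchy shared by all stages of the design protocol."""


class ProstabError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(ProstabError):
    """A structure source contained no polymer residues."""


class NotFoundError(ProstabError, KeyError):
    """A requested chain, residue or atom does not exist."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class FormatError(ProstabError, ValueError):
    """An input file violates its expected format."""


class ConfigurationError(ProstabError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class InvalidModelError(ProstabError, ValueError):
    """A variant model is missing coordinates required for scoring."""


class PipelineError(ProstabError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.manifest = manifest or {}
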