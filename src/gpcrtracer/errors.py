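"""Exception hierarchy shared across the package."""


class GpcrTracerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GpcrTracerError, ValueError):
    """A generator or model configuration violates its invariants."""


class SchemaError(GpcrTracerError, ValueError):
    """A table is missing required columns or carries unexpected labels."""


class PipelineError(GpcrTracerError, RuntimeError):
    """A dataset-pipeline stage produced an unusable result."""


class EncodingError(GpcrTracerError, ValueError):
    """A SMILES string could not be encoded as a fingerprint.

    Carries the offending string as ``smiles``.
    """

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")
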