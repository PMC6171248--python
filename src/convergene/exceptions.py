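"""Exception hierarchy shared across the pipeline stages."""


class ConvergeneError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ConvergeneError):
    """A text input (hit table, Newick, assignment table) is malformed."""


class ValidationError(ConvergeneError):
    """An input violates a documented invariant (range, symmetry, counts)."""


class MissingGenomeError(ConvergeneError):
    """A requested genome is absent from the input table."""


class PipelineError(ConvergeneError):
    """A pipeline stage failed; carries the stage name and partial outputs."""

    def __init__(self, stage: str, message: str, outdir=None):
        self.stage = stage
        self.outdir = outdir
        where = f" (partial outputs in {outdir})" if outdir else ""
        super().__init__(f"stage '{stage}' failed: {message}{where}")
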