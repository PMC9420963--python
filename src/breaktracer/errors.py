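"""Exception hierarchy shared across the pipeline stages."""


class BreaktracerError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(BreaktracerError):
    """Invalid input values, malformed records, or violated preconditions."""


class ParseError(ValidationError):
    """A token or record could not be parsed."""


class BoundsError(ValidationError):
    """A genomic interval falls outside its chromosome."""


class NoFusionCandidateError(BreaktracerError):
    """No structural-variant call links the two partner-gene loci."""


class NoAssayError(BreaktracerError):
    """Assay design infeasible: a candidate pool is empty.

    ``stage`` names which pool (fwd primers, rev primers, probe, pairing)
    emptied first.
    """

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage
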