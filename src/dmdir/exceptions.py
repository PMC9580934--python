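"""Exception types shared across dmdir modules."""


class DmdirError(Exception):
    """Base class for all dmdir errors."""


class ParameterError(DmdirError, ValueError):
    """An argument violates a documented precondition."""


class SingularDesignError(DmdirError, ValueError):
    """The regression design matrix is rank deficient.

    Carries the names of the offending (collinear) columns so the caller can
    see which terms collapsed (e.g. every interaction column when the
    phenotype is constant).
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class InsufficientSamplesError(DmdirError, ValueError):
    """Too few samples for the number of model parameters."""


class IndexMismatchError(DmdirError, ValueError):
    """Two tables that must share a (CpG, cell type) universe do not."""
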