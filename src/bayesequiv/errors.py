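"""Exception types shared across the package."""


class InvalidDataError(ValueError):
    """Raised when input samples or summary statistics are unusable."""


class ScaleMismatchError(ValueError):
    """Raised when an equivalence region is given on the wrong scale."""


class DegenerateRegionError(ValueError):
    """Raised when an equivalence region carries essentially no prior mass
    on one of its sides, making an interval Bayes factor undefined."""


class NumericalError(RuntimeError):
    """Raised when quadrature or normalization fails to reach tolerance.

    The ``achieved_error`` attribute carries the error estimate that was
    actually reached.
    """

    def __init__(self, message: str, achieved_error: float | None = None):
        super().__init__(message)
        self.achieved_error = achieved_error


class MissingCellsError(ValueError):
    """Raised when a selection query needs simulation cells that are absent
    from the supplied results table.  ``missing`` lists the cells to run."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = missing or []
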