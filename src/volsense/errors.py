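"""Exception hierarchy for the volsense pipeline.

Every error raised by the library derives from :class:`VolsenseError` so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class VolsenseError(Exception):
    """Base class for all volsense errors."""


class FormatError(VolsenseError):
    """A file or row failed structural validation.

    Carries an optional line number (1-based, header = line 1) so readers
    can point at the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class RangeError(VolsenseError):
    """A value fell outside its documented closed range."""


class FeatureUndefinedError(VolsenseError):
    """A feature has no defined value for this subject.

    Raised e.g. for a zero-variance autocorrelation segment or an empty
    sleep window; callers typically record the cell as missing rather than
    aborting the cohort.
    """


class ParameterError(VolsenseError):
    """Simulation or pipeline parameters are invalid or inconsistent."""


class PipelineError(VolsenseError):
    """A pipeline stage failed; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
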