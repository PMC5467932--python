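"""Exception hierarchy shared across the pipeline."""


class PetPhError(Exception):
    """Base class for all package errors."""


class FormatError(PetPhError):
    """A file or in-memory object violates the expected raster format."""


class DomainError(PetPhError, ValueError):
    """An operation was called outside its mathematical domain."""


class SpecError(PetPhError, ValueError):
    """A phantom or cohort specification is internally inconsistent."""


class PartitionError(PetPhError):
    """The lung mask cannot be partitioned into the 24 standard regions."""


class ContourabilityError(PetPhError):
    """The ventricular cavity cannot be delineated against the wall uptake.

    Mirrors the clinical situation where myocardial uptake is too low to
    visualise the inner wall boundary, so no contour can be drawn.
    """


class SeedAboveThresholdError(ContourabilityError):
    """The seed voxel is not below the wall-referenced cavity threshold."""


class RegionLeakError(ContourabilityError):
    """Region growing escaped the analysis box: no closed wall boundary."""


class DegenerateVarianceError(DomainError):
    """A t statistic is undefined: zero variance with unequal means."""


class ConstantInputError(DomainError):
    """Rank correlation is undefined for a constant vector."""


class TableError(PetPhError):
    """A cohort table cannot be built (e.g. fewer than two groups)."""


class StageError(PetPhError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject: str, cause: BaseException):
        self.stage = stage
        self.subject = subject
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for subject '{subject}': {cause}")
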