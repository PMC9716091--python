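"""Exception hierarchy.

``HomeoxError`` covers everything raised deliberately by the package; the CLI
maps it to exit code 1 (bad input / configuration) while anything else is an
internal error (exit code 2).
"""


class HomeoxError(Exception):
    """Base class for all errors raised by homeox."""


class FormatError(HomeoxError):
    """A file does not conform to the expected dialect (names the offender)."""


class CoordinateError(HomeoxError):
    """An interval or position falls outside the declared chromosome bounds."""


class CohortError(HomeoxError):
    """Sample set inconsistency between a file and the cohort definition."""


class ConfigError(HomeoxError):
    """Invalid or inconsistent configuration values."""


class EventConflictError(ConfigError):
    """Two planted events overlap for the same carrier on one chromosome."""


class SupportError(HomeoxError):
    """A called genotype carries zero supporting reads."""


class RefinementError(HomeoxError):
    """Coverage-based boundary refinement found no qualifying region."""


class AlignmentError(HomeoxError):
    """Two bin grids that must coincide do not."""


class UndefinedTestError(HomeoxError):
    """A statistical test was requested on an empty margin (n = 0)."""
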