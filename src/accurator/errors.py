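"""Exception hierarchy for scenario validation.

All exceptions derive from :class:`AccuratorError`, itself a ``ValueError``,
so callers that do not care about the distinction can catch a single type.
"""


class AccuratorError(ValueError):
    """Base class for all domain errors raised by this package."""


class DomainError(AccuratorError):
    """A parameter is outside its mathematical domain (e.g. a fraction not in (0,1))."""


class InfeasibleScenarioError(AccuratorError):
    """The parameter combination implies an impossible 2x2 table (PPV > 1 or NPV < 0).

    Raised instead of clamping: silently truncating would fabricate a scenario
    the inputs do not describe.
    """


class DegenerateScenarioError(AccuratorError):
    """A metric is undefined because a margin of the 2x2 table is empty."""
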