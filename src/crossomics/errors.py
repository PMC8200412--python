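"""Exception hierarchy shared across the package.

Two error families matter operationally: violations of the trial data model
(duplicate ids, broken compositional closure, missing metadata) and
statistical preconditions (too few pairs, zero variance, constant profiles).
The CLI maps them to distinct exit codes.
"""


class CrossomicsError(Exception):
    """Base class for all package errors."""


class DataInvariantError(CrossomicsError, ValueError):
    """A trial-data invariant is violated (I/O layer, metadata, closure)."""


class StatisticalPreconditionError(CrossomicsError, ValueError):
    """An operation's statistical precondition is not met (e.g. < 3 pairs)."""
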