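"""Exception hierarchy shared across the package."""


class FocalCbsError(Exception):
    """Base class for all package-specific errors."""


class InvalidRecordError(FocalCbsError, ValueError):
    """An energy or SAPT record violates its invariants."""


class MismatchedRecordsError(InvalidRecordError):
    """Records combined in one operation disagree on system, component,
    cardinal number or basis context."""


class IncompleteDataError(FocalCbsError, ValueError):
    """A required (fragment, component, cardinal) record is absent."""

    def __init__(self, system_id, missing):
        self.system_id = system_id
        #: list of (fragment, component, cardinal) triples that are absent
        self.missing = list(missing)
        triples = ", ".join(
            f"({f.value if hasattr(f, 'value') else f}, "
            f"{c.value if hasattr(c, 'value') else c}, {x})"
            for f, c, x in self.missing
        )
        super().__init__(f"system {system_id!r}: missing records {triples}")


class IllConditionedExtrapolationError(FocalCbsError, ArithmeticError):
    """The two extrapolation weights are numerically indistinguishable, so
    the CBS limit would be a catastrophic cancellation."""


class DegenerateRegressionError(FocalCbsError, ValueError):
    """Regression requested on a constant predictor vector."""


class UndefinedRatioError(FocalCbsError, ZeroDivisionError):
    """Dispersion-to-polarization ratio with a zero polarization component."""


class ZeroReferenceError(FocalCbsError, ZeroDivisionError):
    """Relative deviation requested against a zero reference value."""
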