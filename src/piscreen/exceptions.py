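"""Exception hierarchy."""


class PiscreenError(Exception):
    """Base class for all package errors."""


class ParseError(PiscreenError):
    """A structure file could not be parsed; message names the offending line."""


class UnsupportedElementError(PiscreenError):
    """An element symbol is not recognized."""


class UnsupportedCenterError(PiscreenError):
    """An atom participates in the pi network but has no PPP parameters."""


class OddElectronError(PiscreenError):
    """The perceived pi system carries an odd number of electrons."""


class NotConvergedError(PiscreenError):
    """An SCF solution was requested from a non-converged reference."""
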