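"""Exception hierarchy for macroenum."""


class MacroenumError(Exception):
    """Base class for all macroenum errors."""


class MotifFormatError(MacroenumError):
    """A motif fragment could not be parsed."""


class MotifValidityError(MacroenumError):
    """A motif fragment parsed but violates a structural requirement."""


class MotifConflictError(MacroenumError):
    """Duplicate motif identifier within a registry."""


class RulesInfeasibleError(MacroenumError):
    """Building rules admit no scaffold (e.g. ring size beyond reachable unit count)."""


class RulesReferenceError(MacroenumError):
    """Building rules refer to a motif absent from the registry."""


class ChemistryError(MacroenumError):
    """Assembly or standardization produced an invalid molecule."""
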