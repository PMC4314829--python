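"""Exception hierarchy shared across the toolkit."""


class DhqForgeError(Exception):
    """Base class for all toolkit errors."""


class InputError(DhqForgeError):
    """Malformed user input (bad residue, bad coordinate, bad file)."""


class ConfigurationError(DhqForgeError):
    """Invalid scoring/design/assay configuration."""


class DesignError(DhqForgeError):
    """A gene design could not be completed (e.g. unsatisfiable scrub)."""


class FitError(DhqForgeError):
    """A kinetic fit could not be performed or gave a nonsensical result."""


class PackagingError(DhqForgeError):
    """A packaged fixture failed its integrity check."""
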