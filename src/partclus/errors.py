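"""Exception hierarchy for partclus."""


class PartclusError(Exception):
    """Base class for all partclus errors."""


class InvalidDistributionError(PartclusError, ValueError):
    """A cluster-size distribution is malformed (negative entries, zero sum, ...)."""


class ConfigurationError(PartclusError, ValueError):
    """A design/effect/generation specification is inconsistent or incomplete."""


class DegenerateDesignError(PartclusError, ValueError):
    """An allocation admits no treatment-effect variance (singular information)."""


class FeasibilityError(PartclusError, ValueError):
    """Requested moments cannot be realised by any joint binary distribution."""
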