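"""Exception hierarchy for karyostd.

All toolkit errors derive from :class:`KaryostdError` so callers (and the CLI)
can distinguish input problems from programming errors.
"""


class KaryostdError(Exception):
    """Base class for all karyostd errors."""


class InvalidMeasurementError(KaryostdError):
    """A chromosome measurement violates its invariants (e.g. zero total length)."""


class PairingError(KaryostdError):
    """A metaphase cannot be paired into chromosomes (odd count)."""


class CardinalityError(KaryostdError):
    """Chromosome counts disagree with the declared ploidy or with each other."""


class EmptyInputError(KaryostdError):
    """An operation received no data."""


class FormulaError(KaryostdError):
    """A karyotype formula string cannot be parsed or built."""


class ConfigError(KaryostdError):
    """Invalid pipeline or simulation configuration."""


class FixtureIntegrityError(KaryostdError):
    """The packaged reference table failed its checksum."""


class OrientationWarning(UserWarning):
    """Short/long arm labels were swapped to restore the q >= p convention."""
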