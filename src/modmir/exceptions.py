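"""Exception hierarchy for modmir."""


class ModmirError(Exception):
    """Base class for all modmir errors."""


class ConfigurationError(ModmirError):
    """A configuration value violates its documented constraints."""


class InputError(ModmirError):
    """An input table or file violates the documented contract."""


class IntegrityError(ModmirError):
    """A bundled data file does not match its recorded checksum."""
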