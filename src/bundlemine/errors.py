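"""Exception hierarchy shared by all bundlemine modules."""


class BundlemineError(Exception):
    """Base class for all bundlemine errors."""


class InputError(BundlemineError):
    """An input file is missing, unreadable, or unparseable."""


class EmptyGenomeError(InputError):
    """No gene models remain after the feature-type filter."""


class ValidationError(BundlemineError):
    """Data violates an invariant (duplicate ids, dangling references, ...)."""


class ConfigurationError(BundlemineError):
    """A run configuration is incomplete or internally inconsistent."""
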