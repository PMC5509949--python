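"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied path, column mapping, or dictionary file is unusable."""


class IntegrityError(RuntimeError):
    """Internal consistency violated: row ids outside the corpus, negative
    confusion-cell counts, or similar signs of a bug in upstream set algebra."""
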