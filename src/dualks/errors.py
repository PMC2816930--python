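"""Exception types shared across the package."""


class DualKSError(ValueError):
    """Raised for invalid inputs or configurations.

    The command-line interface maps this to exit code 2.
    """
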