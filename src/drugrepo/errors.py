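"""Package-wide exception types."""


class MissingDataError(ValueError):
    """A drug pair cannot be scored because a modality lacks data.

    Network builders catch this and record a zero entry instead of failing.
    """
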