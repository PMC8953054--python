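"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(ValueError):
    """The input is valid but the quantity is undefined on it.

    Examples: skewness of a constant image (zero standard deviation),
    GLCM correlation of a constant image, fractal dimension of an empty
    edge map.
    """
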