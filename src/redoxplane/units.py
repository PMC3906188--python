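"""Small unit helpers for uptake-rate bookkeeping."""

CARBONS = {
    "glucose": 6,
    "xylose": 5,
    "ethanol": 2,
    "glycerol": 3,
    "pyruvate": 3,
}


def carbon_mmol(rate: float, compound: str = "glucose", digits: int = 1) -> float:
    """Convert mmol gDW^-1 h^-1 to C-mmol gDW^-1 h^-1, rounded as printed.

    >>> carbon_mmol(4.45)
    26.7
    """
    try:
        n_c = CARBONS[compound]
    except KeyError:
        raise KeyError(
            f"unknown compound {compound!r}; known: {sorted(CARBONS)}"
        ) from None
    return round(rate * n_c, digits)
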