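"""Unit conversions between picograms of DNA and megabases.

The standard conversion constant for double-stranded DNA is
1 pg = 978 Mb.
"""

MB_PER_PG = 978.0


def pg_to_mb(x: float) -> float:
    """Convert a DNA mass in picograms to megabases (1 pg = 978 Mb)."""
    if x < 0:
        raise ValueError(f"DNA content must be non-negative, got {x}")
    return x * MB_PER_PG


def mb_to_pg(x: float) -> float:
    """Convert a sequence length in megabases to picograms."""
    if x < 0:
        raise ValueError(f"sequence length must be non-negative, got {x}")
    return x / MB_PER_PG


def bp_to_pg(x: float) -> float:
    """Convert a length in base pairs to picograms."""
    return mb_to_pg(x / 1e6)
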