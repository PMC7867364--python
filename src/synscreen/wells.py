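"""96-well plate addressing.

Addresses are row letter (A-H) plus 1-based column number (1-12),
row-major. Both "A1" and zero-padded "A01" are accepted on input;
output is always zero-padded.
"""

from __future__ import annotations

import re

ROWS = "ABCDEFGH"
N_COLS = 12

_WELL_RE = re.compile(r"^([A-H])(0?[1-9]|1[0-2])$")


class WellAddressError(ValueError):
    """Raised for a string that is not a valid A1-H12 well address."""


def parse_well(address: str) -> tuple[int, int]:
    """Parse a well address into 0-based (row, column) indices.

    Accepts "A1" and "A01" dialects; rejects anything outside A1-H12.
    """
    if not isinstance(address, str):
        raise WellAddressError(f"well address must be a string, got {address!r}")
    m = _WELL_RE.match(address.strip())
    if m is None:
        raise WellAddressError(f"invalid well address {address!r} (expected A1-H12)")
    return ROWS.index(m.group(1)), int(m.group(2)) - 1


def format_well(row: int, col: int) -> str:
    """Format 0-based (row, column) as a zero-padded address, e.g. (2, 6) -> "C07"."""
    if not (0 <= row < len(ROWS) and 0 <= col < N_COLS):
        raise WellAddressError(f"(row={row}, col={col}) outside the 8x12 plate")
    return f"{ROWS[row]}{col + 1:02d}"


def canonical_well(address: str) -> str:
    """Normalize an address to the zero-padded dialect."""
    return format_well(*parse_well(address))


def well_sort_key(address: str) -> tuple[int, int]:
    """Row-major sort key for well addresses."""
    return parse_well(address)


def all_wells() -> list[str]:
    """All 96 addresses in row-major order, zero-padded."""
    return [format_well(r, c) for r in range(len(ROWS)) for c in range(N_COLS)]
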