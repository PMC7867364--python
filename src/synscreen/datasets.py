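"""Packaged example data."""

from __future__ import annotations

from pathlib import Path

from .screen_model import Screen, load_screen


def demo_screen_dir() -> Path:
    """Directory of the packaged demo screen (synthetic, seed-fixed).

    3 compounds x (2 targeted + 1 control) lines at 20 uM, 4 replicate
    wells, one planted interaction (CSNK2A1 x the ATM inhibitor
    KU-60019); generated by :func:`synscreen.simulate.demo_config` with
    seed 7.
    """
    return Path(__file__).parent / "data" / "demo"


def load_demo_screen() -> Screen:
    """Load the packaged demo screen with full validation."""
    return load_screen(demo_screen_dir())
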