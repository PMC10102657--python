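"""Small conversions for proximate (biochemical) assay values."""

from __future__ import annotations

__all__ = ["starch_from_reducing_sugar", "dry_matter_percent"]

#: conversion factor from reducing sugar (%) to starch (%)
STARCH_FACTOR = 0.9


def starch_from_reducing_sugar(reducing_sugar_percent: float) -> float:
    """Starch (%) from reducing sugar (%): starch = reducing_sugar x 0.9."""
    if reducing_sugar_percent < 0:
        raise ValueError("reducing sugar percent cannot be negative")
    return reducing_sugar_percent * STARCH_FACTOR


def dry_matter_percent(fresh_g: float, dry_g: float) -> float:
    """Gravimetric dry-matter percent: 100 * dry / fresh."""
    if fresh_g <= 0:
        raise ValueError("fresh weight must be positive")
    if dry_g < 0 or dry_g > fresh_g:
        raise ValueError("dry weight must lie in [0, fresh weight]")
    return 100.0 * dry_g / fresh_g
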