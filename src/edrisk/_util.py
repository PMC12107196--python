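"""Shared helpers: error types and the reporting rounding convention."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(ValueError):
    """Input value outside its plausible / contractual range."""


class RegistryParseError(ValueError):
    """Malformed registry file; message names the offending row and column."""


class SeparationError(RuntimeError):
    """Quasi-complete separation detected while fitting (diverging coefficients)."""


def round_half_up(x, ndigits: int = 1):
    """Round half away from zero, the convention used for all reported percentages.

    numpy's default rounds half to even; reported tables in this field round
    97.25 -> 97.3, so we shift-and-floor instead.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        return float(out)
    return out


def percent(numerator, denominator, ndigits: int = 1):
    """Percentage of ``numerator`` over ``denominator``, reported to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
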